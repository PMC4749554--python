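"""Per-(cell, frame) organizational features and CMAC intensity handling.

The built-in feature set covers the representative organizational features:
cell area and compactness, CMAC count, median/total CMAC area, median CMAC
lifetime, median CMAC distance to the cell border, median background-corrected
paxillin density and F-actin (LifeAct) association.  Further features plug in
through :data:`FEATURE_REGISTRY` (name -> function taking a
:class:`FrameContext`).

CMAC intensities are corrected by subtracting the mean intensity in a 1 µm
annulus around each CMAC (excluding pixels of any other segmented CMAC) and
standardized per experimental repeat against the median corrected intensity
of reference-sized CMACs (area in [0.15, 0.2] µm²) of a reference condition.

Aggregates over zero CMACs are *undefined* (NaN), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import perimeter_crofton
from skimage.morphology import disk

from .config import AnalysisConfig
from .datatypes import IntensityMovie, LabelMovie
from .io import MODE_NULL

__all__ = [
    "compute_cell_shape",
    "compute_cmac_aggregates",
    "correct_cmac_intensity",
    "reference_median",
    "standardize_intensity",
    "extract_frame_features",
    "assemble_feature_table",
    "FEATURE_REGISTRY",
    "register_feature",
    "BUILTIN_FEATURES",
]

BUILTIN_FEATURES = [
    "cell_area_um2",
    "cell_compactness",
    "cmac_count",
    "cmac_area_median_um2",
    "cmac_area_total_um2",
    "cmac_distance_to_border_median_um",
    "cmac_paxillin_density_median",
    "cmac_factin_assoc_median",
]

#: extension point: name -> callable(FrameContext) -> float
FEATURE_REGISTRY: dict = {}


def register_feature(name: str):
    """Decorator registering an extra per-(cell, frame) feature."""

    def deco(func):
        FEATURE_REGISTRY[name] = func
        return func

    return deco


@dataclass
class FrameContext:
    """Everything a registered feature function may need for one observation."""

    cell_mask: np.ndarray
    cmac_masks: list
    pixel_size_um: float
    paxillin: np.ndarray | None = None
    lifeact: np.ndarray | None = None


def compute_cell_shape(mask: np.ndarray, pixel_size_um: float) -> tuple[float, float]:
    """Area (µm²) and compactness of a single-cell binary mask.

    Compactness is 4πA/P² with the perimeter estimated by the Crofton formula
    (4 directions); 1 for a circle, smaller for protrusive shapes.  Digital
    discretization can push the raw ratio slightly above 1, so the value is
    clipped into (0, 1].
    """
    mask = np.asarray(mask, dtype=bool)
    area_px = int(mask.sum())
    if area_px == 0:
        raise ValueError("empty cell mask")
    area = area_px * pixel_size_um**2
    perim = perimeter_crofton(mask, directions=4) * pixel_size_um
    compactness = min(1.0, 4.0 * np.pi * area / perim**2) if perim > 0 else 1.0
    return area, compactness


def compute_cmac_aggregates(
    cell_mask: np.ndarray, cmac_masks: list, pixel_size_um: float
) -> dict:
    """Count and area/position aggregates of the CMACs inside one cell.

    Distance-to-border is the Euclidean distance (µm) from each CMAC centroid
    to the nearest non-cell pixel, median over CMACs.  With zero CMACs the
    aggregates are NaN (undefined), not 0.
    """
    n = len(cmac_masks)
    if n == 0:
        return {
            "cmac_count": 0,
            "cmac_area_median_um2": np.nan,
            "cmac_area_total_um2": np.nan,
            "cmac_distance_to_border_median_um": np.nan,
        }
    areas = np.array([m.sum() for m in cmac_masks], dtype=float) * pixel_size_um**2
    dist = ndimage.distance_transform_edt(np.asarray(cell_mask, dtype=bool))
    dists = []
    for m in cmac_masks:
        rows, cols = np.nonzero(m)
        r, c = int(round(rows.mean())), int(round(cols.mean()))
        dists.append(dist[r, c] * pixel_size_um)
    return {
        "cmac_count": n,
        "cmac_area_median_um2": float(np.median(areas)),
        "cmac_area_total_um2": float(areas.sum()),
        "cmac_distance_to_border_median_um": float(np.median(dists)),
    }


def correct_cmac_intensity(
    cmac_mask: np.ndarray,
    intensity: np.ndarray,
    all_cmac_mask: np.ndarray,
    pixel_size_um: float,
    radius_um: float = 1.0,
) -> float:
    """Background-corrected mean intensity of one CMAC.

    The local background is the mean intensity in an annulus obtained by
    dilating the CMAC by ``radius_um``, minus the CMAC itself and minus the
    pixels of every other segmented CMAC.  Returns NaN (flagged undefined)
    when the annulus is empty.
    """
    cmac_mask = np.asarray(cmac_mask, dtype=bool)
    radius_px = max(1, int(round(radius_um / pixel_size_um)))
    dilated = ndimage.binary_dilation(cmac_mask, structure=disk(radius_px))
    annulus = dilated & ~cmac_mask & ~np.asarray(all_cmac_mask, dtype=bool)
    if not annulus.any():
        return float("nan")
    return float(intensity[cmac_mask].mean() - intensity[annulus].mean())


def reference_median(
    corrected: np.ndarray,
    areas_um2: np.ndarray,
    size_range_um2: tuple = (0.15, 0.2),
) -> float:
    """Median corrected intensity of reference-sized CMACs (one repeat)."""
    corrected = np.asarray(corrected, dtype=float)
    areas = np.asarray(areas_um2, dtype=float)
    sel = (areas >= size_range_um2[0]) & (areas <= size_range_um2[1])
    sel &= np.isfinite(corrected)
    if not sel.any():
        raise ValueError(
            f"no CMACs in reference size range {size_range_um2} for this repeat"
        )
    return float(np.median(corrected[sel]))


def standardize_intensity(corrected: np.ndarray, ref_median: float) -> np.ndarray:
    """Standardize corrected intensities against a repeat's reference median."""
    if not np.isfinite(ref_median) or ref_median <= 0:
        raise ValueError(f"reference median must be positive, got {ref_median}")
    return np.asarray(corrected, dtype=float) / ref_median


def _cmacs_in_cell(cell_mask: np.ndarray, cmac_frame: np.ndarray) -> list:
    """CMAC binary masks whose majority of pixels lie inside the cell."""
    masks = []
    for lab in np.unique(cmac_frame):
        if lab == 0:
            continue
        m = cmac_frame == lab
        if cell_mask[m].mean() > 0.5:
            masks.append(m)
    return masks


def extract_frame_features(
    cell_movie: LabelMovie,
    cell_tracks: pd.DataFrame,
    cmac_movie: LabelMovie | None = None,
    paxillin: IntensityMovie | None = None,
    lifeact: IntensityMovie | None = None,
) -> pd.DataFrame:
    """Built-in organizational features for every tracked (cell, frame).

    CMACs are assigned to the enclosing cell; intensity features use the
    1 µm annulus correction (unstandardized here — standardization needs the
    per-repeat reference and is applied on the assembled table).
    """
    px = cell_movie.pixel_size_um
    rows = []
    for (tid, frame), sub in cell_tracks.groupby(["track_id", "frame"]):
        lab = int(sub["label_id"].iloc[0])
        cell_mask = cell_movie.frames[frame] == lab
        if not cell_mask.any():
            continue
        area, compactness = compute_cell_shape(cell_mask, px)
        row = {
            "cell_track_id": tid,
            "frame": int(frame),
            "cell_area_um2": area,
            "cell_compactness": compactness,
        }
        if cmac_movie is not None:
            cmac_frame = cmac_movie.frames[frame]
            masks = _cmacs_in_cell(cell_mask, cmac_frame)
            row.update(compute_cmac_aggregates(cell_mask, masks, px))
            all_cmac = cmac_frame > 0
            for channel, movie, col in (
                ("paxillin", paxillin, "cmac_paxillin_density_median"),
                ("lifeact", lifeact, "cmac_factin_assoc_median"),
            ):
                if movie is None:
                    continue
                vals = [
                    correct_cmac_intensity(m, movie.frames[frame], all_cmac & ~m, px)
                    for m in masks
                ]
                vals = [v for v in vals if np.isfinite(v)]
                row[col] = float(np.median(vals)) if vals else np.nan
        ctx = FrameContext(
            cell_mask=cell_mask,
            cmac_masks=_cmacs_in_cell(cell_mask, cmac_movie.frames[frame])
            if cmac_movie is not None
            else [],
            pixel_size_um=px,
            paxillin=paxillin.frames[frame] if paxillin is not None else None,
            lifeact=lifeact.frames[frame] if lifeact is not None else None,
        )
        for name, func in FEATURE_REGISTRY.items():
            row[name] = func(ctx)
        rows.append(row)
    return pd.DataFrame(rows)


def assemble_feature_table(
    frame_features: pd.DataFrame,
    mode_labels: pd.DataFrame,
    behavioral: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join per-frame features with mode labels (and behavioral features).

    One row per (cell, frame); rows labeled ``null`` are excluded.  Keys in
    ``frame_features`` that are missing from ``mode_labels`` are an error
    (the offending keys are named).
    """
    key = ["cell_track_id", "frame"]
    merged = frame_features.merge(
        mode_labels, on=key, how="left", validate="one_to_one"
    )
    missing = merged["mode"].isna()
    if missing.any():
        bad = merged.loc[missing, key].head().to_dict("records")
        raise KeyError(f"observations without mode labels, e.g. {bad}")
    merged = merged[merged["mode"].astype(str).str.strip() != MODE_NULL]
    if behavioral is not None:
        merged = merged.merge(behavioral, on=key, how="left", validate="one_to_one")
    front = ["cell_track_id", "frame", "condition", "repeat_id", "mode"]
    cols = front + [c for c in merged.columns if c not in front]
    return merged[cols].reset_index(drop=True)
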