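"""Object tracking, trajectory smoothing and CMAC filtering.

Cells and CMACs (cell–matrix adhesion complexes) are tracked across frames by
mutual-nearest-centroid linking with a distance gate: an object in frame t is
linked to an object in frame t+1 only if each is the other's nearest centroid
and the distance is within the gate.  Unmatched objects end or start tracks;
tracks never contain frame gaps (no gap closing — objects must be present in
consecutive frames).

Cells touching the image border in a frame are excluded from that frame
before tracking.  CMAC observations at or below the minimum area are dropped,
CMAC tracks shorter than three consecutive frames are discarded, and lifetime
is only defined for tracks that do not touch the first or last frame of the
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from skimage.measure import regionprops

from .config import AnalysisConfig
from .datatypes import CELL_LAYER, CMAC_LAYER, LabelMovie

__all__ = [
    "TRACK_COLUMNS",
    "exclude_border_cells",
    "track_objects",
    "smooth_trajectory",
    "smooth_tracks",
    "filter_cmacs",
]

TRACK_COLUMNS = [
    "track_id",
    "layer",
    "frame",
    "label_id",
    "centroid_x_um",
    "centroid_y_um",
    "smoothed_x_um",
    "smoothed_y_um",
    "area_um2",
]


def exclude_border_cells(movie: LabelMovie) -> LabelMovie:
    """Remove, per frame, every label with at least one image-border pixel."""
    frames = movie.frames.copy()
    for t in range(len(movie)):
        frame = frames[t]
        border = np.concatenate(
            [frame[0, :], frame[-1, :], frame[:, 0], frame[:, -1]]
        )
        bad = np.unique(border)
        bad = bad[bad != 0]
        if bad.size:
            frame[np.isin(frame, bad)] = 0
    return LabelMovie(
        frames=frames,
        pixel_size_um=movie.pixel_size_um,
        frame_interval_min=movie.frame_interval_min,
        layer=movie.layer,
    )


def _frame_objects(frame: np.ndarray, pixel_size: float) -> pd.DataFrame:
    props = regionprops(frame)
    rows = [
        {
            "label_id": p.label,
            # centroid is (row, col); x = col, y = row in physical µm
            "centroid_x_um": p.centroid[1] * pixel_size,
            "centroid_y_um": p.centroid[0] * pixel_size,
            "area_um2": p.area * pixel_size**2,
        }
        for p in props
    ]
    out = pd.DataFrame(rows, columns=["label_id", "centroid_x_um", "centroid_y_um", "area_um2"])
    return out.sort_values("label_id").reset_index(drop=True)


def _mutual_nearest_links(
    prev: pd.DataFrame, curr: pd.DataFrame, gate_um: np.ndarray
) -> list[tuple[int, int]]:
    """Indices (i_prev, j_curr) of mutual nearest pairs within per-prev gates."""
    if prev.empty or curr.empty:
        return []
    pxy = prev[["centroid_x_um", "centroid_y_um"]].to_numpy()
    cxy = curr[["centroid_x_um", "centroid_y_um"]].to_numpy()
    d = np.linalg.norm(pxy[:, None, :] - cxy[None, :, :], axis=2)
    # argmin breaks distance ties by lower index = lower label id (sorted input)
    nearest_fwd = d.argmin(axis=1)
    nearest_bwd = d.argmin(axis=0)
    links = []
    for i, j in enumerate(nearest_fwd):
        if nearest_bwd[j] == i and d[i, j] <= gate_um[i]:
            links.append((i, int(j)))
    return links


def _gates(objects: pd.DataFrame, layer: str, max_displacement_um: float | None) -> np.ndarray:
    if max_displacement_um is not None:
        return np.full(len(objects), float(max_displacement_um))
    if layer == CMAC_LAYER:
        return np.full(len(objects), 2.0)
    # cells: 3 equivalent radii of the earlier object
    radii = np.sqrt(objects["area_um2"].to_numpy() / np.pi)
    return 3.0 * radii


def track_objects(
    movie: LabelMovie, max_displacement_um: float | None = None
) -> pd.DataFrame:
    """Track labeled objects across frames by gated mutual-nearest linking.

    Default gates: 3 equivalent cell radii for the cell layer, 2 µm for the
    CMAC layer.  Returns a track table with one row per (track_id, frame);
    smoothed coordinates are initialized to the raw centroids (see
    :func:`smooth_tracks`).
    """
    per_frame = [_frame_objects(f, movie.pixel_size_um) for f in movie.frames]
    rows: list[dict] = []
    next_track = 0
    active: dict[int, int] = {}  # index in per_frame[t] -> track_id
    for t, objs in enumerate(per_frame):
        if t == 0:
            assigned = {}
            for i in range(len(objs)):
                assigned[i] = next_track
                next_track += 1
        else:
            links = _mutual_nearest_links(
                per_frame[t - 1], objs, _gates(per_frame[t - 1], movie.layer, max_displacement_um)
            )
            assigned = {}
            for i_prev, j in links:
                if i_prev in active:
                    assigned[j] = active[i_prev]
            for j in range(len(objs)):
                if j not in assigned:
                    assigned[j] = next_track
                    next_track += 1
        for j, tid in assigned.items():
            rec = objs.iloc[j]
            rows.append(
                {
                    "track_id": tid,
                    "layer": movie.layer,
                    "frame": t,
                    "label_id": int(rec["label_id"]),
                    "centroid_x_um": rec["centroid_x_um"],
                    "centroid_y_um": rec["centroid_y_um"],
                    "smoothed_x_um": rec["centroid_x_um"],
                    "smoothed_y_um": rec["centroid_y_um"],
                    "area_um2": rec["area_um2"],
                }
            )
        active = assigned
    table = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return table.sort_values(["track_id", "frame"]).reset_index(drop=True)


def smooth_trajectory(
    x: np.ndarray,
    y: np.ndarray,
    t: np.ndarray | None = None,
    smoothing_param: float | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Smooth one trajectory with a cubic smoothing spline.

    ``smoothing_param`` follows the csaps convention on [0, 1]: 1 reproduces
    the input exactly (interpolation), 0 yields the least-squares line, and
    ``None`` selects the penalty by generalized cross-validation.  Tracks
    with fewer than 4 points pass through unchanged (flag ``False``).

    Returns ``(x_smooth, y_smooth, smoothed)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite coordinates")
    n = len(x)
    if t is None:
        t = np.arange(n, dtype=float)
    else:
        t = np.asarray(t, dtype=float)
    if n < 4:
        return x.copy(), y.copy(), False
    if smoothing_param is not None and not 0.0 <= smoothing_param <= 1.0:
        raise ValueError("smoothing_param must be in [0, 1]")
    if smoothing_param == 0.0:
        out = []
        for v in (x, y):
            coef = np.polyfit(t, v, 1)
            out.append(np.polyval(coef, t))
        return out[0], out[1], True
    if smoothing_param is None:
        lam = None  # GCV
    else:
        # csaps-style p: penalty weight (1-p)/p relative to the data term
        lam = (1.0 - smoothing_param) / smoothing_param
    xs = make_smoothing_spline(t, x, lam=lam)(t)
    ys = make_smoothing_spline(t, y, lam=lam)(t)
    return xs, ys, True


def smooth_tracks(
    table: pd.DataFrame, smoothing_param: float | None = None
) -> pd.DataFrame:
    """Fill ``smoothed_x_um/smoothed_y_um`` per track (cells by default).

    Smoothing is applied to cell-layer tracks; CMAC tracks pass through with
    raw centroids (membrane adhesions are short-lived and their positions are
    used for lifetime/area statistics, not motion analysis).
    """
    table = table.sort_values(["track_id", "frame"]).reset_index(drop=True)
    for tid, idx in table.groupby("track_id").groups.items():
        sub = table.loc[idx]
        if sub["layer"].iloc[0] != CELL_LAYER:
            continue
        xs, ys, _ = smooth_trajectory(
            sub["centroid_x_um"].to_numpy(),
            sub["centroid_y_um"].to_numpy(),
            sub["frame"].to_numpy(dtype=float),
            smoothing_param,
        )
        table.loc[idx, "smoothed_x_um"] = xs
        table.loc[idx, "smoothed_y_um"] = ys
    return table


@dataclass
class CmacTrackSummary:
    track_id: int
    n_frames: int
    lifetime_min: float | None
    touches_sequence_boundary: bool


def filter_cmacs(
    cmac_tracks: pd.DataFrame,
    config: AnalysisConfig,
    n_movie_frames: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply CMAC quality filters and compute per-track lifetime.

    * observations with area <= ``cmac_min_area_um2`` are removed;
    * surviving runs of consecutive frames shorter than 3 are removed
      (runs are re-labeled as separate tracks when a filter splits one);
    * ``lifetime_min = n_frames * frame_interval_min``, defined only for
      tracks absent from both the first and last frame of the sequence.

    Returns the filtered track table and a per-track summary table.
    """
    if n_movie_frames is None:
        n_movie_frames = int(cmac_tracks["frame"].max()) + 1 if len(cmac_tracks) else 0
    kept = cmac_tracks[cmac_tracks["area_um2"] > config.cmac_min_area_um2]
    out_rows = []
    summaries = []
    new_tid = 0
    for _, sub in kept.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        # split at gaps introduced by the area filter
        breaks = np.flatnonzero(np.diff(frames) != 1) + 1
        for run in np.split(np.arange(len(frames)), breaks):
            if len(run) < 3:
                continue
            piece = sub.iloc[run].copy()
            piece["track_id"] = new_tid
            touches = frames[run[0]] == 0 or frames[run[-1]] == n_movie_frames - 1
            lifetime = None if touches else len(run) * config.frame_interval_min
            summaries.append(
                {
                    "track_id": new_tid,
                    "n_frames": len(run),
                    "lifetime_min": np.nan if lifetime is None else lifetime,
                    "touches_sequence_boundary": bool(touches),
                }
            )
            out_rows.append(piece)
            new_tid += 1
    filtered = (
        pd.concat(out_rows, ignore_index=True)
        if out_rows
        else cmac_tracks.iloc[0:0].copy()
    )
    summary = pd.DataFrame(
        summaries,
        columns=["track_id", "n_frames", "lifetime_min", "touches_sequence_boundary"],
    )
    return filtered, summary
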