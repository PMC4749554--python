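"""File I/O, blinding support and mode-frequency summaries.

Movies travel as multi-page TIFF stacks (uint16 label masks, one file per
layer; intensity channels as separate stacks).  Tables travel as CSV with
fixed headers.  Two table schemas exist:

* mode-label tables: one row per (cell, frame) with a manually assigned
  migration-mode label — ``Discontinuous``, ``Continuous`` or ``null``
  (dead cells / sustained contact, excluded from analysis);
* feature tables: the same keys plus per-observation feature columns
  (see :mod:`migmode.features`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import AnalysisConfig
from .datatypes import CELL_LAYER, IntensityMovie, LabelMovie

__all__ = [
    "read_label_movie",
    "write_label_movie",
    "read_intensity_movie",
    "write_intensity_movie",
    "read_table",
    "write_table",
    "blind_randomize",
    "mode_frequencies",
    "MODE_DISCONTINUOUS",
    "MODE_CONTINUOUS",
    "MODE_NULL",
    "MODE_TABLE_COLUMNS",
]

MODE_DISCONTINUOUS = "Discontinuous"
MODE_CONTINUOUS = "Continuous"
MODE_NULL = "null"

MODE_TABLE_COLUMNS = ["cell_track_id", "frame", "mode", "condition", "repeat_id"]


class TableSchemaError(ValueError):
    """A CSV table does not match the documented schema."""


def read_label_movie(
    path: str | Path,
    meta: AnalysisConfig | None = None,
    layer: str = CELL_LAYER,
) -> LabelMovie:
    """Read a multi-page TIFF of integer label masks.

    Frames are returned in acquisition (page) order.  Mixed frame shapes or
    non-integer pixel types are format errors.
    """
    meta = meta or AnalysisConfig()
    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise ValueError(f"{path}: empty TIFF")
    shapes = {p.shape for p in pages}
    if len(shapes) > 1:
        raise ValueError(f"{path}: mixed frame shapes {sorted(shapes)}")
    stack = np.stack(pages)
    if not np.issubdtype(stack.dtype, np.integer):
        raise ValueError(f"{path}: label masks must be integer, got {stack.dtype}")
    return LabelMovie(
        frames=stack,
        pixel_size_um=meta.pixel_size_um,
        frame_interval_min=meta.frame_interval_min,
        layer=layer,
    )


def write_label_movie(path: str | Path, movie: LabelMovie) -> None:
    frames = movie.frames
    if frames.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label values exceed uint16 range")
    tifffile.imwrite(str(path), frames.astype(np.uint16), photometric="minisblack")


def read_intensity_movie(path: str | Path, channel: str = "other") -> IntensityMovie:
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    return IntensityMovie(frames=stack, channel=channel)


def write_intensity_movie(path: str | Path, movie: IntensityMovie) -> None:
    tifffile.imwrite(
        str(path), movie.frames.astype(np.float32), photometric="minisblack"
    )


def _validate_table(
    table: pd.DataFrame, required: list[str], unique_key: tuple | None
) -> pd.DataFrame:
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise TableSchemaError(f"missing required columns: {missing}")
    if unique_key is not None:
        dup = table.duplicated(subset=list(unique_key))
        if dup.any():
            keys = table.loc[dup, list(unique_key)].head().to_dict("records")
            raise TableSchemaError(f"duplicate {unique_key} keys, e.g. {keys}")
    return table


def read_table(
    path: str | Path,
    kind: str = "feature",
) -> pd.DataFrame:
    """Read a feature or mode-label CSV table, validating its schema.

    ``kind`` is ``"feature"`` or ``"mode"``.  Both require one row per
    (cell_track_id, frame).
    """
    table = pd.read_csv(path)
    if kind == "mode":
        required = MODE_TABLE_COLUMNS
    elif kind == "feature":
        required = ["cell_track_id", "frame", "condition", "repeat_id", "mode"]
    else:
        raise ValueError(f"unknown table kind {kind!r}")
    return _validate_table(table, required, ("cell_track_id", "frame"))


def write_table(path: str | Path, table: pd.DataFrame, kind: str = "feature") -> None:
    """Write a table as CSV; round-trips floats at full (repr) precision."""
    if kind == "mode":
        _validate_table(table, MODE_TABLE_COLUMNS, ("cell_track_id", "frame"))
    elif kind == "feature":
        _validate_table(
            table,
            ["cell_track_id", "frame", "condition", "repeat_id", "mode"],
            ("cell_track_id", "frame"),
        )
    table.to_csv(path, index=False)


def blind_randomize(sequence_ids: list, seed: int) -> dict:
    """Blind a set of sequence ids for unbiased manual mode classification.

    Returns a manifest with a seed-deterministic bijection from each id to an
    anonymous code and a randomized presentation order.  Condition metadata
    must not be carried into the manifest; pass bare sequence ids.
    """
    ids = list(sequence_ids)
    if not ids:
        raise ValueError("sequence_ids is empty")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    rng = np.random.default_rng(seed)
    # codes assigned in shuffled order so the code does not leak input order
    order = rng.permutation(len(ids))
    width = max(4, len(str(len(ids))))
    code_map = {
        ids[idx]: f"BLIND-{rank:0{width}d}" for rank, idx in enumerate(order, start=1)
    }
    presentation = [code_map[ids[idx]] for idx in rng.permutation(len(ids))]
    return {"seed": seed, "code_map": code_map, "presentation_order": presentation}


def mode_frequencies(labels: pd.DataFrame, group_by: str = "condition") -> pd.DataFrame:
    """Per-group fractions of Discontinuous/Continuous observations.

    Null observations are excluded from the denominator.  Groups with zero
    non-null observations get NaN fractions and ``undefined=True`` rather
    than a 0/0.
    """
    _validate_table(labels, ["mode", group_by], None)
    rows = []
    for group, sub in labels.groupby(group_by, sort=True):
        modes = sub["mode"].astype(str).str.strip()
        n_disc = int((modes == MODE_DISCONTINUOUS).sum())
        n_cont = int((modes == MODE_CONTINUOUS).sum())
        n = n_disc + n_cont
        rows.append(
            {
                group_by: group,
                "n_observations": n,
                "frac_discontinuous": n_disc / n if n else np.nan,
                "frac_continuous": n_cont / n if n else np.nan,
                "undefined": n == 0,
            }
        )
    return pd.DataFrame(rows)
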