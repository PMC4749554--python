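"""Membrane protrusion/retraction dynamics.

Protrusions are the pixels a cell segment gains between two frames, and
retractions the pixels it loses; both converted to µm².  Comparing frames
separated by window sizes of 1–15 frames (5–75 min at the default interval)
probes net shape/position changes on different timescales using the same
criteria as the single-frame window.

The temporal coordination of protrusion and retraction is measured by a
lagged cross-correlation per cell: at lag k the protrusion series shifted by
k frames is correlated with the retraction series, so *negative* lags mean
protrusion leads retraction and positive lags mean retraction leads
protrusion.  Lags of −12..+12 frames (±60 min) are assessed.  Missing values
are replaced by the trajectory mean before computation.  Each lag is
normalized on the overlapping segments (a per-lag correlation coefficient),
so values are bounded by 1 in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "protrusion_retraction",
    "multiwindow_series",
    "SizeDistribution",
    "size_probability_distribution",
    "distribution_difference",
    "default_bin_edges",
    "XcovProfile",
    "protrusion_retraction_xcov",
    "mean_abs_xcov_summary",
    "friedman_mode_comparison",
]


def protrusion_retraction(
    mask_a: np.ndarray, mask_b: np.ndarray, pixel_size_um: float
) -> tuple[float, float]:
    """Protrusion and retraction area (µm²) between two masks of one cell.

    Protrusion = pixels in B but not A; retraction = pixels in A but not B.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    pa = pixel_size_um**2
    protrusion = int((b & ~a).sum()) * pa
    retraction = int((a & ~b).sum()) * pa
    return protrusion, retraction


def multiwindow_series(
    masks: list,
    pixel_size_um: float,
    windows: tuple = tuple(range(1, 16)),
    cell_track_id: int | None = None,
) -> pd.DataFrame:
    """Protrusion/retraction event series for every window size.

    ``masks`` are the cell masks of one track in frame order.  For window w
    the event at start frame t compares masks t and t+w; the series has
    ``len(masks) - w`` entries.  Windows longer than the track yield no rows.
    """
    rows = []
    n = len(masks)
    for w in windows:
        for t in range(n - w):
            p, r = protrusion_retraction(masks[t], masks[t + w], pixel_size_um)
            rows.append(
                {
                    "cell_track_id": cell_track_id,
                    "window_frames": w,
                    "start_frame": t,
                    "protrusion_area_um2": p,
                    "retraction_area_um2": r,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_track_id",
            "window_frames",
            "start_frame",
            "protrusion_area_um2",
            "retraction_area_um2",
        ],
    )


@dataclass
class SizeDistribution:
    """Event-size probability distribution on shared bins (µm²)."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)


def default_bin_edges(pooled_events: np.ndarray, width_um2: float = 1.0) -> np.ndarray:
    """Fixed-width bins from 0 to the 99.5th percentile of pooled events."""
    pooled = np.asarray(pooled_events, dtype=float)
    top = np.percentile(pooled, 99.5) if pooled.size else width_um2
    top = max(top, width_um2)
    return np.arange(0.0, top + width_um2, width_um2)


def size_probability_distribution(
    events: np.ndarray, bin_edges: np.ndarray
) -> SizeDistribution:
    """Histogram of event sizes normalized to probabilities.

    Events below/above the outermost edges are counted into the first/last
    (open-ended) bin.
    """
    events = np.asarray(events, dtype=float)
    events = events[np.isfinite(events)]
    if events.size == 0:
        raise ValueError("no events")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 entries")
    clipped = np.clip(events, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return SizeDistribution(edges, counts / counts.sum())


def distribution_difference(p: SizeDistribution, q: SizeDistribution) -> np.ndarray:
    """Per-bin probability difference P − Q (sums to 0); shared bins required."""
    if p.bin_edges.shape != q.bin_edges.shape or not np.allclose(
        p.bin_edges, q.bin_edges
    ):
        raise ValueError("distributions must share identical bin edges")
    return p.probabilities - q.probabilities


@dataclass
class XcovProfile:
    """Lagged protrusion–retraction cross-correlation of one cell."""

    cell_track_id: int | None
    window_frames: int
    lags: np.ndarray
    values: np.ndarray
    flagged: bool = False

    def mean_abs(self) -> float:
        return float(np.nanmean(np.abs(self.values)))


def _impute_mean(series: np.ndarray) -> np.ndarray:
    s = np.asarray(series, dtype=float).copy()
    bad = ~np.isfinite(s)
    if bad.all():
        raise ValueError("series is entirely missing")
    if bad.any():
        s[bad] = s[~bad].mean()
    return s


def protrusion_retraction_xcov(
    protrusion: np.ndarray,
    retraction: np.ndarray,
    max_lag: int = 12,
    cell_track_id: int | None = None,
    window_frames: int = 1,
) -> XcovProfile:
    """Cross-correlation of protrusion vs retraction at lags −max_lag..+max_lag.

    At lag k the pairs are (protrusion(t+k), retraction(t)) over the
    overlapping range, mean-removed and normalized per lag, so a retraction
    series that simply repeats the protrusion series one frame later peaks at
    lag −1 with value 1.  Constant (zero-variance) series yield a flagged
    all-NaN profile.
    """
    p = _impute_mean(protrusion)
    r = _impute_mean(retraction)
    if len(p) != len(r):
        raise ValueError("series lengths differ")
    n = len(p)
    lags = np.arange(-max_lag, max_lag + 1)
    values = np.full(lags.shape, np.nan)
    if np.ptp(p) == 0 or np.ptp(r) == 0 or n < 2:
        return XcovProfile(cell_track_id, window_frames, lags, values, flagged=True)
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = p[k:], r[: n - k]
        else:
            a, b = p[: n + k], r[-k:]
        if len(a) >= 2 and np.ptp(a) > 0 and np.ptp(b) > 0:
            ac = a - a.mean()
            bc = b - b.mean()
            values[i] = float(
                (ac * bc).sum() / np.sqrt((ac**2).sum() * (bc**2).sum())
            )
    return XcovProfile(cell_track_id, window_frames, lags, values, flagged=False)


def mean_abs_xcov_summary(profiles: list) -> pd.DataFrame:
    """Mean absolute cross-correlation per window with a 95% CI over cells.

    Each cell contributes, per window, the mean of |values| over all lags;
    cells are weighted equally.  The CI is the t-based 95% interval of the
    per-cell means (NaN with a single cell, width 0 for identical cells).
    """
    rows = [
        {
            "cell_track_id": pr.cell_track_id,
            "window_frames": pr.window_frames,
            "mean_abs_xcov": pr.mean_abs(),
        }
        for pr in profiles
        if not pr.flagged
    ]
    per_cell = pd.DataFrame(rows)
    out = []
    for w, sub in per_cell.groupby("window_frames"):
        vals = sub["mean_abs_xcov"].to_numpy()
        n = len(vals)
        mean = float(vals.mean())
        if n > 1:
            sem = vals.std(ddof=1) / np.sqrt(n)
            half = float(stats.t.ppf(0.975, n - 1) * sem)
            lo, hi = mean - half, mean + half
        else:
            lo = hi = np.nan
        out.append(
            {
                "window_frames": w,
                "n_cells": n,
                "mean_abs_xcov": mean,
                "ci95_low": lo,
                "ci95_high": hi,
            }
        )
    return pd.DataFrame(out)


def friedman_mode_comparison(values: np.ndarray) -> tuple[float, float]:
    """Friedman test across blocks (rows) and treatments (columns).

    Intended layout: blocks = the sampled time-window sizes, treatments = the
    migration modes, one summary value per (window, mode).  Uses the
    chi-square statistic with tie correction; supports two treatments (where
    generic implementations often require three).  Fully tied data give
    statistic 0 and p = 1.
    """
    data = np.asarray(values, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a blocks x treatments matrix")
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 blocks")
    if k < 2:
        raise ValueError("need at least 2 treatments")
    ranks = stats.rankdata(data, axis=1)
    rj = ranks.sum(axis=0)
    chi = 12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3.0 * n * (k + 1)
    # tie correction: sum of (t^3 - t) over tie groups in each block
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = 1.0 - ties / (n * k * (k**2 - 1))
    statistic = 0.0 if denom <= 0 else chi / denom
    p = float(stats.chi2.sf(statistic, k - 1))
    return float(statistic), p
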