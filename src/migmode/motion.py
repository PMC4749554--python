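"""Cell motion: instantaneous speed, moving-window MSD and the Furth fit.

Cell translocation is characterized by the instantaneous speed of the
(smoothed) centroid and by mean squared displacement (MSD) profiles computed
in a moving window along each trajectory (default 24 frames = 2 h).  The
first 12 time lags (up to 1 h at 5-min framing) of each profile are fitted to
the persistent-random-walk MSD of Furth,

    MSD(t) = 4 M (t − t_p (1 − exp(−t / t_p))),

yielding a migration coefficient M (µm²/min, the long-time diffusion-like
scale) and a persistence time t_p (min, the directional memory) per window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "instantaneous_speed",
    "msd_moving_window",
    "furth_msd",
    "FurthFit",
    "fit_furth",
    "bin_by_quantile",
]


def instantaneous_speed(
    x_um: np.ndarray, y_um: np.ndarray, frame_interval_min: float
) -> np.ndarray:
    """Frame-to-frame speed (µm/min); entry t covers the step t -> t+1.

    Divide by 60 for µm/s display units.  A single-frame track yields an
    empty array.
    """
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    if len(x) < 2:
        return np.empty(0)
    return np.hypot(np.diff(x), np.diff(y)) / frame_interval_min


def msd_moving_window(
    x_um: np.ndarray,
    y_um: np.ndarray,
    window: int = 24,
    max_lag: int = 12,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Moving-window MSD profiles along one trajectory.

    For each window position the MSD at lag k (k = 1..max_lag, in frames)
    averages the squared displacement over *all* in-window pairs (t, t+k).
    Windows are centered on the reported frame; truncated windows at the
    track ends are dropped.  ``stride`` subsamples window positions (default
    1 = every position).

    Returns ``(center_frames, msd)`` with ``msd`` of shape
    ``(n_windows, max_lag)`` in µm²; both empty when the track is shorter
    than the window.
    """
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    n = len(x)
    if window < max_lag + 1:
        raise ValueError("window must exceed max_lag")
    if n < window:
        return np.empty(0, dtype=int), np.empty((0, max_lag))
    starts = np.arange(0, n - window + 1, stride)
    centers = starts + window // 2
    msd = np.empty((len(starts), max_lag))
    for k in range(1, max_lag + 1):
        d2 = (x[k:] - x[:-k]) ** 2 + (y[k:] - y[:-k]) ** 2  # length n-k
        # mean over the window-k pairs starting inside each window
        csum = np.concatenate([[0.0], np.cumsum(d2)])
        npairs = window - k
        msd[:, k - 1] = (csum[starts + npairs] - csum[starts]) / npairs
    return centers, msd


def furth_msd(t: np.ndarray, m: float, t_p: float) -> np.ndarray:
    """Persistent-random-walk MSD: 4M(t − t_p(1 − e^{−t/t_p}))."""
    t = np.asarray(t, dtype=float)
    if t_p < 1e-12:
        return 4.0 * m * t
    return 4.0 * m * (t - t_p * (1.0 - np.exp(-t / t_p)))


@dataclass
class FurthFit:
    """Fitted Furth-model parameters for one MSD profile."""

    m: float  # migration coefficient, µm²/min
    t_p: float  # persistence time, min
    residual_norm: float
    converged: bool


def fit_furth(
    lags_min: np.ndarray,
    msd_um2: np.ndarray,
    n_frames: int | None = None,
    n_starts: int = 3,
) -> FurthFit:
    """Nonlinear least-squares Furth fit of one MSD profile.

    Bounds M, t_p >= 0.  Initialization: M from the terminal slope / 4 and
    t_p at two frame intervals, with additional starts on failure.  A fit
    that never converges is returned flagged (``converged=False``).

    When ``n_frames`` (the length of the trajectory segment the profile was
    averaged over) is given, lags are weighted by the standard sampling
    variance of a time-averaged MSD, var ∝ MSD²·(2k²+1)/(3k(n−k+1)) for lag
    k frames; without it the fit is unweighted.  Weighting matters because
    long-lag MSD values are strongly correlated and noisy, and would
    otherwise dominate the fit.
    """
    t = np.asarray(lags_min, dtype=float)
    y = np.asarray(msd_um2, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 positive-lag points")
    sigma = None
    if n_frames is not None and np.all(y > 0):
        k = np.arange(1, len(y) + 1, dtype=float)
        sigma = y * np.sqrt((2 * k**2 + 1) / (3 * k * (n_frames - k + 1)))
    slope = max((y[-1] - y[-2]) / (t[-1] - t[-2]), 1e-12)
    dt = t[1] - t[0]
    starts = [(slope / 4.0, 2.0 * dt)]
    for mult in (0.2, 5.0):
        starts.append((slope / 4.0 * mult, 2.0 * dt / mult))
    best = None
    for m0, tp0 in starts[:n_starts]:
        try:
            popt, _ = curve_fit(
                furth_msd,
                t,
                y,
                p0=[m0, tp0],
                sigma=sigma,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=2000,
            )
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(furth_msd(t, *popt) - y))
        if best is None or resid < best.residual_norm:
            best = FurthFit(float(popt[0]), float(popt[1]), resid, True)
    if best is None:
        return FurthFit(np.nan, np.nan, np.nan, False)
    return best


def bin_by_quantile(
    values: np.ndarray,
    k: int = 5,
    companion: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Assign values to k equal-probability bins (quintiles, tertiles, ...).

    Bin edges sit at the i/k empirical quantiles (linear interpolation).
    Returns ``(bin_index, edges, summary)`` where the summary holds, per bin,
    the count and — when a companion variable is given — its median and notch
    interval (median ± 1.57·IQR/√n).  Empty bins caused by heavy ties are
    flagged in the summary.
    """
    from .mvstats import notch_summary

    vals = np.asarray(values, dtype=float)
    if len(vals) < k:
        raise ValueError(f"need at least k={k} values")
    edges = np.quantile(vals, np.linspace(0, 1, k + 1))
    idx = np.clip(np.searchsorted(edges[1:-1], vals, side="right"), 0, k - 1)
    rows = []
    for b in range(k):
        sel = idx == b
        row = {"bin": b, "n": int(sel.sum()), "empty": not sel.any()}
        if companion is not None and sel.any():
            comp = np.asarray(companion, dtype=float)[sel]
            comp = comp[np.isfinite(comp)]
            if comp.size:
                ns = notch_summary(comp)
                row.update(
                    {
                        "companion_median": ns.median,
                        "notch_low": ns.notch_low,
                        "notch_high": ns.notch_high,
                    }
                )
        rows.append(row)
    return idx, edges, pd.DataFrame(rows)
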