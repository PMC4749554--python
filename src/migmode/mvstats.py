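"""Multivariate and univariate statistics for single-cell feature tables.

Canonical variates analysis (CVA) projects observations onto directions
maximizing between-group relative to within-group covariance (eigenvectors of
W⁻¹B); the first canonical vector's absolute coefficients rank features by
their contribution to group separation.  PCA uses SVD of the z-scored data
matrix.  Feature co-variation is summarized by Spearman rank-correlation
matrices; correlation differences between groups are judged against a
permutation null built by shuffling the pair identity of one matrix's values
while holding the other fixed.  Probability surfaces over a two-component
score space use Gaussian kernel density estimation.  Univariate comparisons
use the Wilcoxon rank-sum test and notched median summaries
(median ± 1.57·IQR/√n, an approximate 95% CI of the median).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "spearman_matrix",
    "correlation_difference_with_permutation",
    "CvaModel",
    "cva_fit",
    "cva_separation",
    "PcaModel",
    "pca_fit",
    "DensitySurface",
    "kde2d_surface",
    "NotchSummary",
    "notch_summary",
    "wilcoxon_rank_sum",
    "speed_correlation_catalogue",
]


# ---------------------------------------------------------------- Spearman


def spearman_matrix(table: pd.DataFrame, features: list | None = None) -> pd.DataFrame:
    """Pairwise-complete Spearman rank correlation matrix (average-rank ties).

    Pairs with fewer than 3 complete observations and constant features come
    back NaN (flagged undefined).
    """
    data = table[features] if features is not None else table
    data = data.astype(float)
    rs = data.corr(method="spearman", min_periods=3)
    counts = data.notna().astype(int)
    n = counts.T @ counts
    rs.attrs["pair_n"] = n
    return rs


def correlation_difference_with_permutation(
    a: pd.DataFrame,
    b: pd.DataFrame,
    n_perm: int = 100,
    seed: int | None = None,
) -> dict:
    """Observed |A − B| correlation differences and their permutation null.

    A and B are correlation matrices over the same ordered feature set.  The
    null shuffles which feature-pair identity each off-diagonal value of A
    belongs to while holding B fixed, recomputes |A_perm − B|, and pools the
    differences over ``n_perm`` permutations.  Returns observed and permuted
    difference samples plus their empirical CDF supports (sorted values).
    """
    if list(a.columns) != list(b.columns):
        raise ValueError("correlation matrices must share the same ordered features")
    av = a.to_numpy()
    bv = b.to_numpy()
    iu = np.triu_indices(av.shape[0], k=1)
    a_vals = av[iu]
    b_vals = bv[iu]
    observed = np.abs(a_vals - b_vals)
    rng = np.random.default_rng(seed)
    permuted = np.concatenate(
        [np.abs(rng.permutation(a_vals) - b_vals) for _ in range(n_perm)]
    )
    return {
        "observed": observed,
        "permuted": permuted,
        "observed_cdf_support": np.sort(observed),
        "permuted_cdf_support": np.sort(permuted),
    }


# --------------------------------------------------------------------- CVA


@dataclass
class CvaModel:
    """Canonical variates model: vectors, variance fractions, scores."""

    features: list
    canonical_vectors: np.ndarray  # (n_features, n_cv)
    variance_fractions: np.ndarray
    scores: np.ndarray  # (n_obs, n_cv)
    groups: np.ndarray
    group_centers: dict  # group -> center of mass in CV space
    feature_means: np.ndarray = field(repr=False, default=None)
    feature_stds: np.ndarray = field(repr=False, default=None)

    def cv1_ranking(self) -> pd.DataFrame:
        """Features ranked by |coefficient| in the first canonical vector."""
        coef = self.canonical_vectors[:, 0]
        out = pd.DataFrame(
            {"feature": self.features, "cv1_coefficient": coef,
             "abs_coefficient": np.abs(coef)}
        )
        return out.sort_values("abs_coefficient", ascending=False).reset_index(
            drop=True
        )


def _prepare_matrix(
    table: pd.DataFrame, features: list, max_missing_frac: float = 0.2
) -> tuple[np.ndarray, list, np.ndarray]:
    data = table[features].astype(float)
    frac_missing = data.isna().mean()
    dropped = list(frac_missing[frac_missing > max_missing_frac].index)
    if dropped:
        warnings.warn(
            f"excluding features with >{max_missing_frac:.0%} missing: {dropped}"
        )
        data = data.drop(columns=dropped)
    keep = data.notna().all(axis=1).to_numpy()
    return data.to_numpy()[keep], list(data.columns), keep


def cva_fit(
    table: pd.DataFrame,
    features: list,
    group_col: str = "mode",
    ridge: float | None = None,
    standardize: bool = True,
) -> CvaModel:
    """Fit canonical variates analysis on a feature table.

    Rows with any missing selected feature are dropped (complete-case);
    features missing in >20% of rows are excluded with a warning.  Features
    are z-scored, the pooled within-group covariance W is ridge-regularized
    (default λ = 1e-6·trace(W)/p), and the canonical vectors solve the
    generalized eigenproblem B v = λ W v sorted by decreasing λ, retaining
    min(groups − 1, features) vectors.  Variance fractions are λ_i/Σλ.
    """
    x, feats, keep = _prepare_matrix(table, features)
    groups = table[group_col].to_numpy()[keep]
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [f for f, s in zip(feats, sd) if s == 0]
            raise ValueError(f"zero-variance features: {bad}")
        x = (x - mu) / sd
    else:
        mu = np.zeros(x.shape[1])
        sd = np.ones(x.shape[1])
    n, p = x.shape
    g = len(uniq)
    grand = x.mean(axis=0)
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    for u in uniq:
        xg = x[groups == u]
        mg = xg.mean(axis=0)
        w += (xg - mg).T @ (xg - mg)
        d = (mg - grand)[:, None]
        b += len(xg) * (d @ d.T)
    w /= n - g
    b /= g - 1
    lam = ridge if ridge is not None else 1e-6 * np.trace(w) / p
    w_reg = w + lam * np.eye(p)
    try:
        evals, evecs = linalg.eigh(b, w_reg)
    except linalg.LinAlgError as err:
        raise ValueError(
            "singular within-group covariance; increase the ridge parameter"
        ) from err
    order = np.argsort(evals)[::-1]
    n_cv = min(g - 1, p)
    evals = np.clip(evals[order][:n_cv], 0, None)
    vectors = evecs[:, order][:, :n_cv]
    # sign convention: largest-|coefficient| entry positive
    for j in range(n_cv):
        i = np.argmax(np.abs(vectors[:, j]))
        if vectors[i, j] < 0:
            vectors[:, j] = -vectors[:, j]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.full(n_cv, np.nan)
    scores = x @ vectors
    centers = {u: scores[groups == u].mean(axis=0) for u in uniq}
    return CvaModel(
        features=feats,
        canonical_vectors=vectors,
        variance_fractions=fractions,
        scores=scores,
        groups=groups,
        group_centers=centers,
        feature_means=mu,
        feature_stds=sd,
    )


def cva_separation(model: CvaModel) -> float:
    """Fraction of observations nearest (Euclidean, CV space) to their own
    group's center of mass."""
    centers = np.stack([model.group_centers[u] for u in model.group_centers])
    names = list(model.group_centers)
    d = np.linalg.norm(model.scores[:, None, :] - centers[None, :, :], axis=2)
    nearest = np.asarray(names, dtype=object)[d.argmin(axis=1)]
    return float((nearest == model.groups).mean())


# --------------------------------------------------------------------- PCA


@dataclass
class PcaModel:
    features: list
    loadings: np.ndarray  # (n_features, n_pc), orthonormal columns
    variance_fractions: np.ndarray
    scores: np.ndarray


def pca_fit(table: pd.DataFrame, features: list | None = None) -> PcaModel:
    """PCA via SVD of the z-scored (normalized) data matrix, complete-case."""
    if features is None:
        features = [c for c in table.columns if table[c].dtype.kind in "fi"]
    x, feats, _ = _prepare_matrix(table, features)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [f for f, s in zip(feats, sd) if s == 0]
        raise ValueError(f"zero-variance features: {bad}")
    xz = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(xz, full_matrices=False)
    var = s**2 / (len(xz) - 1)
    return PcaModel(
        features=feats,
        loadings=vt.T,
        variance_fractions=var / var.sum(),
        scores=u * s,
    )


# --------------------------------------------------------------------- KDE


@dataclass
class DensitySurface:
    """Probability mass on a regular grid over two score axes (sums to 1)."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    mass: np.ndarray  # (ny, nx)
    bandwidth_factor: float
    flagged: bool = False


def kde2d_surface(
    points: np.ndarray,
    bandwidth_factor: float = 0.5,
    grid_size: int = 128,
    padding_bw: float = 3.0,
) -> DensitySurface:
    """Gaussian-KDE probability surface over two component axes.

    The kernel bandwidth is Silverman's rule scaled by ``bandwidth_factor``
    (default 0.5 — deliberately smaller than the overall group spread so the
    surface reflects the value distribution rather than the kernel).  Mass on
    the grid is normalized to sum to 1.  Degenerate (collinear) point sets
    are flagged.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 10:
        raise ValueError("need at least 10 points")
    if np.linalg.matrix_rank(np.cov(pts.T)) < 2:
        x = np.unique(pts[:, 0])
        return DensitySurface(x, x, np.full((len(x), len(x)), np.nan),
                              bandwidth_factor, flagged=True)
    kde = stats.gaussian_kde(pts.T, bw_method="silverman")
    kde.set_bandwidth(kde.factor * bandwidth_factor)
    sd = pts.std(axis=0, ddof=1)
    pad = padding_bw * kde.factor * sd
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    xc = np.linspace(lo[0], hi[0], grid_size)
    yc = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(xc, yc)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    cell = (xc[1] - xc[0]) * (yc[1] - yc[0])
    mass = dens * cell
    mass /= mass.sum()
    return DensitySurface(xc, yc, mass, bandwidth_factor)


# --------------------------------------------------------- univariate stats


@dataclass
class NotchSummary:
    """Median with its approximate 95% CI: median ± 1.57·IQR/√n."""

    median: float
    iqr: float
    n: int
    notch_low: float
    notch_high: float


def notch_summary(values: np.ndarray) -> NotchSummary:
    """Median, IQR (linear-interpolation quantiles) and notch interval."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty sample")
    med = float(np.median(vals))
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = float(q3 - q1)
    half = 1.57 * iqr / np.sqrt(len(vals))
    return NotchSummary(med, iqr, len(vals), med - half, med + half)


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration for small tie-free samples, normal approximation with
    tie correction otherwise; fully tied data give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def speed_correlation_catalogue(
    table: pd.DataFrame,
    features: list,
    speed_col: str = "cell_speed_um_per_min",
    mode_col: str = "mode",
    cell_col: str = "cell_track_id",
    min_timepoints: int = 8,
) -> tuple[pd.DataFrame, dict]:
    """Per-mode median within-cell Spearman correlation of features to speed.

    For each cell with at least ``min_timepoints`` complete observations the
    Spearman rs between each feature and speed is computed along the
    trajectory; the per-mode summary is the median over cells, called
    non-significant (ns) when 0 falls inside the notch interval of the
    per-cell rs values.  Feature classes compare the two modes:
    ``both_positive``, ``both_negative``, ``one_mode_only``, ``inverted``
    (significant with opposite signs) or ``ns``.

    Returns the catalogue table and a dict of skipped-cell counts per mode.
    """
    modes = sorted(table[mode_col].dropna().unique())
    if len(modes) != 2:
        raise ValueError(f"expected exactly 2 modes, got {modes}")
    per_mode: dict = {m: {} for m in modes}
    skipped = {m: 0 for m in modes}
    for (mode, _), sub in table.groupby([mode_col, cell_col]):
        ok = sub[[speed_col]].notna().to_numpy().ravel()
        if ok.sum() < min_timepoints:
            skipped[mode] += 1
            continue
        for f in features:
            pair = sub[[f, speed_col]].dropna()
            if len(pair) < min_timepoints:
                continue
            rs = stats.spearmanr(pair[f], pair[speed_col]).statistic
            if np.isfinite(rs):
                per_mode[mode].setdefault(f, []).append(rs)
    rows = []
    for f in features:
        rec: dict = {"feature": f}
        signs = {}
        for m in modes:
            vals = np.asarray(per_mode[m].get(f, []), dtype=float)
            if vals.size == 0:
                rec[f"rs_median_{m}"] = np.nan
                rec[f"significant_{m}"] = False
                signs[m] = 0
                continue
            ns = notch_summary(vals)
            sig = not (ns.notch_low <= 0 <= ns.notch_high)
            rec[f"rs_median_{m}"] = ns.median
            rec[f"significant_{m}"] = sig
            signs[m] = int(np.sign(ns.median)) if sig else 0
        s = [signs[m] for m in modes]
        if s[0] > 0 and s[1] > 0:
            cls = "both_positive"
        elif s[0] < 0 and s[1] < 0:
            cls = "both_negative"
        elif s[0] * s[1] < 0:
            cls = "inverted"
        elif s[0] != 0 or s[1] != 0:
            cls = "one_mode_only"
        else:
            cls = "ns"
        rec["class"] = cls
        rows.append(rec)
    return pd.DataFrame(rows), skipped
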