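import numpy as np
import pandas as pd
import pytest
from scipy import stats

from migmode import mvstats, synthetic


class TestSpearmanMatrix:
    def test_self_correlation_is_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        rs = mvstats.spearman_matrix(df)
        np.testing.assert_allclose(np.diag(rs), 1.0)

    def test_monotone_transform_invariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 2)), columns=["u", "v"])
        rs1 = mvstats.spearman_matrix(df).loc["u", "v"]
        df2 = pd.DataFrame({"u": np.exp(df["u"]), "v": df["v"] ** 3})
        rs2 = mvstats.spearman_matrix(df2).loc["u", "v"]
        assert rs1 == pytest.approx(rs2, abs=1e-12)

    def test_rank_then_pearson_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        df.iloc[2, 0] = df.iloc[3, 0]  # introduce a tie
        rs = mvstats.spearman_matrix(df)
        ranks = df.rank()
        oracle = np.corrcoef(ranks.to_numpy().T)
        np.testing.assert_allclose(rs.to_numpy(), oracle, atol=1e-12)

    def test_pairwise_complete_and_counts(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 2)), columns=["u", "v"])
        df.loc[:4, "u"] = np.nan
        rs = mvstats.spearman_matrix(df)
        sub = df.dropna()
        expected = stats.spearmanr(sub["u"], sub["v"]).statistic
        assert rs.loc["u", "v"] == pytest.approx(expected)
        assert rs.attrs["pair_n"].loc["u", "v"] == 15

    def test_constant_feature_undefined(self):
        df = pd.DataFrame({"u": [1.0, 1.0, 1.0, 1.0], "v": [1.0, 2.0, 3.0, 4.0]})
        rs = mvstats.spearman_matrix(df)
        assert np.isnan(rs.loc["u", "v"])


class TestCorrelationPermutation:
    @staticmethod
    def _mat(values, names):
        m = np.eye(len(names))
        iu = np.triu_indices(len(names), 1)
        m[iu] = values
        m.T[iu] = values
        return pd.DataFrame(m, index=names, columns=names)

    def test_identical_matrices_observed_dominates_null(self, rng):
        names = list("abcd")
        a = self._mat(rng.uniform(-1, 1, 6), names)
        out = mvstats.correlation_difference_with_permutation(a, a, 50, seed=0)
        assert (out["observed"] == 0).all()
        # observed CDF (step at 0) lies above the permuted CDF everywhere
        assert np.mean(out["permuted"] > 0) > 0

    def test_seed_reproducibility(self, rng):
        names = list("abcd")
        a = self._mat(rng.uniform(-1, 1, 6), names)
        b = self._mat(rng.uniform(-1, 1, 6), names)
        o1 = mvstats.correlation_difference_with_permutation(a, b, 20, seed=42)
        o2 = mvstats.correlation_difference_with_permutation(a, b, 20, seed=42)
        np.testing.assert_array_equal(o1["permuted"], o2["permuted"])

    def test_enumeration_oracle(self):
        names = list("abcd")
        a_vals = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        b_vals = np.array([0.0, 0.1, 0.0, 0.1, 0.0, 0.1])
        a, b = self._mat(a_vals, names), self._mat(b_vals, names)
        out = mvstats.correlation_difference_with_permutation(a, b, 2, seed=7)
        rng = np.random.default_rng(7)
        expected = np.concatenate(
            [np.abs(rng.permutation(a_vals) - b_vals) for _ in range(2)]
        )
        np.testing.assert_allclose(out["permuted"], expected)

    def test_mismatched_features_rejected(self):
        a = self._mat([0.5], ["x", "y"])
        b = self._mat([0.5], ["x", "z"])
        with pytest.raises(ValueError, match="same ordered features"):
            mvstats.correlation_difference_with_permutation(a, b, 2)


class TestCva:
    @staticmethod
    def _two_gaussians(rng, n=300, p=4, delta=(3.0, 0, 0, 0)):
        x0 = rng.normal(size=(n, p))
        x1 = rng.normal(size=(n, p)) + np.asarray(delta)
        df = pd.DataFrame(np.vstack([x0, x1]), columns=[f"f{i}" for i in range(p)])
        df["mode"] = ["A"] * n + ["B"] * n
        return df

    def test_identity_within_cov_gives_mean_difference_direction(self, rng):
        df = self._two_gaussians(rng, n=2000, delta=(2.0, 1.0, 0.0, 0.0))
        feats = [f"f{i}" for i in range(4)]
        model = mvstats.cva_fit(df, feats, standardize=False)
        v = model.canonical_vectors[:, 0]
        mu_diff = (
            df[df["mode"] == "B"][feats].mean() - df[df["mode"] == "A"][feats].mean()
        ).to_numpy()
        cos = abs(v @ mu_diff) / (np.linalg.norm(v) * np.linalg.norm(mu_diff))
        assert cos == pytest.approx(1.0, abs=0.01)

    def test_matches_fisher_lda_direction(self, rng):
        # oracle: closed-form Fisher direction W^{-1}(mu1 - mu0) on z-scored data
        df = self._two_gaussians(rng, n=150)
        feats = [f"f{i}" for i in range(4)]
        model = mvstats.cva_fit(df, feats, ridge=0.0)
        x = df[feats].to_numpy()
        xz = (x - x.mean(0)) / x.std(0, ddof=1)
        g = (df["mode"] == "B").to_numpy()
        mu0, mu1 = xz[~g].mean(0), xz[g].mean(0)
        n0, n1 = (~g).sum(), g.sum()
        w = (
            (xz[~g] - mu0).T @ (xz[~g] - mu0) + (xz[g] - mu1).T @ (xz[g] - mu1)
        ) / (len(xz) - 2)
        fisher = np.linalg.solve(w, mu1 - mu0)
        v = model.canonical_vectors[:, 0]
        cos = abs(v @ fisher) / (np.linalg.norm(v) * np.linalg.norm(fisher))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_number_of_cvs_is_groups_minus_one(self, rng):
        df = self._two_gaussians(rng, n=100)
        df.loc[df.sample(60, random_state=0).index, "mode"] = "C"
        model = mvstats.cva_fit(df, [f"f{i}" for i in range(4)])
        assert model.canonical_vectors.shape[1] == 2
        assert model.variance_fractions.sum() == pytest.approx(1.0)

    def test_separated_clouds_rank_and_variance(self, rng):
        df = self._two_gaussians(rng, n=500, delta=(4.0, 0, 0, 0))
        model = mvstats.cva_fit(df, [f"f{i}" for i in range(4)])
        assert model.cv1_ranking()["feature"].iloc[0] == "f0"
        assert model.variance_fractions[0] > 0.99
        assert mvstats.cva_separation(model) > 0.95

    def test_affine_rescaling_invariance_of_scores(self, rng):
        df = self._two_gaussians(rng, n=200)
        feats = [f"f{i}" for i in range(4)]
        m1 = mvstats.cva_fit(df, feats)
        df2 = df.copy()
        df2["f1"] = df2["f1"] * 7.0 - 3.0
        m2 = mvstats.cva_fit(df2, feats)
        np.testing.assert_allclose(
            np.abs(m1.scores[:, 0]), np.abs(m2.scores[:, 0]), atol=1e-8
        )

    def test_single_group_rejected(self, rng):
        df = self._two_gaussians(rng, n=20)
        df["mode"] = "A"
        with pytest.raises(ValueError, match="2 groups"):
            mvstats.cva_fit(df, [f"f{i}" for i in range(4)])


class TestPca:
    def test_orthonormal_loadings_and_variance_fractions(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        model = mvstats.pca_fit(df)
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(5), atol=1e-10
        )
        assert model.variance_fractions.sum() == pytest.approx(1.0)

    def test_correlated_pair_closed_form_variance(self, rng):
        # 2 features with correlation rho: PC1 fraction = (1+rho)/2
        rho = 0.8
        n = 50000
        z = rng.normal(size=(n, 2))
        x = z[:, 0]
        y = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
        model = mvstats.pca_fit(pd.DataFrame({"x": x, "y": y}))
        assert model.variance_fractions[0] == pytest.approx((1 + rho) / 2, abs=0.01)

    def test_zero_variance_feature_named(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        with pytest.raises(ValueError, match="b"):
            mvstats.pca_fit(df)


class TestKde:
    def test_grid_mass_sums_to_one(self, rng):
        pts = rng.normal(size=(200, 2))
        surf = mvstats.kde2d_surface(pts)
        assert surf.mass.sum() == pytest.approx(1.0, abs=1e-3)

    def test_mirror_symmetric_points_give_symmetric_surface(self, rng):
        half = rng.normal(size=(100, 2)) + [2.0, 0.0]
        pts = np.vstack([half, half * [-1, 1]])
        surf = mvstats.kde2d_surface(pts, grid_size=64)
        np.testing.assert_allclose(surf.mass, surf.mass[:, ::-1], atol=1e-10)

    def test_matches_analytic_mixture_density(self, rng):
        # two well-separated unit Gaussians, large n
        n = 20000
        comp = rng.random(n) < 0.5
        pts = rng.normal(size=(n, 2))
        pts[comp] += [3.0, 0.0]
        pts[~comp] -= [3.0, 0.0]
        surf = mvstats.kde2d_surface(pts, grid_size=80)
        xx, yy = np.meshgrid(surf.x_centers, surf.y_centers)

        def gauss(cx):
            return np.exp(-((xx - cx) ** 2 + yy**2) / 2) / (2 * np.pi)

        true = 0.5 * gauss(3.0) + 0.5 * gauss(-3.0)
        cell = (surf.x_centers[1] - surf.x_centers[0]) * (
            surf.y_centers[1] - surf.y_centers[0]
        )
        est_density = surf.mass / cell
        # pointwise agreement within 15% of the mixture's peak density
        assert np.max(np.abs(est_density - true)) < 0.15 * true.max()

    def test_collinear_points_flagged(self):
        pts = np.column_stack([np.arange(20.0), np.arange(20.0) * 2])
        surf = mvstats.kde2d_surface(pts)
        assert surf.flagged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            mvstats.kde2d_surface(np.zeros((5, 2)))


class TestNotchSummary:
    def test_constant_sample_zero_width(self):
        ns = mvstats.notch_summary(np.full(9, 3.3))
        assert ns.iqr == 0.0
        assert ns.notch_low == ns.notch_high == ns.median == pytest.approx(3.3)

    def test_one_to_nine(self):
        ns = mvstats.notch_summary(np.arange(1.0, 10.0))
        assert ns.median == 5.0
        assert ns.iqr == pytest.approx(4.0)
        assert ns.notch_low == pytest.approx(5 - 1.57 * 4 / 3)  # ~2.907
        assert ns.notch_high == pytest.approx(5 + 1.57 * 4 / 3)  # ~7.093

    def test_width_shrinks_like_inverse_sqrt_n(self):
        base = np.arange(1.0, 10.0)
        w1 = mvstats.notch_summary(base)
        w4 = mvstats.notch_summary(np.concatenate([base] * 4))
        assert (w4.notch_high - w4.notch_low) == pytest.approx(
            (w1.notch_high - w1.notch_low) / 2
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mvstats.notch_summary(np.array([]))


class TestWilcoxonRankSum:
    def test_identical_samples_p_one(self):
        a = np.array([1.0, 1.0, 1.0])
        _, p = mvstats.wilcoxon_rank_sum(a, a)
        assert p == 1.0

    def test_exact_enumeration_oracle(self):
        # fully separated 3v3: most extreme of C(6,3)=20 orderings, two-sided
        _, p = mvstats.wilcoxon_rank_sum(np.array([1, 2, 3]), np.array([4, 5, 6]))
        assert p == pytest.approx(2 / 20)

    def test_p_decreases_with_shift(self, rng):
        a = rng.normal(size=30)
        ps = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            _, p = mvstats.wilcoxon_rank_sum(a, a + shift)
            ps.append(p)
        assert ps == sorted(ps, reverse=True)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mvstats.wilcoxon_rank_sum(np.array([]), np.array([1.0]))


class TestSpeedCatalogue:
    def test_uniform_positive_coupling_significant(self, rng):
        rows = []
        for mode in ("Discontinuous", "Continuous"):
            for cell in range(10):
                z = rng.standard_normal(15)
                speed = 0.2 + 0.05 * z
                feat = 0.5 * z + 0.1 * rng.standard_normal(15)
                for t in range(15):
                    rows.append(
                        {"cell_track_id": f"{mode}{cell}", "frame": t, "mode": mode,
                         "cell_speed_um_per_min": speed[t], "g": feat[t]}
                    )
        cat, _ = mvstats.speed_correlation_catalogue(pd.DataFrame(rows), ["g"])
        assert cat["class"].iloc[0] == "both_positive"
        assert cat["rs_median_Continuous"].iloc[0] > 0

    def test_symmetric_rs_not_significant(self, rng):
        rows = []
        for mode in ("Discontinuous", "Continuous"):
            for cell in range(12):
                speed = rng.standard_normal(15)
                feat = rng.standard_normal(15)  # independent -> rs around 0
                for t in range(15):
                    rows.append(
                        {"cell_track_id": f"{mode}{cell}", "frame": t, "mode": mode,
                         "cell_speed_um_per_min": speed[t], "g": feat[t]}
                    )
        cat, _ = mvstats.speed_correlation_catalogue(pd.DataFrame(rows), ["g"])
        assert cat["class"].iloc[0] == "ns"

    def test_inverted_coupling_detected(self):
        table = synthetic.simulate_feature_table(seed=3)
        cat, _ = mvstats.speed_correlation_catalogue(table, ["f19"])
        assert cat["class"].iloc[0] == "inverted"

    def test_short_cells_skipped_and_counted(self, rng):
        rows = []
        for cell in range(4):
            n = 3 if cell == 0 else 15
            for t in range(n):
                rows.append(
                    {"cell_track_id": cell, "frame": t,
                     "mode": "Continuous" if cell % 2 else "Discontinuous",
                     "cell_speed_um_per_min": rng.random(), "g": rng.random()}
                )
        _, skipped = mvstats.speed_correlation_catalogue(pd.DataFrame(rows), ["g"])
        assert skipped["Discontinuous"] == 1
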