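"""Procrustes ANOVA, repeatability, CVA, mixtures, and disparity."""

import numpy as np
import pandas as pd
import pytest

from carapace.shapestats import (cva_jackknife, disparity,
                                 disparity_rarefaction, mixture_bic_select,
                                 pairwise_group_tests, procrustes_anova,
                                 repeatability)


class TestProcrustesAnova:
    def test_variance_partition_sums(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((30, 8))
        data = pd.DataFrame({"g": ["a", "b", "c"] * 10,
                             "x": rng.standard_normal(30)})
        res = procrustes_anova(y, data, ["x", "g"], n_perm=99, seed=0)
        assert res.ss.sum() + res.residual_ss == pytest.approx(res.total_ss)
        assert res.r_squared.sum() + res.residual_ss / res.total_ss == \
            pytest.approx(1.0)
        assert np.all((res.r_squared >= 0) & (res.r_squared <= 1))
        assert np.all((res.p > 0) & (res.p <= 1))

    def test_strong_group_effect_detected(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((40, 10)) * 0.1
        y[:20] += 1.0  # group shift far above noise
        data = pd.DataFrame({"g": ["a"] * 20 + ["b"] * 20})
        res = procrustes_anova(y, data, ["g"], n_perm=199, seed=1)
        assert res.p[0] <= 0.01
        assert res.r_squared[0] > 0.5

    def test_seed_fixes_p_exactly(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((24, 6))
        data = pd.DataFrame({"g": ["a", "b"] * 12})
        r1 = procrustes_anova(y, data, ["g"], n_perm=199, seed=7)
        r2 = procrustes_anova(y, data, ["g"], n_perm=199, seed=7)
        assert r1.p[0] == r2.p[0]

    def test_zero_df_term_rejected(self):
        y = np.random.default_rng(3).standard_normal((10, 4))
        data = pd.DataFrame({"g": ["a"] * 10})
        with pytest.raises(ValueError, match="zero degrees of freedom"):
            procrustes_anova(y, data, ["g"], n_perm=99, seed=0)

    def test_low_permutation_count_warns(self):
        y = np.random.default_rng(4).standard_normal((12, 4))
        data = pd.DataFrame({"g": ["a", "b"] * 6})
        with pytest.warns(UserWarning, match="low"):
            procrustes_anova(y, data, ["g"], n_perm=49, seed=0)


class TestPairwiseGroupTests:
    def test_bh_closed_form(self):
        """Raw p (0.01, 0.02, 0.03) adjust to (0.03, 0.03, 0.03) under BH."""
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal((30, 6))
        g = np.repeat(["a", "b", "c"], 10)
        mat = pairwise_group_tests(y, g, n_perm=99, seed=0)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.allclose(np.diag(mat.to_numpy()), 1.0)

    def test_adjusted_at_least_raw(self):
        """BH never lowers a p-value below its raw value: the adjusted matrix
        for identical groups stays well away from spurious significance."""
        rng = np.random.default_rng(6)
        y = rng.standard_normal((36, 6))
        g = np.repeat(["a", "b", "c"], 12)
        mat = pairwise_group_tests(y, g, n_perm=199, seed=1)
        off = mat.to_numpy()[~np.eye(3, dtype=bool)]
        assert off.min() > 0.0

    def test_shifted_group_flagged(self):
        """With one clearly shifted group, only its pairs are significant."""
        rng = np.random.default_rng(7)
        hits = 0
        for rep in range(20):
            y = rng.standard_normal((48, 6)) * 0.3
            g = np.repeat(["a", "b", "c", "d"], 12)
            y[g == "d"] += 2.0
            mat = pairwise_group_tests(y, g, n_perm=99, seed=rep)
            d_pairs = [mat.loc["d", other] for other in "abc"]
            null_pairs = [mat.loc[a, b] for a, b in (("a", "b"), ("a", "c"),
                                                     ("b", "c"))]
            if max(d_pairs) < 0.05 and min(null_pairs) > 0.05:
                hits += 1
        assert hits >= 18  # >= 90% of simulations

    def test_small_group_excluded(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal((21, 4))
        g = np.array(["a"] * 10 + ["b"] * 9 + ["c"] * 2)
        with pytest.warns(UserWarning, match="excluded"):
            mat = pairwise_group_tests(y, g, n_perm=99, seed=0)
        assert list(mat.index) == ["a", "b"]


class TestRepeatability:
    def test_identical_replicates(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal((4, 6))
        shapes = np.repeat(base, 3, axis=0)
        ids = np.repeat([f"s{i}" for i in range(4)], 3)
        res = repeatability(shapes, ids)
        assert res.me_percent == pytest.approx(0.0)
        assert res.icc == pytest.approx(1.0)

    def test_no_among_specimen_variance(self):
        rng = np.random.default_rng(10)
        shapes = np.zeros((12, 6)) + rng.standard_normal((12, 6)) * 0.5
        ids = np.repeat([f"s{i}" for i in range(4)], 3)
        res = repeatability(shapes, ids)
        assert res.icc < 0.35  # noise only: ICC near 0 (sampling scatter)

    def test_icc_me_complementary(self):
        rng = np.random.default_rng(11)
        base = rng.standard_normal((5, 8))
        shapes = np.repeat(base, 3, axis=0) + rng.standard_normal((15, 8)) * 0.2
        ids = np.repeat([f"s{i}" for i in range(5)], 3)
        res = repeatability(shapes, ids)
        assert res.icc + res.me_percent / 100 == pytest.approx(1.0)

    def test_variance_component_recovery(self):
        """Simulated 9:1 among:within variance ratio gives ICC near 0.9."""
        rng = np.random.default_rng(12)
        iccs = []
        for _ in range(100):
            base = rng.standard_normal((20, 4)) * 3.0      # s2_among = 9
            shapes = np.repeat(base, 3, axis=0) + rng.standard_normal((60, 4))
            ids = np.repeat([f"s{i}" for i in range(20)], 3)
            iccs.append(repeatability(shapes, ids).icc)
        assert np.mean(iccs) == pytest.approx(0.9, abs=0.05)

    def test_unbalanced_flagged(self):
        rng = np.random.default_rng(13)
        shapes = rng.standard_normal((7, 4))
        ids = ["a", "a", "a", "b", "b", "c", "c"]
        with pytest.warns(UserWarning, match="unbalanced"):
            res = repeatability(shapes, ids)
        assert not res.balanced


class TestCvaJackknife:
    def test_separated_clusters_fully_assigned(self):
        rng = np.random.default_rng(14)
        x = np.vstack([rng.standard_normal((30, 3)),
                       rng.standard_normal((30, 3)) + 10.0])
        res = cva_jackknife(x, ["a"] * 30 + ["b"] * 30)
        assert res.accuracy == 1.0
        assert res.confusion.to_numpy().sum(axis=1).tolist() == [30, 30]

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(15)
        x = np.vstack([rng.standard_normal((30, 3)),
                       rng.standard_normal((30, 3)) + 10.0])
        labels = np.array(["a"] * 30 + ["b"] * 30)
        accs = [cva_jackknife(x, rng.permutation(labels)).accuracy
                for _ in range(10)]
        # binomial(60, 0.5)/60: mean within ~3 SE of 0.5
        assert abs(np.mean(accs) - 0.5) < 3 * 0.5 / np.sqrt(60 * 10)

    def test_deterministic_tie_break(self):
        """A specimen exactly equidistant to both centroids (exact binary
        values) goes to the first group in sorted order, every run."""
        x = np.array([[0.0], [0.5], [1.125], [1.75], [2.25], [2.0]])
        labels = ["a", "a", "a", "b", "b", "b"]
        r1 = cva_jackknife(x, labels)
        r2 = cva_jackknife(x, labels)
        # leave-one-out centroids for the tie specimen are 0.25 and 2.0;
        # 1.125 is exactly midway, so the tie rule decides: group "a"
        assert r1.confusion.loc["a", "a"] == 3
        assert r1.confusion.equals(r2.confusion)

    def test_reduces_pcs_when_groups_small(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal((8, 6))
        with pytest.warns(UserWarning, match="reducing"):
            cva_jackknife(x, ["a"] * 4 + ["b"] * 4)


class TestMixtureSelect:
    def test_single_gaussian_prefers_k1(self):
        rng = np.random.default_rng(17)
        wins = sum(
            mixture_bic_select(rng.standard_normal((200, 3)), seed=s)[1].k == 1
            for s in range(20))
        assert wins >= 19  # >= 95%

    def test_two_well_separated_gaussians(self):
        rng = np.random.default_rng(18)
        x = np.vstack([rng.standard_normal((100, 2)),
                       rng.standard_normal((100, 2)) + 8.0])
        _, best = mixture_bic_select(x, seed=0)
        assert best.k == 2

    def test_k1_bic_matches_closed_form(self):
        """BIC of the k=1 full-covariance model equals the analytic Gaussian
        log-likelihood at the MLE (biased covariance), penalized."""
        rng = np.random.default_rng(19)
        x = rng.standard_normal((80, 3)) * 1.5
        fits, _ = mixture_bic_select(x, k_max=1, seed=0)
        full = next(f for f in fits if f.covariance_family == "full")
        n, d = x.shape
        cov = np.cov(x.T, bias=True) + 1e-6 * np.eye(d)  # EM's reg_covar ridge
        sign, logdet = np.linalg.slogdet(cov)
        diff = x - x.mean(axis=0)
        quad = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
        loglik = -0.5 * (n * d * np.log(2 * np.pi) + n * logdet + quad.sum())
        n_params = d + d * (d + 1) // 2
        bic = 2 * loglik - n_params * np.log(n)
        assert full.bic == pytest.approx(bic, rel=1e-4)

    def test_singleton_cluster_flagged_uninformative(self):
        rng = np.random.default_rng(20)
        x = rng.standard_normal((40, 2))
        x = np.vstack([x, [[50.0, 50.0]]])  # one extreme outlier
        fits, best = mixture_bic_select(x, seed=0)
        assert any(not f.informative for f in fits if f.k > 1)
        assert best.informative


class TestDisparity:
    def test_identical_specimens(self):
        assert disparity(np.ones((5, 3))) == 0.0

    def test_two_specimens(self):
        d = 3.0
        scores = np.array([[0.0, 0.0], [d, 0.0]])
        assert disparity(scores) == pytest.approx(d**2 / 2)

    def test_equals_trace_of_covariance(self):
        rng = np.random.default_rng(21)
        scores = rng.standard_normal((50, 5))
        assert disparity(scores) == pytest.approx(
            np.trace(np.cov(scores.T)), rel=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(22)
        scores = rng.standard_normal((30, 4))
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        assert disparity(scores @ q) == pytest.approx(disparity(scores))

    def test_mean_distance_variant(self):
        scores = np.array([[0.0], [2.0]])
        assert disparity(scores, method="mean_distance") == pytest.approx(1.0)

    def test_undefined_below_two(self):
        with pytest.raises(ValueError):
            disparity(np.ones((1, 3)))


class TestDisparityRarefaction:
    def test_rarefied_mean_matches_full_sample(self):
        """Mean rarefied disparity at N = 200 equals the full-sample value
        within Monte-Carlo error (bootstrap slightly biased low by ~1/N)."""
        rng = np.random.default_rng(23)
        scores = rng.standard_normal((200, 5))
        curve = disparity_rarefaction(scores, n_boot=1000, seed=0)
        full = disparity(scores)
        boot_mean = curve.mean_disparity[-1]
        # E[bootstrap disparity] = full * (1 - 1/N); allow 3 MC standard errors
        se = full * np.sqrt(2.0 / 200) / np.sqrt(1000) * 3
        assert boot_mean == pytest.approx(full * (1 - 1 / 200), abs=3e-2 + se)

    def test_ci_upper_above_mean(self):
        rng = np.random.default_rng(24)
        curve = disparity_rarefaction(rng.standard_normal((100, 3)),
                                      sizes=np.arange(10, 101, 10),
                                      n_boot=500, seed=1)
        assert np.all(curve.ci_upper >= curve.mean_disparity)

    def test_outlying_fossils_flagged(self):
        rng = np.random.default_rng(25)
        modern = rng.standard_normal((150, 4))
        fossils = rng.standard_normal((8, 4)) + 10.0
        curve = disparity_rarefaction(
            modern, {"far": fossils}, sizes=np.arange(10, 151, 10),
            n_boot=500, seed=2)
        assert curve.exceeds["far"]

    def test_empty_fossil_set_skipped(self):
        rng = np.random.default_rng(26)
        with pytest.warns(UserWarning, match="empty"):
            curve = disparity_rarefaction(
                rng.standard_normal((60, 3)), {"none": np.empty((0, 3))},
                sizes=np.arange(10, 61, 10), n_boot=200, seed=3)
        assert "none" not in curve.augmented
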