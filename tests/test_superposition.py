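"""Superposition: centroid size, GPA, sliding, symmetry, tangent PCA."""

import numpy as np
import pytest

from carapace.io import LandmarkConfiguration
from carapace.schemes import LandmarkScheme, get_scheme
from carapace.superposition import (DegenerateConfigurationError,
                                    UnrecoverablePointError, centroid_size,
                                    estimate_missing_by_reflection,
                                    full_procrustes_distance, procrustes_align,
                                    procrustes_distance, symmetric_component,
                                    tangent_pca)
from carapace.synthgen import make_template


def rotate(coords, theta):
    c, s = np.cos(theta), np.sin(theta)
    return coords @ np.array([[c, -s], [s, c]])


class TestCentroidSize:
    def test_unit_square(self):
        sq = np.array([(0.5, 0.5), (0.5, -0.5), (-0.5, -0.5), (-0.5, 0.5)])
        assert centroid_size(sq) == pytest.approx(np.sqrt(2))

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        c = rng.standard_normal((8, 2))
        assert centroid_size(3 * c) == pytest.approx(3 * centroid_size(c))

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        c = rng.standard_normal((6, 2))
        moved = rotate(c, 1.1) + [4, -2]
        assert centroid_size(moved) == pytest.approx(centroid_size(c))

    def test_brute_force_formula(self):
        rng = np.random.default_rng(2)
        c = rng.standard_normal((10, 2))
        ctr = c.mean(axis=0)
        brute = np.sqrt(sum((p - ctr) @ (p - ctr) for p in c))
        assert abs(centroid_size(c) - brute) < 1e-12

    def test_too_few_points(self):
        with pytest.raises(DegenerateConfigurationError):
            centroid_size(np.array([(0, 0), (1, 1)]))


class TestGPA:
    def test_identical_shapes_align_exactly(self):
        tri = np.array([(0.0, 0.0), (1.0, 0.0), (0.3, 0.8)])
        out = procrustes_align(np.stack([tri, tri]))
        assert np.sqrt(np.sum((out.coords[0] - out.coords[1]) ** 2)) < 1e-12

    def test_similarity_invariance(self):
        tri = np.array([(0.0, 0.0), (1.0, 0.0), (0.3, 0.8)])
        copy = rotate(tri, np.radians(37)) * 2.5 + [10, -4]
        out = procrustes_align(np.stack([tri, copy]))
        assert np.sqrt(np.sum((out.coords[0] - out.coords[1]) ** 2)) < 1e-10

    def test_pairwise_distances_match_two_config_oracle(self):
        """Full Procrustes distances among 5 random quadrilaterals agree with
        the closed-form complex-regression two-configuration solution."""
        rng = np.random.default_rng(3)
        quads = rng.standard_normal((5, 4, 2))
        out = procrustes_align(quads)
        for i in range(5):
            for j in range(i + 1, 5):
                # closed-form 2-D oracle: shapes as centered complex vectors;
                # full PD^2 = 1 - |<z, w>|^2 / (|z|^2 |w|^2)
                z = (quads[i][:, 0] + 1j * quads[i][:, 1])
                w = (quads[j][:, 0] + 1j * quads[j][:, 1])
                z -= z.mean()
                w -= w.mean()
                oracle = np.sqrt(
                    1 - np.abs(np.vdot(z, w)) ** 2
                    / ((np.abs(z) ** 2).sum() * (np.abs(w) ** 2).sum()))
                ours = full_procrustes_distance(out.coords[i], out.coords[j])
                assert ours == pytest.approx(oracle, abs=1e-6)

    def test_invariant_to_input_similarity_transforms(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((6, 5, 2))
        out1 = procrustes_align(base)
        messed = np.stack([
            rotate(c, rng.uniform(0, 2 * np.pi)) * rng.uniform(0.5, 3)
            + rng.uniform(-5, 5, 2)
            for c in base
        ])
        out2 = procrustes_align(messed)
        for a, b in zip(out1.coords, out2.coords):
            assert procrustes_distance(a, b) < 1e-8

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((6, 5, 2))
        out1 = procrustes_align(base)
        perm = rng.permutation(6)
        out2 = procrustes_align(base[perm])
        inv = np.argsort(perm)
        for a, b in zip(out1.coords, out2.coords[inv]):
            assert procrustes_distance(a, b) < 1e-8

    def test_needs_two_configs(self):
        with pytest.raises(ValueError):
            procrustes_align(np.zeros((1, 4, 2)))


class TestSliding:
    def _noisy_templates(self, seed, n=8, noise=0.01):
        scheme = get_scheme("lateral")
        tpl = make_template("lateral").coords
        rng = np.random.default_rng(seed)
        return scheme, tpl[None] + rng.standard_normal((n, *tpl.shape)) * noise

    def test_sliding_never_increases_objective(self):
        """Monotone descent of the GPA objective across 100 random datasets."""
        for seed in range(100):
            scheme, configs = self._noisy_templates(seed, n=6)
            plain = procrustes_align(configs, scheme, slide=False)
            slid = procrustes_align(configs, scheme, slide=True)
            obj_plain = np.sum((plain.coords - plain.mean_shape) ** 2)
            obj_slid = np.sum((slid.coords - slid.mean_shape) ** 2)
            assert obj_slid <= obj_plain + 1e-12

    def test_sliding_reduces_semilandmark_scatter(self):
        scheme, configs = self._noisy_templates(11, n=20, noise=0.02)
        plain = procrustes_align(configs, scheme, slide=False)
        slid = procrustes_align(configs, scheme, slide=True)
        semis = sorted(scheme.semilandmark_indices)
        var_plain = np.sum(np.var(plain.coords[:, semis], axis=0))
        var_slid = np.sum(np.var(slid.coords[:, semis], axis=0))
        assert var_slid < var_plain


class TestMissingEstimation:
    def _config(self, coords, mask=None):
        return LandmarkConfiguration("s", "symtoy", coords, missing_mask=mask)

    def test_exact_recovery_on_symmetric_config(self, symmetric_toy_scheme):
        coords = np.array([(0.0, 0.0), (2.0, 0.0), (1.0, 1.0), (1.0, -1.0),
                           (0.5, 0.7), (0.5, -0.7)])
        broken = coords.copy()
        broken[4] = np.nan
        cfg = self._config(broken, [0, 0, 0, 0, 1, 0])
        fixed = estimate_missing_by_reflection(cfg, symmetric_toy_scheme)
        assert np.abs(fixed.coords[4] - coords[4]).max() < 1e-10

    def test_identity_when_complete(self, symmetric_toy_scheme):
        coords = np.random.default_rng(0).standard_normal((6, 2))
        cfg = self._config(coords)
        assert estimate_missing_by_reflection(cfg, symmetric_toy_scheme) is cfg

    def test_manual_reflection_oracle(self, symmetric_toy_scheme):
        # midline along y = x; pair of the missing point 4 is point 5 at (2, 0);
        # reflecting (x, y) across y = x gives (y, x) -> expect (0, 2)
        coords = np.array([(0.0, 0.0), (3.0, 3.0), (1.0, 0.2), (0.2, 1.0),
                           (np.nan, np.nan), (2.0, 0.0)])
        cfg = self._config(coords, [0, 0, 0, 0, 1, 0])
        fixed = estimate_missing_by_reflection(cfg, symmetric_toy_scheme)
        assert np.abs(fixed.coords[4] - [0.0, 2.0]).max() < 1e-10

    def test_pair_also_missing_is_unrecoverable(self, symmetric_toy_scheme):
        coords = np.full((6, 2), np.nan)
        coords[:2] = [(0, 0), (1, 0)]
        cfg = self._config(coords, [0, 0, 1, 1, 1, 1])
        with pytest.raises(UnrecoverablePointError):
            estimate_missing_by_reflection(cfg, symmetric_toy_scheme)

    def test_lateral_view_unsupported(self):
        cfg = LandmarkConfiguration("s", "lateral", np.zeros((44, 2)))
        with pytest.raises(ValueError, match="symmetry"):
            estimate_missing_by_reflection(cfg, get_scheme("lateral"))


class TestSymmetricComponent:
    def test_symmetric_specimen_recovers_its_half(self):
        scheme = get_scheme("dorsal")
        tpl = make_template("dorsal").coords
        rng = np.random.default_rng(0)
        # symmetric perturbations only
        from carapace.synthgen import symmetrize_vector
        configs = []
        for _ in range(4):
            v = symmetrize_vector(rng.standard_normal(tpl.size) * 0.01, scheme)
            configs.append(tpl + v.reshape(-1, 2))
        aligned = procrustes_align(np.stack(configs), scheme)
        sym = symmetric_component(aligned, scheme)
        half = scheme.half_indices()
        for i in range(4):
            assert procrustes_distance(sym.coords[i],
                                       aligned.coords[i][half]) < 1e-6

    def test_antisymmetric_displacement_cancels(self):
        """Specimens differing only by +/- delta on opposite sides collapse to
        the undisplaced shape; the cancellation is exact to second order in
        delta, so the residual must shrink quadratically."""
        scheme = get_scheme("dorsal")
        tpl = make_template("dorsal").coords
        rng = np.random.default_rng(1)
        perm = scheme.mirror_permutation()
        v = rng.standard_normal(tpl.shape)
        mirrored = v[perm].copy()
        mirrored[:, 1] *= -1
        anti = 0.5 * (v - mirrored)  # purely asymmetric displacement field
        residuals = []
        for delta in (1e-2, 1e-3):
            configs = np.stack([tpl, tpl + delta * anti, tpl - delta * anti])
            aligned = procrustes_align(configs, scheme)
            sym = symmetric_component(aligned, scheme)
            residuals.append(max(
                procrustes_distance(sym.coords[i], sym.coords[0])
                for i in (1, 2)))
        assert residuals[0] < 1e-3
        assert residuals[1] < residuals[0] / 50  # ~quadratic decay

    def test_invariant_to_relabel_and_mirror(self):
        """Applying the mirror involution to inputs leaves the symmetric
        component unchanged (up to superposition)."""
        scheme = get_scheme("posterior")
        tpl = make_template("posterior").coords
        rng = np.random.default_rng(2)
        configs = tpl[None] + rng.standard_normal((5, *tpl.shape)) * 0.01
        perm = scheme.mirror_permutation()
        mirrored = configs[:, perm, :].copy()
        mirrored[:, :, 1] *= -1
        s1 = symmetric_component(procrustes_align(configs, scheme), scheme)
        s2 = symmetric_component(procrustes_align(mirrored, scheme), scheme)
        for a, b in zip(s1.coords, s2.coords):
            assert procrustes_distance(a, b) < 1e-6

    def test_lateral_rejected(self):
        scheme = get_scheme("lateral")
        rng = np.random.default_rng(3)
        sample = procrustes_align(rng.standard_normal((3, 44, 2)), scheme)
        with pytest.raises(ValueError):
            symmetric_component(sample, scheme)


class TestTangentPCA:
    def test_identical_shapes_zero_variance(self):
        tri = np.array([(0.0, 0.0), (1.0, 0.0), (0.3, 0.8)])
        aligned = procrustes_align(np.stack([tri] * 4))
        space = tangent_pca(aligned)
        assert np.allclose(space.variance_explained, 0.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        aligned = procrustes_align(rng.standard_normal((10, 6, 2)))
        space = tangent_pca(aligned)
        assert space.variance_explained.sum() == pytest.approx(1.0)
        assert np.all(np.diff(space.variance_explained) <= 1e-12)

    def test_scores_preserve_distances(self):
        rng = np.random.default_rng(5)
        aligned = procrustes_align(rng.standard_normal((8, 6, 2)))
        space = tangent_pca(aligned)
        flat = aligned.flat()
        for i in range(8):
            for j in range(i + 1, 8):
                d_flat = np.linalg.norm(flat[i] - flat[j])
                d_pc = np.linalg.norm(space.scores[i] - space.scores[j])
                assert d_pc == pytest.approx(d_flat, abs=1e-8)

    def test_projection_matches_training_scores(self):
        rng = np.random.default_rng(6)
        aligned = procrustes_align(rng.standard_normal((8, 6, 2)))
        space = tangent_pca(aligned)
        proj = space.project(aligned.flat())
        assert np.allclose(proj, space.scores, atol=1e-8)
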