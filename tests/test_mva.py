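import warnings

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from nanoftir.errors import InvalidInputError, UndefinedCorrelationError
from nanoftir.grids import FrequencyGrid
from nanoftir.mva import (
    DistanceMap,
    cluster_stats,
    composite_map,
    d_value,
    euclidean_distance_map,
    hca,
    superposition_test,
    unmix,
)
from nanoftir.scene import hair_components
from nanoftir.stitching import BaselineAnchors, baseline_correct


def _blend_references(run, lo=1030.0, hi=1870.0):
    """Baseline-corrected pure-component phases on the hypercube grid."""
    hyper, scene = run.hypercube, run.scene
    anchors = BaselineAnchors(*run.config.anchors)
    sel = hyper.grid.mask(lo, hi)
    refs = {}
    for name in ("AC", "FP"):
        p = np.interp(hyper.grid.values, scene.grid.values, scene.components[name].phase)
        refs[name] = baseline_correct((hyper.grid, p), anchors)[sel]
    return refs, sel


def _averaged_spectra(run, label, sel, n=30):
    """3x3-neighbourhood averages of noisy pixel spectra of one truth label."""
    hyper, scene = run.hypercube, run.scene
    ny, nx = hyper.shape
    ys, xs = np.nonzero(scene.labels == label)
    out = []
    for y, x in list(zip(ys, xs))[:n]:
        block = hyper.phase[max(y - 1, 0): y + 2, max(x - 1, 0): x + 2]
        out.append(block.mean(axis=(0, 1))[sel])
    return out


class TestEuclideanDistanceMap:
    def test_own_spectrum_zero(self):
        grid = FrequencyGrid.regular(1000.0, 1100.0, 10.0)
        cube = np.random.default_rng(0).normal(size=(4, 5, len(grid)))
        dm = euclidean_distance_map(cube, cube[2, 3])
        assert dm.values[2, 3] == pytest.approx(0.0, abs=1e-12)

    def test_all_zeros(self):
        cube = np.zeros((3, 3, 8))
        dm = euclidean_distance_map(cube, np.zeros(8))
        np.testing.assert_allclose(dm.values, 0.0)

    def test_three_point_hand_computation(self):
        cube = np.array([[[3.0, 4.0, 0.0]]])
        dm = euclidean_distance_map(cube, np.zeros(3))
        assert dm.values[0, 0] == pytest.approx(5.0)

    def test_constant_shift_invariance(self):
        grid = FrequencyGrid.regular(1000.0, 1100.0, 10.0)
        rng = np.random.default_rng(1)
        cube = rng.normal(size=(3, 4, len(grid)))
        ref = rng.normal(size=len(grid))
        a = euclidean_distance_map(cube, ref)
        b = euclidean_distance_map(cube + 5.0, ref + 5.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)


class TestCompositeMap:
    def test_extreme_pixels(self):
        red = DistanceMap(np.array([[0.0, 10.0], [10.0, 5.0]]), "A", (0, 1))
        blue = DistanceMap(np.array([[10.0, 10.0], [0.0, 5.0]]), "B", (0, 1))
        comp = composite_map([red, blue], ["red", "blue"], clip_percentiles=(0, 100))
        np.testing.assert_allclose(comp.rgb[0, 0], [1.0, 0.0, 0.0])  # saturated red
        np.testing.assert_allclose(comp.rgb[0, 1], [0.0, 0.0, 0.0])  # both far: black
        assert comp.rgb[1, 1, 0] == pytest.approx(comp.rgb[1, 1, 2])  # purple

    def test_requires_two_maps(self):
        dm = DistanceMap(np.zeros((2, 2)), "A", (0, 1))
        with pytest.raises(InvalidInputError):
            composite_map([dm], ["red"])


class TestDValue:
    def test_identical_zero(self):
        a = np.array([1.0, 2.0, 5.0, 3.0])
        assert d_value(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_anticorrelated_2000(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert d_value(a, -a) == pytest.approx(2000.0, abs=1e-9)

    def test_toy_vectors_brute_force_pearson(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 4.0])
        # independent brute-force Pearson evaluation
        r = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert d_value(a, b) == pytest.approx((1 - r) * 1000.0, abs=1e-9)

    def test_affine_invariance_and_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        assert d_value(a, b) == pytest.approx(d_value(b, a))
        assert d_value(3.0 * a + 7.0, b) == pytest.approx(d_value(a, b), abs=1e-9)
        assert 0.0 <= d_value(a, b) <= 2000.0

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            d_value(np.ones(5), np.arange(5.0))


class TestHCA:
    def test_single_cluster(self):
        rng = np.random.default_rng(0)
        cube = rng.normal(size=(3, 3, 12))
        result = hca(cube, n_clusters=1, analysis_range=None)
        assert np.all(result.labels == 1)

    def test_two_population_perfect_separation(self):
        comps = hair_components()
        ker, mel = comps["keratin"].phase, comps["melanin"].phase
        cube = np.empty((4, 6, len(ker)))
        truth = np.zeros((4, 6), dtype=int)
        rng = np.random.default_rng(1)
        for y in range(4):
            for x in range(6):
                if (y * 6 + x) % 2:
                    cube[y, x] = mel + rng.normal(0, 0.05, mel.size)
                    truth[y, x] = 1
                else:
                    cube[y, x] = ker + rng.normal(0, 0.05, ker.size)
        result = hca(cube, n_clusters=2, grid=comps["keratin"].grid)
        assert adjusted_rand_score(truth.ravel(), result.labels.ravel()) == 1.0

    def test_blend_hypercube_ari(self, noisy_run, analysis_mask):
        result = hca(noisy_run.hypercube, n_clusters=5, mask=analysis_mask)
        ari = adjusted_rand_score(
            noisy_run.scene.labels[analysis_mask], result.labels[analysis_mask]
        )
        assert ari >= 0.9

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        cube = rng.normal(size=(4, 4, 10))
        a = hca(cube, n_clusters=3, analysis_range=None)
        b = hca(cube, n_clusters=3, analysis_range=None)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_labels_sorted_by_size(self, noisy_run, analysis_mask):
        result = hca(noisy_run.hypercube, n_clusters=5, mask=analysis_mask)
        sizes = [(result.labels == k).sum() for k in range(1, 6)]
        assert sizes == sorted(sizes, reverse=True)

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(4)
        cube = rng.normal(size=(4, 4, 10))
        result = hca(cube, n_clusters=2, analysis_range=None)
        heights = result.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-9)

    def test_too_many_clusters_rejected(self):
        cube = np.random.default_rng(0).normal(size=(2, 2, 5))
        with pytest.raises(InvalidInputError):
            hca(cube, n_clusters=10, analysis_range=None)


class TestClusterStats:
    def test_single_pixel_cluster(self):
        cube = np.arange(24.0).reshape(2, 3, 4)
        labels = np.ones((2, 3), dtype=int)
        labels[0, 0] = 2
        means, sds = cluster_stats(cube, labels)
        np.testing.assert_allclose(means[2], cube[0, 0])
        np.testing.assert_allclose(sds[2], 0.0)

    def test_identical_spectra_zero_sd(self):
        cube = np.tile(np.arange(4.0), (2, 2, 1))
        means, sds = cluster_stats(cube, np.ones((2, 2), dtype=int))
        np.testing.assert_allclose(sds[1], 0.0)

    def test_two_value_hand_computation(self):
        cube = np.array([[[0.0], [10.0]]])
        means, sds = cluster_stats(cube, np.ones((1, 2), dtype=int))
        assert means[1][0] == pytest.approx(5.0)
        assert sds[1][0] == pytest.approx(5.0)  # population sd

    def test_empty_cluster_flagged(self):
        cube = np.zeros((1, 2, 3))
        labels = np.array([[1, 3]])
        means, _ = cluster_stats(cube, labels)
        assert means[2].size == 0


class TestUnmix:
    def test_identity(self):
        rng = np.random.default_rng(0)
        refs = [rng.normal(size=30), rng.normal(size=30)]
        result = unmix(refs[0], refs, allow_offset=False)
        np.testing.assert_allclose(result.coefficients, [1.0, 0.0], atol=1e-9)
        assert result.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_constructed_mixture(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=40), rng.normal(size=40)
        result = unmix(0.3 * a + 0.7 * b, [a, b])
        np.testing.assert_allclose(result.coefficients, [0.3, 0.7], atol=1e-6)

    def test_scene_mixture_weights_noiseless(self, noiseless_run):
        refs, sel = _blend_references(noiseless_run)
        scene = noiseless_run.scene
        ys, xs = np.nonzero(scene.labels == scene.label_id("interface"))
        spectrum = noiseless_run.hypercube.phase[ys[0], xs[0]][sel]
        result = unmix(spectrum, [refs["AC"], refs["FP"]])
        # interface rule: 0.65 AC + 0.35 FP; reconstruction-limited tolerance
        np.testing.assert_allclose(result.coefficients, [0.65, 0.35], atol=0.02)

    def test_noisy_averaged_mixture_weights(self, driftfree_noisy_run):
        refs, sel = _blend_references(driftfree_noisy_run)
        scene = driftfree_noisy_run.scene
        lab = scene.label_id("FP+AC")
        spectra = _averaged_spectra(driftfree_noisy_run, lab, sel)
        coeffs = np.mean(
            [unmix(s, [refs["AC"], refs["FP"]]).coefficients for s in spectra], axis=0
        )
        np.testing.assert_allclose(coeffs, [0.3, 0.7], atol=0.1)

    def test_interaction_residual_5x_mixture(self, driftfree_noisy_run):
        refs, sel = _blend_references(driftfree_noisy_run)
        scene = driftfree_noisy_run.scene
        ref_list = [refs["AC"], refs["FP"]]
        mix = [
            unmix(s, ref_list).residual_rms
            for s in _averaged_spectra(driftfree_noisy_run, scene.label_id("interface"), sel)
        ]
        inter = [
            unmix(s, ref_list).residual_rms
            for s in _averaged_spectra(driftfree_noisy_run, scene.label_id("interaction"), sel)
        ]
        assert np.median(inter) >= 5.0 * np.median(mix)

    def test_collinear_references_warn(self):
        a = np.arange(20.0)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = unmix(a, [a, 2.0 * a], allow_offset=False)
        assert result.ill_conditioned
        assert any("collinear" in str(w.message) for w in caught)

    def test_r_squared_perfect_fit(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=25)
        result = unmix(0.4 * a + 2.0, [a])
        assert result.r_squared == pytest.approx(1.0, abs=1e-9)
        assert result.offset == pytest.approx(2.0, abs=1e-6)


class TestSuperpositionTest:
    def test_true_mixture_accepted(self, driftfree_noisy_run):
        refs, sel = _blend_references(driftfree_noisy_run)
        scene = driftfree_noisy_run.scene
        ref_list = [refs["AC"], refs["FP"]]
        pure = [
            unmix(s, ref_list).residual_rms
            for s in _averaged_spectra(driftfree_noisy_run, scene.label_id("AC"), sel)
        ]
        spectra = _averaged_spectra(driftfree_noisy_run, scene.label_id("interface"), sel)
        for s in spectra:
            ok, _ = superposition_test(s, ref_list, pure_residuals=pure)
            assert ok

    def test_interaction_rejected(self, driftfree_noisy_run):
        refs, sel = _blend_references(driftfree_noisy_run)
        scene = driftfree_noisy_run.scene
        ref_list = [refs["AC"], refs["FP"]]
        pure = [
            unmix(s, ref_list).residual_rms
            for s in _averaged_spectra(driftfree_noisy_run, scene.label_id("AC"), sel)
        ]
        for s in _averaged_spectra(driftfree_noisy_run, scene.label_id("interaction"), sel):
            ok, _ = superposition_test(s, ref_list, pure_residuals=pure)
            assert not ok

    def test_pure_reference_trivially_true(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        ok, result = superposition_test(a, [a], threshold=1e-9, allow_offset=False)
        assert ok and result.residual_rms == pytest.approx(0.0, abs=1e-10)

    def test_threshold_requires_pure_residuals(self):
        with pytest.raises(InvalidInputError):
            superposition_test(np.arange(5.0), [np.ones(5)])
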