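"""Brightness computation, light-class thresholds and class statistics."""

import numpy as np
import pytest

from phenospectra import light, scene, segment
from phenospectra.cube import SpectralCube, calibrate_reflectance
from phenospectra.light import (
    LIGHT_CLASS_NAMES,
    LightThresholds,
    classify_pixels,
    class_mean_spectra,
    compute_brightness,
    derive_light_thresholds,
    variance_reduction,
)


def _rgb_cube(blue, green, red):
    vals = np.stack([np.asarray(blue, float), np.asarray(green, float),
                     np.asarray(red, float)], axis=-1)
    return SpectralCube(vals, [492.0, 539.0, 651.0], "VNIR", calibrated=True)


def optimal_1d_kmeans(values: np.ndarray, k: int):
    """Exhaustive dynamic-programming 1-D k-means (globally optimal SSE).

    Independent oracle for the Lloyd-based implementation: O(k n^2) DP over
    the sorted values returning the optimal cluster centroids.
    """
    x = np.sort(np.asarray(values, float))
    n = x.size
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def sse(i, j):  # cost of cluster x[i..j] inclusive
        s = pref[j + 1] - pref[i]
        s2 = pref2[j + 1] - pref2[i]
        m = j - i + 1
        return s2 - s * s / m

    INF = np.inf
    D = np.full((k + 1, n + 1), INF)
    arg = np.zeros((k + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            best, bi = INF, 0
            for i in range(kk - 1, j):
                c = D[kk - 1, i] + sse(i, j - 1)
                if c < best:
                    best, bi = c, i
            D[kk, j], arg[kk, j] = best, bi
    # backtrack cluster boundaries
    bounds = []
    j = n
    for kk in range(k, 0, -1):
        i = arg[kk, j]
        bounds.append((i, j - 1))
        j = i
    bounds.reverse()
    return np.array([x[i : j + 1].mean() for i, j in bounds])


class TestBrightness:
    def test_max_of_three_channels(self):
        c = _rgb_cube([[0.2]], [[0.5]], [[0.3]])
        assert compute_brightness(c)[0, 0] == pytest.approx(0.5)

    def test_equal_channels(self):
        c = _rgb_cube([[0.4]], [[0.4]], [[0.4]])
        assert compute_brightness(c)[0, 0] == pytest.approx(0.4)

    def test_green_dominates_for_vegetation(self, calibrated_small_scene):
        """For generated leaf spectra brightness is the green band almost
        everywhere, mirroring that HSV value tracks green reflection."""
        rho_v, _, truth = calibrated_small_scene
        b = compute_brightness(rho_v)
        green = rho_v.band_image(539.0)
        frac = np.mean(b[truth.plant_mask] == green[truth.plant_mask])
        assert frac > 0.95

    def test_band_out_of_range_rejected(self):
        c = SpectralCube(np.ones((1, 1, 2)), [900.0, 950.0], "VNIR", True)
        with pytest.raises(ValueError):
            compute_brightness(c)


class TestThresholds:
    def test_five_gaussians_match_dp_oracle(self):
        """Nested k-means boundaries agree with the globally optimal 1-D
        clustering on well-separated populations."""
        rng = np.random.default_rng(0)
        centers = [0.05, 0.12, 0.35, 0.62, 0.70]
        x = np.concatenate([rng.normal(c, 0.012, 700) for c in centers])
        thr = derive_light_thresholds(x, seed=0)
        oracle_centroids = optimal_1d_kmeans(x, 5)
        oracle_bounds = (oracle_centroids[:-1] + oracle_centroids[1:]) / 2
        assert np.all(np.abs(thr.boundaries - oracle_bounds) < 0.01 * np.ptp(x))

    def test_same_seed_identical(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(c, 0.02, 500) for c in (0.1, 0.3, 0.6)])
        a = derive_light_thresholds(x, seed=3)
        b = derive_light_thresholds(x, seed=3)
        assert np.array_equal(a.boundaries, b.boundaries)
        assert a.specular_cut == b.specular_cut

    def test_overlapping_clusters_still_increasing(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(c, 0.15, 800) for c in (0.3, 0.35, 0.4)])
        thr = derive_light_thresholds(x, seed=0)
        assert np.all(np.diff(thr.boundaries) > 0)
        assert thr.specular_cut >= thr.boundaries[-1]

    def test_constant_brightness_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            derive_light_thresholds(np.full(2000, 0.5))

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            derive_light_thresholds(np.linspace(0, 1, 500))

    def test_json_round_trip(self, tmp_path):
        thr = LightThresholds([0.1, 0.2, 0.3, 0.4], 0.9, {"seed": 0})
        p = tmp_path / "thr.json"
        thr.to_json(p)
        back = LightThresholds.from_json(p)
        assert np.array_equal(back.boundaries, thr.boundaries)
        assert back.specular_cut == thr.specular_cut


class TestClassification:
    THR = LightThresholds([0.1, 0.2, 0.3, 0.4], 0.9)

    def test_below_first_boundary_is_ex_low(self):
        cm = classify_pixels(np.array([[0.05]]), np.array([[True]]), self.THR)
        assert cm.labels[0, 0] == 1  # ex-low

    def test_above_specular_cut_is_specular(self):
        cm = classify_pixels(np.array([[0.95]]), np.array([[True]]), self.THR)
        assert cm.labels[0, 0] == light.SPECULAR_LABEL

    def test_background_stays_background(self):
        cm = classify_pixels(np.array([[0.25]]), np.array([[False]]), self.THR)
        assert cm.labels[0, 0] == 0

    def test_partition_property(self, calibrated_small_scene):
        """Class counts sum exactly to the plant pixel count."""
        rho_v, _, truth = calibrated_small_scene
        b = compute_brightness(rho_v)
        thr = derive_light_thresholds(b[truth.plant_mask], seed=0)
        cm = classify_pixels(b, truth.plant_mask, thr)
        assert sum(cm.counts().values()) == int(truth.plant_mask.sum())
        assert not np.any((cm.labels > 0) & ~truth.plant_mask)

    def test_class_gain_ordering(self):
        """With a purely linear illumination field, higher light classes
        correspond to strictly higher median ground-truth gain."""
        cfg = scene.SceneConfig(
            lines=192, vnir_samples=144, swir_samples=132,
            vnir_wavelengths=np.linspace(400, 1000, 40),
            swir_wavelengths=np.linspace(970, 2500, 10),
            shade_fraction=0.10, specular_fraction=0.0, leaf_scale_sd=0.0,
        )
        vnir, _, refs_v, _, truth = scene.generate_scene(cfg, seed=4)
        rho = calibrate_reflectance(vnir, refs_v)
        b = compute_brightness(rho)
        thr = derive_light_thresholds(b[truth.plant_mask], seed=0)
        cm = classify_pixels(b, truth.plant_mask, thr)
        g = truth.illumination.effective_gain()
        medians = [
            np.median(g[cm.class_mask(n)])
            for n in LIGHT_CLASS_NAMES
            if cm.class_mask(n).any()
        ]
        assert len(medians) >= 3
        assert np.all(np.diff(medians) > 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            classify_pixels(np.zeros((2, 2)), np.zeros((3, 3), bool), self.THR)


class TestClassMeans:
    def test_uniform_cube_identical_means(self):
        c = SpectralCube(np.full((4, 4, 3), 0.3), [500.0, 600.0, 700.0], "VNIR", True)
        b = np.tile(np.linspace(0, 0.5, 4), (4, 1))
        cm = classify_pixels(b, np.ones((4, 4), bool), TestClassification.THR)
        recs = class_mean_spectra(c, cm)
        wcols = [col for col in recs.columns if isinstance(col, float)]
        assert np.allclose(recs[wcols].to_numpy(), 0.3)

    def test_weighted_mean_identity(self, calibrated_small_scene):
        rho_v, _, truth = calibrated_small_scene
        b = compute_brightness(rho_v)
        thr = derive_light_thresholds(b[truth.plant_mask], seed=0)
        cm = classify_pixels(b, truth.plant_mask, thr)
        recs = class_mean_spectra(rho_v, cm, "p1")
        wcols = [col for col in recs.columns if isinstance(col, float)]
        weighted = np.average(
            recs[wcols].to_numpy(), axis=0, weights=recs["pixel_count"]
        )
        whole = rho_v.values[cm.labels > 0].mean(axis=0)
        assert np.max(np.abs(weighted - whole)) < 1e-12

    def test_two_constructed_halves(self):
        vals = np.full((2, 4, 2), 0.2)
        vals[:, 2:, :] = 0.6
        c = SpectralCube(vals, [500.0, 600.0], "VNIR", True)
        brightness = vals[:, :, 0]
        cm = classify_pixels(brightness, np.ones((2, 4), bool),
                             LightThresholds([0.3, 0.35, 0.4, 0.45], 0.9))
        recs = class_mean_spectra(c, cm)
        means = sorted(recs[500.0])
        assert means == [pytest.approx(0.2), pytest.approx(0.6)]

    def test_empty_mask_rejected(self):
        c = SpectralCube(np.ones((2, 2, 1)), [500.0], "VNIR", True)
        cm = classify_pixels(np.zeros((2, 2)), np.zeros((2, 2), bool),
                             TestClassification.THR)
        with pytest.raises(ValueError, match="empty"):
            class_mean_spectra(c, cm)


class TestVarianceReduction:
    def test_random_labels_no_reduction(self):
        rng = np.random.default_rng(0)
        n = 10000
        vals = rng.normal(0.4, 0.08, (1, n, 1))
        c = SpectralCube(vals, [600.0], "VNIR", True)
        labels = rng.integers(1, 6, (1, n)).astype(np.int8)
        red = variance_reduction(c, light.LightClassMap(labels))
        assert abs(red) < 0.05

    def test_closed_form_two_population_mixture(self):
        """Perfect separation of a two-component mixture removes exactly the
        between-component share of the total variance."""
        n = 4000
        a, b = 0.2, 0.6
        vals = np.concatenate([np.full(n, a), np.full(n, b)])
        rng = np.random.default_rng(1)
        vals = vals + rng.normal(0, 0.01, 2 * n)
        c = SpectralCube(vals.reshape(1, -1, 1), [600.0], "VNIR", True)
        labels = np.concatenate([np.full(n, 1), np.full(n, 3)]).reshape(1, -1)
        red = variance_reduction(c, light.LightClassMap(labels.astype(np.int8)))
        total = vals.var()
        within = 0.5 * vals[:n].var() + 0.5 * vals[n:].var()
        assert red == pytest.approx(1 - within / total, abs=1e-12)
        assert red > 0.9

    def test_single_class_rejected(self):
        c = SpectralCube(np.random.default_rng(0).random((1, 50, 1)),
                         [600.0], "VNIR", True)
        labels = np.full((1, 50), 3, dtype=np.int8)
        with pytest.raises(ValueError, match="two populated"):
            variance_reduction(c, light.LightClassMap(labels))

    def test_default_scene_reduction_floor(self, calibrated_small_scene):
        """Light classification removes a substantial share of within-plant
        variance on simulated scenes."""
        rho_v, _, truth = calibrated_small_scene
        b = compute_brightness(rho_v)
        thr = derive_light_thresholds(b[truth.plant_mask], seed=0)
        cm = classify_pixels(b, truth.plant_mask, thr)
        assert variance_reduction(rho_v, cm) >= 0.25
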