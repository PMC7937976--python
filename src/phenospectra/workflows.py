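"""End-to-end evaluation workflows on simulated data.

Two studies that exercise the whole pipeline against ground truth:

* :func:`masked_drought_power` — does light-class conditioning recover a
  drought effect that plant-to-plant illumination differences mask in
  whole-plant mean reflectance?
* :func:`trait_recovery_study` — when a trait is generated from a known band
  combination, do index discovery and the two model families (index-based
  linear and PLSR) recover it?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import chemometrics as chem
from . import cube, light, scene, segment
from .indices import (
    IndexDefinition,
    compute_index,
    exhaustive_pair_search,
    get_index,
    greedy_index_builder,
)

__all__ = [
    "MaskedDroughtResult",
    "masked_drought_power",
    "TraitRecoveryResult",
    "trait_recovery_study",
    "train_light_thresholds",
    "plant_mean_658",
]

#: drought level of the water-deficit arm in the masked-drought study:
#: a moderate stress whose 658 nm signal is comparable to the
#: illumination-induced spread of whole-plant means
MASKED_DROUGHT_LEVEL = 0.25


def train_light_thresholds(seed: int = 0) -> light.LightThresholds:
    """Fixed thresholds from a pooled training set spanning drought levels."""
    parts = []
    for i, d in enumerate([0.0, 0.25, 0.5] * 3):
        cfg = scene.confounded_drought_config(d)
        v, _, rv, _, _ = scene.generate_scene(cfg, seed=seed * 1000 + i)
        rho = cube.calibrate_reflectance(v, rv)
        mask = segment.segment_vnir(rho)
        parts.append(light.compute_brightness(rho)[mask.labels])
    return light.derive_light_thresholds(np.concatenate(parts), seed=seed)


def plant_mean_658(drought: float, seed: int, thresholds: light.LightThresholds):
    """One plant's 658 nm mean: (whole-plant, intermediate-class)."""
    cfg = scene.confounded_drought_config(drought)
    v, _, rv, _, _ = scene.generate_scene(cfg, seed)
    rho = cube.calibrate_reflectance(v, rv)
    mask = segment.segment_vnir(rho)
    b = light.compute_brightness(rho)
    cm = light.classify_pixels(b, mask, thresholds)
    r658 = rho.band_image(658.0)
    analysis = (cm.labels > 0) & (cm.labels < light.SPECULAR_LABEL)
    whole = float(r658[analysis].mean()) if analysis.any() else np.nan
    inter = cm.class_mask("intermediate")
    inter_mean = float(r658[inter].mean()) if inter.any() else np.nan
    return whole, inter_mean


def six_class_demo(seed: int = 0) -> dict[str, int]:
    """Light-class counts on a scene whose brightness spans every class.

    Thresholds are derived from a glint-free training scene (glint saturates
    far above leaf brightness, so it falls beyond the uppermost threshold by
    construction); the classified scene adds specular pixels.  With shading,
    a wide gain range and glint present, all five analysis classes and the
    specular class are populated.
    """
    cfg_train = scene.SceneConfig(
        lines=256, vnir_samples=192, swir_samples=176,
        vnir_wavelengths=np.linspace(400, 1000, 40),
        swir_wavelengths=np.linspace(970, 2500, 10),
        gain_min=0.5, gain_max=1.5, shade_fraction=0.12,
        specular_fraction=0.0, leaf_scale_sd=0.02,
    )
    vnir, _, refs, _, truth = scene.generate_scene(cfg_train, seed=seed)
    rho = cube.calibrate_reflectance(vnir, refs)
    b = light.compute_brightness(rho)
    thr = light.derive_light_thresholds(b[truth.plant_mask], seed=seed)

    # same scene geometry with glint added: every k-means cluster keeps its
    # own brightness bin populated, and glint lands above the specular cut
    cfg_apply = scene.SceneConfig(**{**cfg_train.__dict__,
                                     "specular_fraction": 0.01})
    vnir2, _, refs2, _, truth2 = scene.generate_scene(cfg_apply, seed=seed)
    rho2 = cube.calibrate_reflectance(vnir2, refs2)
    # classify on the true plant mask: glint pixels are spectrally white and
    # would be dropped by red-edge segmentation before ever being classified
    cm = light.classify_pixels(
        light.compute_brightness(rho2), truth2.plant_mask, thr
    )
    return cm.counts()


@dataclass
class MaskedDroughtResult:
    power_whole_plant: float
    power_intermediate: float
    n_scenes: int
    n_per_arm: int
    drought_level: float


def masked_drought_power(
    n_replicates: int = 200,
    n_per_arm: int = 8,
    drought_level: float = MASKED_DROUGHT_LEVEL,
    alpha: float = 0.05,
    seed: int = 0,
) -> MaskedDroughtResult:
    """Detection power at 658 nm: whole-plant vs intermediate-class means.

    Each replicate renders ``n_per_arm`` well-watered and ``n_per_arm``
    water-deficit plants under per-plant illumination-level variation, then
    runs a two-sample t test on the plant means from each pipeline.  Power is
    the fraction of replicates with p < alpha.
    """
    thr = train_light_thresholds(seed)
    rng = np.random.default_rng(seed)
    hits_w = hits_i = 0
    for _ in range(n_replicates):
        ww_w, ww_i, wd_w, wd_i = [], [], [], []
        for _ in range(n_per_arm):
            w, i_ = plant_mean_658(0.0, int(rng.integers(2**31)), thr)
            ww_w.append(w)
            ww_i.append(i_)
            w, i_ = plant_mean_658(drought_level, int(rng.integers(2**31)), thr)
            wd_w.append(w)
            wd_i.append(i_)
        pw = stats.ttest_ind(ww_w, wd_w).pvalue
        ok_ww = [x for x in ww_i if np.isfinite(x)]
        ok_wd = [x for x in wd_i if np.isfinite(x)]
        pi = stats.ttest_ind(ok_ww, ok_wd).pvalue if min(len(ok_ww), len(ok_wd)) > 1 else 1.0
        hits_w += pw < alpha
        hits_i += pi < alpha
    return MaskedDroughtResult(
        hits_w / n_replicates, hits_i / n_replicates,
        n_replicates, n_per_arm, drought_level,
    )


@dataclass
class TraitRecoveryResult:
    generating_abs_r: float
    exhaustive_abs_r: float
    greedy_abs_r: float
    index_test_r2: float
    plsr_test_r2: float
    index_test_rmse: float
    plsr_test_rmse: float
    plsr_components: int
    n: int


def merged_grid() -> np.ndarray:
    """VNIR+SWIR wavelengths on one axis; the 970-1000 nm overlap comes from
    the finer-resolution VNIR sensor."""
    wv = scene.default_vnir_grid()
    ws = scene.default_swir_grid()
    return np.concatenate([wv, ws[ws > wv[-1]]])


def trait_recovery_study(
    trait_name: str = "Psi",
    generating_index: str | IndexDefinition = "WPI2",
    population_r2: float = 0.92,
    slope: float = -8.0,
    intercept: float = 6.0,
    n_observations: int = 150,
    max_plsr_components: int = 12,
    seed: int = 0,
) -> TraitRecoveryResult:
    """Generate a trait from a known index and try to win it back.

    The trait is linear in the generating index plus Gaussian noise sized for
    the requested population R².  Both discovery methods search the merged
    VNIR+SWIR grid; both model families are fitted on a stratified 80/20
    split and evaluated on the held-out test set.
    """
    wl = merged_grid()
    gen = get_index(generating_index) if isinstance(generating_index, str) else generating_index
    tab = scene.generate_spectra_table(
        n_plants=50, days=(0, 3, 5, 7, 9), hours=(8.0, 11.0, 14.0, 17.0),
        wavelengths=wl, seed=seed,
    )
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(len(tab), size=n_observations, replace=False))
    tab = tab.iloc[rows].reset_index(drop=True)
    wlv, X, _ = scene.spectra_matrix(tab)
    idx = np.asarray(compute_index(wlv, X, gen))
    noise_sd = scene.noise_sd_for_r2(idx, slope, population_r2)
    link = scene.TraitLinkSpec(trait_name, gen, slope, intercept, noise_sd,
                               seed=seed + 1)
    trait_tab = scene.generate_trait_table(link, tab)
    y = trait_tab.data[trait_name].to_numpy(float)
    r_gen = abs(float(np.corrcoef(idx, y)[0, 1]))

    exh = exhaustive_pair_search(wlv, X, y, trait_name=trait_name)
    grd = greedy_index_builder(wlv, X, y, trait_name=trait_name)

    full = trait_tab.data.join(tab[[c for c in tab.columns if isinstance(c, float)]])
    train, test = chem.split_train_test(full, 0.8, seed=seed)
    band_cols = [c for c in full.columns if isinstance(c, float)]
    y_tr = train[trait_name].to_numpy(float)
    y_te = test[trait_name].to_numpy(float)
    x_tr = np.asarray(compute_index(wlv, train[band_cols].to_numpy(float), exh.definition))
    x_te = np.asarray(compute_index(wlv, test[band_cols].to_numpy(float), exh.definition))
    ev_idx = chem.evaluate(y_te, chem.fit_index_model(x_tr, y_tr).predict(x_te))
    X_tr = train[band_cols].to_numpy(float)
    X_te = test[band_cols].to_numpy(float)
    k = chem.select_components(X_tr, y_tr, max_plsr_components)
    plsr = chem.fit_plsr(X_tr, y_tr, k, wlv)
    ev_plsr = chem.evaluate(y_te, plsr.predict(X_te))
    return TraitRecoveryResult(
        r_gen, abs(exh.correlation), abs(grd.correlation),
        ev_idx.r_squared, ev_plsr.r_squared,
        ev_idx.rmse, ev_plsr.rmse, k, len(full),
    )
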