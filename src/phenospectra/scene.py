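"""Synthetic greenhouse scene generator with known ground truth.

Emulates a top-view two-sensor pushbroom acquisition of a single maize plant:
a VNIR cube (~400-1000 nm, 194 bands, 511 x 328 pixels) and a SWIR cube
(~970-2500 nm, 256 bands, 511 x 320 pixels) plus per-sensor white and dark
reference frames.  Every stage of the analysis pipeline can be validated
against the scene's ground truth: the plant mask, the per-pixel illumination
field (linear gain from distance/inclination, non-linear shading, specular
glint), the affine VNIR->SWIR registration, and the parameters linking traits
to band combinations.

The leaf spectrum is a parametric template (logistic red edge plus Gaussian
absorption valleys), not a physical leaf-optics model: exact ground-truth
control matters more here than radiometric realism.  Drought and time of day
shift the template in the directions observed for moderately water-stressed
maize: drought raises blue-green, red and SWIR reflectance and lowers green,
red-edge and NIR reflectance; over the day visible reflectance rises while
red-edge, NIR and SWIR reflectance fall, more steeply under water deficit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .cube import ReferencePair, SpectralCube
from .indices import Expr, IndexDefinition, compute_index

__all__ = [
    "WATER_TROUGH_CENTERS",
    "LeafSpectrumParams",
    "IlluminationField",
    "TraitLinkSpec",
    "SceneTruth",
    "SceneConfig",
    "generate_leaf_spectrum",
    "generate_scene",
    "generate_trait_table",
    "generate_diurnal_series",
    "generate_spectra_table",
    "noise_sd_for_r2",
    "default_vnir_grid",
    "default_swir_grid",
]

#: centres (nm) of the water absorption valleys carved into the template
WATER_TROUGH_CENTERS = (979.0, 1232.0, 1445.0, 1955.0)

#: widths (nm) of the corresponding Gaussian valleys
_TROUGH_SIGMA = {979.0: 30.0, 1232.0: 40.0, 1445.0: 60.0, 1955.0: 55.0}

#: default valley depths (reflectance fraction) for a well-watered leaf
_DEFAULT_TROUGH_DEPTH = {979.0: 0.05, 1232.0: 0.06, 1445.0: 0.16, 1955.0: 0.14}


def default_vnir_grid() -> np.ndarray:
    """194 bands over 400-1000 nm (3 nm spacing after 4x spectral binning)."""
    return np.linspace(400.0, 1000.0, 194)


def default_swir_grid() -> np.ndarray:
    """256 bands over 970-2500 nm (6 nm spacing)."""
    return np.linspace(970.0, 2500.0, 256)


@dataclass
class LeafSpectrumParams:
    """Parameters of the leaf reflectance template.

    All reflectance components are fractions in [0, 1].  ``drought_level`` in
    [0, 1] interpolates between the well-watered template (0) and the full
    water-deficit response (1); ``hour_of_day`` applies the diurnal trend
    around solar noon.
    """

    green_peak_height: float = 0.10
    red_trough_depth: float = 0.06
    nir_plateau: float = 0.45
    water_trough_depths: dict[float, float] = field(
        default_factory=lambda: dict(_DEFAULT_TROUGH_DEPTH)
    )
    drought_level: float = 0.0
    hour_of_day: float = 12.0

    def __post_init__(self) -> None:
        if set(self.water_trough_depths) != set(WATER_TROUGH_CENTERS):
            raise ValueError(
                f"water_trough_depths must be keyed by {WATER_TROUGH_CENTERS}"
            )
        for name in ("green_peak_height", "red_trough_depth", "nir_plateau"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.drought_level <= 1.0:
            raise ValueError("drought_level must lie in [0, 1]")


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# Drought response: signed Gaussian bumps (fraction reflectance at drought 1).
# Positive at 523, 658 nm and in the SWIR (1482, 2110 nm); negative at
# 551, 708/721 (red edge) and 976 nm (NIR water trough region).
_DROUGHT_BUMPS = (
    (523.0, 11.0, +0.015),
    (551.0, 11.0, -0.018),
    (658.0, 16.0, +0.030),
    (715.0, 16.0, -0.030),
    (976.0, 35.0, -0.030),
    (1482.0, 60.0, +0.030),
    (2110.0, 90.0, +0.025),
)

# Diurnal response: slope of percent reflectance per hour for the well-watered
# template, and the additional slope reached at drought level 1.  Signs follow
# the observed pattern: visible bands brighten over the day, red-edge/NIR/SWIR
# bands darken, with the water-deficit decline steeper at 721, 976 and 1694 nm.
_DIURNAL_BUMPS = (
    # (center, sigma, ww %/h, wd extra %/h)
    (523.0, 11.0, +0.0857, +0.005),
    (551.0, 11.0, +0.0303, -0.027),
    (658.0, 16.0, +0.0828, +0.009),
    (708.0, 7.0, -0.0690, -0.008),
    (721.0, 7.0, -0.2087, -0.117),
    (976.0, 35.0, -0.2281, -0.251),
    (1482.0, 60.0, -0.0972, -0.063),
    (1694.0, 60.0, -0.2546, -0.146),
    (1937.0, 40.0, -0.0363, -0.006),
    (2110.0, 70.0, -0.0999, -0.061),
    (2321.0, 70.0, -0.1108, -0.064),
)


def _baseline(wl: np.ndarray, p: LeafSpectrumParams) -> np.ndarray:
    """Template without the water absorption valleys.

    Visible: low base with a green peak at 551 nm and a red trough at 670 nm.
    A logistic red edge at ~715 nm rises to the NIR plateau; beyond 1300 nm
    the plateau relaxes linearly to a SWIR level, then a dry-matter shoulder
    climbs from 1650 nm to a plateau at 1825 nm.  The shoulder's slope
    exceeds the inward tail of the 1955 nm absorption valley, which places
    the ridge between the 1445 and 1955 nm valleys at 1825 nm; past 1825 nm
    the baseline is flat, so the 1955 nm valley floor sits on the same
    baseline as the 1825 nm shoulder.
    """
    visible = 0.10 + p.green_peak_height * _gauss(wl, 551.0, 35.0)
    visible = visible - p.red_trough_depth * _gauss(wl, 670.0, 40.0)
    edge = _sigmoid((wl - 715.0) / 12.0)
    base = visible * (1.0 - edge) + p.nir_plateau * edge
    # linear relaxation from the NIR plateau to the SWIR level
    swir_level = 0.62 * p.nir_plateau
    ramp = np.clip((wl - 1300.0) / 400.0, 0.0, 1.0)
    base = base * (1.0 - ramp) + swir_level * ramp
    # dry-matter shoulder: +0.03 between 1650 and 1825 nm, flat afterwards
    shoulder = 0.03 * np.clip((wl - 1650.0) / 175.0, 0.0, 1.0)
    return base + shoulder


def generate_leaf_spectrum(
    params: LeafSpectrumParams, wavelengths: np.ndarray
) -> np.ndarray:
    """Leaf reflectance (fraction) on an ascending wavelength grid.

    Raises on an unsorted grid or wavelengths outside 400-2500 nm.
    Deterministic: identical parameters give identical spectra.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size > 1 and np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be sorted ascending")
    if wl.size and (wl[0] < 400.0 or wl[-1] > 2500.0):
        raise ValueError("wavelengths must lie within 400-2500 nm")
    rho = _baseline(wl, params)
    for center in WATER_TROUGH_CENTERS:
        depth = params.water_trough_depths[center]
        rho = rho - depth * _gauss(wl, center, _TROUGH_SIGMA[center])
    d = params.drought_level
    if d:
        for center, sigma, amp in _DROUGHT_BUMPS:
            rho = rho + d * amp * _gauss(wl, center, sigma)
    dt = params.hour_of_day - 12.0
    if dt:
        for center, sigma, ww, wd_extra in _DIURNAL_BUMPS:
            slope = (ww + d * wd_extra) / 100.0  # percent -> fraction
            rho = rho + dt * slope * _gauss(wl, center, sigma)
    return np.clip(rho, 0.0, 1.0)


@dataclass
class IlluminationField:
    """Per-pixel illumination ground truth on one sensor grid.

    ``multiplicative_gain`` is the linear distance/inclination effect;
    ``shading_mask``/``shade_factor`` encode the non-linear shadow attenuation
    (applied multiplicatively after the gain); ``specular_mask`` marks glint
    pixels whose signal saturates near the white level.
    """

    multiplicative_gain: np.ndarray
    shading_mask: np.ndarray
    specular_mask: np.ndarray
    shade_factor: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.shading_mask & self.specular_mask):
            raise ValueError("shading and specular masks must be disjoint")
        if not np.all(np.isfinite(self.multiplicative_gain)):
            raise ValueError("gain must be finite everywhere")
        if np.any(self.multiplicative_gain < 0):
            raise ValueError("gain must be non-negative")

    def effective_gain(self) -> np.ndarray:
        g = self.multiplicative_gain.astype(float).copy()
        if self.shade_factor is not None:
            g[self.shading_mask] *= self.shade_factor[self.shading_mask]
        return g


@dataclass
class TraitLinkSpec:
    """Ground-truth link from spectra to a physiological trait.

    trait = slope * generating_expression(spectrum) + intercept + N(0, noise_sd).
    """

    trait_name: str
    generating_expression: IndexDefinition | Expr
    slope: float
    intercept: float
    noise_sd: float
    seed: int = 0

    _TRAITS = ("A", "E", "gs", "PhiCO2", "PhiPS2", "FvpFmp", "Psi", "WC")

    def __post_init__(self) -> None:
        if self.trait_name not in self._TRAITS:
            raise ValueError(f"trait_name must be one of {self._TRAITS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        expr = (
            self.generating_expression.expression
            if isinstance(self.generating_expression, IndexDefinition)
            else self.generating_expression
        )
        for b in expr.bands():
            lo, hi = b.lo, (b.hi if b.hi is not None else b.lo)
            if lo < 480.0 or hi > 2470.0:
                raise ValueError("generating bands must lie within 480-2470 nm")

    @property
    def generating_bands(self) -> list[float]:
        expr = (
            self.generating_expression.expression
            if isinstance(self.generating_expression, IndexDefinition)
            else self.generating_expression
        )
        return sorted({b.lo for b in expr.bands()})


@dataclass
class RegistrationTruth:
    """Affine VNIR->SWIR pixel mapping: s' = a s + b l + c, l' = d s + e l + f."""

    sample_coeffs: tuple[float, float, float]
    line_coeffs: tuple[float, float, float]

    def __post_init__(self) -> None:
        a, b, _ = self.sample_coeffs
        d, e, _ = self.line_coeffs
        if abs(a * e - b * d) < 1e-12:
            raise ValueError("registration transform must be invertible")

    def apply(self, s: np.ndarray, l: np.ndarray):
        a, b, c = self.sample_coeffs
        d, e, f = self.line_coeffs
        return a * s + b * l + c, d * s + e * l + f


@dataclass
class SceneTruth:
    """Everything the simulator knows that the pipeline must recover."""

    illumination: IlluminationField
    plant_mask: np.ndarray
    leaf_params: LeafSpectrumParams
    leaf_scale: np.ndarray
    registration_truth: RegistrationTruth
    swir_plant_mask: np.ndarray | None = None
    swir_illumination: IlluminationField | None = None
    background_reflectance: float = 0.03

    def leaf_reflectance(self, wavelengths: np.ndarray) -> np.ndarray:
        """Scene-level leaf spectrum (before per-pixel scale and illumination)."""
        return generate_leaf_spectrum(self.leaf_params, wavelengths)


@dataclass
class SceneConfig:
    """Scene geometry, optics and illumination statistics.

    Defaults reproduce the acquisition geometry of the emulated setup
    (511 lines; 328 VNIR / 320 SWIR samples; 194 / 256 bands).  Illumination:
    the gain field is a smooth random surface in [gain_min, gain_max]
    multiplied by a per-scene global level drawn from N(1, gain_scene_sd);
    shading covers ~``shade_fraction`` of plant pixels with attenuation
    0.2-0.5; ~``specular_fraction`` of plant pixels saturate at 98% of the
    white signal.
    """

    lines: int = 511
    vnir_samples: int = 328
    swir_samples: int = 320
    vnir_wavelengths: np.ndarray = field(default_factory=default_vnir_grid)
    swir_wavelengths: np.ndarray = field(default_factory=default_swir_grid)
    drought_level: float = 0.0
    hour_of_day: float = 12.0
    leaf_params: LeafSpectrumParams | None = None
    n_leaves: int = 8
    gain_min: float = 0.65
    gain_max: float = 1.35
    gain_scene_sd: float = 0.0
    shade_fraction: float = 0.08
    specular_fraction: float = 0.005
    leaf_scale_sd: float = 0.0
    background_reflectance: float = 0.03
    registration_shift: float = 0.0
    white_level: float = 3500.0
    dark_level: float = 100.0

    def __post_init__(self) -> None:
        if self.lines <= 0 or self.vnir_samples <= 0 or self.swir_samples <= 0:
            raise ValueError("image dimensions must be positive")
        self.vnir_wavelengths = np.asarray(self.vnir_wavelengths, dtype=float)
        self.swir_wavelengths = np.asarray(self.swir_wavelengths, dtype=float)


def _leaf_rosette_mask(lines: int, samples: int, n_leaves: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Union of elongated elliptical leaves radiating from the pot centre."""
    ll, ss = np.mgrid[0:lines, 0:samples]
    cy, cx = (lines - 1) / 2.0, (samples - 1) / 2.0
    scale = min(lines, samples)
    mask = np.zeros((lines, samples), dtype=bool)
    for k in range(n_leaves):
        angle = 2.0 * np.pi * k / n_leaves + rng.uniform(-0.2, 0.2)
        length = scale * rng.uniform(0.28, 0.42)
        width = scale * rng.uniform(0.035, 0.06)
        mx = cx + 0.55 * length * np.cos(angle)
        my = cy + 0.55 * length * np.sin(angle)
        u = (ss - mx) * np.cos(angle) + (ll - my) * np.sin(angle)
        v = -(ss - mx) * np.sin(angle) + (ll - my) * np.cos(angle)
        mask |= (u / (0.5 * length)) ** 2 + (v / (0.5 * width)) ** 2 <= 1.0
    return mask


def _smooth_field(shape, rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Smooth random surface normalized to [0, 1]."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (f - lo) / (hi - lo)


def _resample_nearest(img: np.ndarray, reg: RegistrationTruth,
                      target_shape: tuple[int, int], fill) -> np.ndarray:
    """Pull-back resampling of a VNIR-grid image onto the SWIR grid."""
    a, b, c = reg.sample_coeffs
    d, e, f = reg.line_coeffs
    det = a * e - b * d
    tl, ts = np.mgrid[0:target_shape[0], 0:target_shape[1]]
    sp, lp = ts - c, tl - f
    src_s = (e * sp - b * lp) / det
    src_l = (-d * sp + a * lp) / det
    si = np.ceil(src_s - 0.5).astype(int)
    li = np.ceil(src_l - 0.5).astype(int)
    inside = (si >= 0) & (si < img.shape[1]) & (li >= 0) & (li < img.shape[0])
    out = np.full(target_shape, fill, dtype=img.dtype)
    out[inside] = img[li[inside], si[inside]]
    return out


def _reference_frames(samples: int, wavelengths: np.ndarray, cfg: SceneConfig,
                      rng: np.random.Generator):
    """White/dark frames with smooth cross-track and spectral structure."""
    s = np.arange(samples) / max(samples - 1, 1)
    cross = 1.0 - 0.15 * (s - 0.5) ** 2 + 0.02 * np.sin(2 * np.pi * 3 * s)
    spectral = 0.7 + 0.3 * np.exp(
        -0.5 * ((wavelengths - wavelengths.mean()) / (0.4 * np.ptp(wavelengths) + 1)) ** 2
    )
    white = cfg.white_level * cross[:, None] * spectral[None, :]
    dark = cfg.dark_level * (1.0 + 0.05 * rng.standard_normal((samples, wavelengths.size)))
    return white, dark


def _render(reflectance_bands: np.ndarray, eff_gain: np.ndarray,
            specular: np.ndarray, white: np.ndarray, dark: np.ndarray,
            plant: np.ndarray, background: float) -> np.ndarray:
    """raw = dark + (white-dark) * gain * reflectance; glint saturates at 98%."""
    lines, samples = eff_gain.shape
    bands = white.shape[1]
    factor = np.where(plant, eff_gain, 1.0)
    cube = np.empty((lines, samples, bands), dtype=float)
    span = (white - dark)[None, :, :]
    refl = np.where(plant[:, :, None], reflectance_bands, background)
    cube[:] = dark[None, :, :] + span * factor[:, :, None] * refl
    if specular.any():
        cube[specular] = (dark + 0.98 * (white - dark))[
            np.nonzero(specular)[1]
        ]
    return cube


def generate_scene(config: SceneConfig | None = None, seed: int = 0):
    """Simulate one two-sensor acquisition.

    Returns ``(vnir_raw, swir_raw, vnir_refs, swir_refs, truth)`` where the
    cubes are raw digital numbers, refs are :class:`ReferencePair` frames and
    ``truth`` is the :class:`SceneTruth`.  Same seed, same scene.
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)

    leaf_params = cfg.leaf_params or LeafSpectrumParams(
        drought_level=cfg.drought_level, hour_of_day=cfg.hour_of_day
    )
    shape_v = (cfg.lines, cfg.vnir_samples)
    plant_v = _leaf_rosette_mask(cfg.lines, cfg.vnir_samples, cfg.n_leaves, rng)

    # linear gain: smooth surface in [gain_min, gain_max], times a scene level
    surf = _smooth_field(shape_v, rng, sigma=max(4.0, min(shape_v) / 16.0))
    gain = cfg.gain_min + (cfg.gain_max - cfg.gain_min) * surf
    if cfg.gain_scene_sd > 0:
        gain = gain * max(0.1, 1.0 + cfg.gain_scene_sd * rng.standard_normal())

    # non-linear shading: thresholded second smooth field, attenuation 0.2-0.5
    shade_field = _smooth_field(shape_v, rng, sigma=max(3.0, min(shape_v) / 24.0))
    if cfg.shade_fraction > 0:
        cut = np.quantile(shade_field[plant_v], cfg.shade_fraction) if plant_v.any() \
            else -np.inf
        shading = plant_v & (shade_field <= cut)
    else:
        shading = np.zeros(shape_v, dtype=bool)
    shade_factor = np.ones(shape_v)
    shade_factor[shading] = rng.uniform(0.2, 0.5, int(shading.sum()))

    # specular glint: random isolated plant pixels, disjoint from shade
    specular = np.zeros(shape_v, dtype=bool)
    if cfg.specular_fraction > 0 and plant_v.any():
        cand = np.flatnonzero(plant_v & ~shading)
        k = int(round(cfg.specular_fraction * plant_v.sum()))
        if k > 0 and cand.size:
            pick = rng.choice(cand, size=min(k, cand.size), replace=False)
            specular.flat[pick] = True

    illum_v = IlluminationField(gain, shading, specular, shade_factor)

    # per-pixel biological variation of the leaf spectrum (multiplicative)
    if cfg.leaf_scale_sd > 0:
        leaf_scale = 1.0 + cfg.leaf_scale_sd * (
            2.0 * _smooth_field(shape_v, rng, sigma=max(2.0, min(shape_v) / 20.0)) - 1.0
        )
    else:
        leaf_scale = np.ones(shape_v)

    reg = RegistrationTruth(
        (cfg.swir_samples / cfg.vnir_samples, 0.0, cfg.registration_shift),
        (0.0, 1.0, 0.0),
    )

    white_v, dark_v = _reference_frames(cfg.vnir_samples, cfg.vnir_wavelengths, cfg, rng)
    white_s, dark_s = _reference_frames(cfg.swir_samples, cfg.swir_wavelengths, cfg, rng)
    if np.any(white_v <= dark_v) or np.any(white_s <= dark_s):
        raise ValueError("white reference must exceed dark reference at every band")

    spec_v = generate_leaf_spectrum(leaf_params, cfg.vnir_wavelengths)
    spec_s = generate_leaf_spectrum(leaf_params, cfg.swir_wavelengths)

    refl_v = np.clip(leaf_scale[:, :, None] * spec_v[None, None, :], 0.0, 1.0)
    eff_gain = illum_v.effective_gain()
    vnir_raw = _render(refl_v, eff_gain, specular, white_v, dark_v,
                       plant_v, cfg.background_reflectance)

    # SWIR shares the scene, observed through the registration transform
    plant_s = _resample_nearest(plant_v, reg, (cfg.lines, cfg.swir_samples), False)
    gain_s = _resample_nearest(eff_gain, reg, (cfg.lines, cfg.swir_samples), 1.0)
    spec_mask_s = _resample_nearest(specular, reg, (cfg.lines, cfg.swir_samples), False)
    shade_s = _resample_nearest(shading, reg, (cfg.lines, cfg.swir_samples), False)
    scale_s = _resample_nearest(leaf_scale, reg, (cfg.lines, cfg.swir_samples), 1.0)
    illum_s = IlluminationField(
        _resample_nearest(gain, reg, (cfg.lines, cfg.swir_samples), 1.0),
        shade_s & ~spec_mask_s, spec_mask_s,
    )
    refl_s = np.clip(scale_s[:, :, None] * spec_s[None, None, :], 0.0, 1.0)
    swir_raw = _render(refl_s, gain_s, spec_mask_s, white_s, dark_s,
                       plant_s, cfg.background_reflectance)

    truth = SceneTruth(
        illumination=illum_v,
        plant_mask=plant_v,
        leaf_params=leaf_params,
        leaf_scale=leaf_scale,
        registration_truth=reg,
        swir_plant_mask=plant_s,
        swir_illumination=illum_s,
        background_reflectance=cfg.background_reflectance,
    )
    vnir = SpectralCube(vnir_raw, cfg.vnir_wavelengths, "VNIR", calibrated=False)
    swir = SpectralCube(swir_raw, cfg.swir_wavelengths, "SWIR", calibrated=False)
    return (
        vnir,
        swir,
        ReferencePair(white_v, dark_v),
        ReferencePair(white_s, dark_s),
        truth,
    )


# --------------------------------------------------------------------------
# Tabular generators (per-plant spectra, traits, diurnal series)
# --------------------------------------------------------------------------

def generate_spectra_table(
    n_plants: int = 50,
    days: tuple[int, ...] = (0, 5, 7, 9),
    hours: tuple[float, ...] = (8.0, 11.0, 14.0, 17.0),
    wavelengths: np.ndarray | None = None,
    treatments: tuple[str, str] = ("WW", "WD"),
    max_drought: float = 1.0,
    spectral_noise_sd: float = 0.002,
    trough_jitter_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-plant mean spectra over a drought time course.

    Plants alternate between treatments; water-deficit plants ramp their
    drought level linearly over the listed days up to ``max_drought``.
    Pigment/structure parameters (green peak, NIR plateau) vary between
    plants; the water-absorption trough depths additionally vary between
    observations (leaf water content changes across days and within a day),
    so the SWIR valleys carry information not redundant with the visible
    bands.  Additive per-band noise emulates the residual uncertainty of a
    plant-mean spectrum averaged over thousands of pixels.
    Columns: plant_id, treatment, day, hour, then one column per wavelength.
    """
    wl = np.asarray(
        default_vnir_grid() if wavelengths is None else wavelengths, dtype=float
    )
    rng = np.random.default_rng(seed)
    rows = []
    spectra = []
    max_day = max(days) if days else 1
    for p in range(n_plants):
        treat = treatments[p % len(treatments)]
        green = 0.10 + 0.01 * rng.standard_normal()
        nir = 0.45 + 0.02 * rng.standard_normal()
        plant_depth = {
            c: max(0.0, d * (1.0 + 0.1 * rng.standard_normal()))
            for c, d in _DEFAULT_TROUGH_DEPTH.items()
        }
        for day in days:
            drought = 0.0
            if treat == "WD" and max_day > 0:
                drought = np.clip(max_drought * day / max_day, 0.0, 1.0)
                drought = float(np.clip(drought + 0.05 * rng.standard_normal(), 0, 1))
            for hour in hours:
                # leaf water status fluctuates between observations
                wob = 1.0 + trough_jitter_sd * rng.standard_normal()
                depths = {c: max(0.0, d * wob) for c, d in plant_depth.items()}
                params = LeafSpectrumParams(
                    green_peak_height=float(np.clip(green, 0, 1)),
                    nir_plateau=float(np.clip(nir, 0, 1)),
                    water_trough_depths=depths,
                    drought_level=drought,
                    hour_of_day=hour,
                )
                spec = generate_leaf_spectrum(params, wl)
                if spectral_noise_sd > 0:
                    spec = np.clip(
                        spec + spectral_noise_sd * rng.standard_normal(wl.size), 0, 1
                    )
                rows.append((f"plant_{p:03d}", treat, day, hour))
                spectra.append(spec)
    meta = pd.DataFrame(rows, columns=["plant_id", "treatment", "day", "hour"])
    spec_df = pd.DataFrame(np.asarray(spectra), columns=[float(w) for w in wl])
    return pd.concat([meta, spec_df], axis=1)


def spectra_matrix(table: pd.DataFrame):
    """Split a spectra table into (wavelengths, matrix, metadata)."""
    band_cols = [c for c in table.columns if isinstance(c, float)]
    wl = np.asarray(band_cols, dtype=float)
    meta = table[[c for c in table.columns if not isinstance(c, float)]]
    return wl, table[band_cols].to_numpy(dtype=float), meta


@dataclass
class TraitTable:
    """Trait realizations plus the realized strength of the generating link."""

    data: pd.DataFrame
    generating_r2: float
    link: TraitLinkSpec


def noise_sd_for_r2(index_values: np.ndarray, slope: float, r2: float) -> float:
    """Noise level giving population R² ``r2`` for trait = slope*index + noise."""
    if not 0 < r2 <= 1:
        raise ValueError("r2 must lie in (0, 1]")
    signal_sd = abs(slope) * float(np.std(index_values))
    return signal_sd * np.sqrt((1.0 - r2) / r2)


def generate_trait_table(
    link: TraitLinkSpec, spectra_table: pd.DataFrame, seed: int | None = None
) -> TraitTable:
    """Realize a trait from per-plant spectra through the generating link."""
    wl, X, meta = spectra_matrix(spectra_table)
    expr = (
        link.generating_expression.expression
        if isinstance(link.generating_expression, IndexDefinition)
        else link.generating_expression
    )
    for b in expr.bands():
        lo = b.lo if b.hi is None else b.lo
        hi = b.lo if b.hi is None else b.hi
        if lo < wl[0] - 1 or hi > wl[-1] + 1:
            raise ValueError(
                f"generating band {b!r} absent from spectra grid "
                f"{wl[0]:.0f}-{wl[-1]:.0f} nm"
            )
    idx = np.asarray(compute_index(wl, X, expr), dtype=float)
    rng = np.random.default_rng(link.seed if seed is None else seed)
    noise = rng.normal(0.0, link.noise_sd, idx.size) if link.noise_sd > 0 else 0.0
    trait = link.slope * idx + link.intercept + noise
    out = meta.copy()
    out["index_value"] = idx
    out[link.trait_name] = trait
    signal = link.slope * idx + link.intercept
    denom = float(np.var(trait))
    r2 = float(np.corrcoef(signal, trait)[0, 1] ** 2) if denom > 0 else 1.0
    if link.noise_sd == 0:
        r2 = 1.0
    return TraitTable(out, r2, link)


def confounded_drought_config(drought_level: float = 0.0) -> SceneConfig:
    """Small-scene conditions where illumination masks a drought shift.

    Plants differ in their overall illumination level (the lamp distance and
    canopy height vary plant to plant: ``gain_scene_sd`` = 0.15), which
    inflates the between-plant variance of whole-plant mean reflectance far
    beyond the moderate drought signal at 658 nm.  Light-class conditioning
    on fixed absolute brightness thresholds selects pixels in a narrow
    illumination window and so removes most of that variance.  The reduced
    VNIR grid keeps the bands the pipeline needs (brightness RGB, 551/658 nm,
    red-edge segmentation pair, NIR).
    """
    return SceneConfig(
        lines=64,
        vnir_samples=48,
        swir_samples=44,
        vnir_wavelengths=np.array(
            [492.0, 539.0, 551.0, 651.0, 658.0, 705.0, 750.0, 850.0, 976.0]
        ),
        swir_wavelengths=np.linspace(970.0, 2500.0, 8),
        drought_level=drought_level,
        n_leaves=5,
        gain_min=0.75,
        gain_max=1.25,
        gain_scene_sd=0.15,
        shade_fraction=0.06,
        specular_fraction=0.003,
        leaf_scale_sd=0.02,
    )


def diurnal_slope_profile(
    wavelengths: np.ndarray, drought_level: float = 0.0
) -> np.ndarray:
    """Ground-truth diurnal slope (reflectance fraction per hour) per band."""
    wl = np.asarray(wavelengths, dtype=float)
    slope = np.zeros_like(wl)
    for center, sigma, ww, wd_extra in _DIURNAL_BUMPS:
        slope += (ww + drought_level * wd_extra) / 100.0 * _gauss(wl, center, sigma)
    return slope


def generate_diurnal_series(
    hours: tuple[float, ...] = (8.0, 9.5, 11.0, 12.5, 14.0, 15.5, 17.0, 18.5),
    n_plants_per_treatment: int = 10,
    wavelengths: np.ndarray | None = None,
    wd_drought_level: float = 1.0,
    noise_sd: float = 0.002,
    slope_scale: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Spectra time series over one day for WW and WD plants.

    Per-wavelength trends are linear in the hour with the template's default
    diurnal slopes (scaled by ``slope_scale``; 0 switches the trend off):
    positive in the visible (523/551/658 nm), negative at the red edge, NIR
    and SWIR bands, and steeper under water deficit at 721/976/1694 nm.
    """
    if not hours:
        raise ValueError("hour grid must be non-empty")
    wl = np.asarray(
        default_vnir_grid() if wavelengths is None else wavelengths, dtype=float
    )
    rng = np.random.default_rng(seed)
    rows, spectra = [], []
    for treat, drought in (("WW", 0.0), ("WD", wd_drought_level)):
        for p in range(n_plants_per_treatment):
            for hour in hours:
                params = LeafSpectrumParams(
                    drought_level=drought,
                    hour_of_day=12.0 + slope_scale * (hour - 12.0),
                )
                spec = generate_leaf_spectrum(params, wl)
                if noise_sd > 0:
                    spec = np.clip(spec + noise_sd * rng.standard_normal(wl.size), 0, 1)
                rows.append((f"{treat}_{p:03d}", treat, 6, hour))
                spectra.append(spec)
    meta = pd.DataFrame(rows, columns=["plant_id", "treatment", "day", "hour"])
    spec_df = pd.DataFrame(np.asarray(spectra), columns=[float(w) for w in wl])
    return pd.concat([meta, spec_df], axis=1)
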