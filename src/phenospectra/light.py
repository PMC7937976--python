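"""Brightness-based illumination classification of plant pixels.

Proximal top-view imaging leaves large brightness differences across a plant:
leaves sit at different distances from the lamps, at different inclinations,
shade each other, and glint.  That illumination variation is non-biological
and can drown out treatment effects.  The remedy implemented here bins plant
pixels into five light classes (ex-low, low, intermediate, high, ex-high)
using fixed brightness thresholds derived once from a training set by nested
1-D k-means (k=3, then the low and high clusters re-split k=2), plus a
specular cut-off above which glint pixels are discarded.  Downstream analysis
uses per-plant per-class mean spectra; the intermediate class is the default
analysis class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cube import SpectralCube
from .segment import PlantMask

__all__ = [
    "LIGHT_CLASS_NAMES",
    "SPECULAR_LABEL",
    "RGB_BANDS_NM",
    "LightThresholds",
    "LightClassMap",
    "compute_brightness",
    "derive_light_thresholds",
    "classify_pixels",
    "class_mean_spectra",
    "variance_reduction",
]

#: analysis classes in ascending brightness order; label codes 1..5
LIGHT_CLASS_NAMES = ("ex-low", "low", "intermediate", "high", "ex-high")
#: label code for specular glint (removed from analysis)
SPECULAR_LABEL = 6
BACKGROUND_LABEL = 0

#: blue/green/red band positions used for the brightness proxy
RGB_BANDS_NM = (492.0, 539.0, 651.0)


def compute_brightness(
    cube: SpectralCube, rgb_bands: tuple[float, float, float] = RGB_BANDS_NM
) -> np.ndarray:
    """Brightness image: max of the blue/green/red reflectances per pixel.

    This is the HSV value convention; for vegetation the green band usually
    dominates, so brightness effectively tracks green reflection, the band
    least affected by drought.
    """
    if not cube.calibrated:
        raise ValueError("brightness is computed on calibrated reflectance")
    channels = np.stack([cube.band_image(nm) for nm in rgb_bands], axis=0)
    return channels.max(axis=0)


@dataclass
class LightThresholds:
    """Fixed brightness cut points separating the five light classes.

    ``boundaries`` holds the four interior Voronoi edges (midpoints between
    the five sorted k-means centroids); ``specular_cut`` is the glint
    cut-off.  ``provenance`` records how the thresholds were derived.
    """

    boundaries: np.ndarray
    specular_cut: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.size != len(LIGHT_CLASS_NAMES) - 1:
            raise ValueError("expected one boundary per adjacent class pair")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.specular_cut < self.boundaries[-1]:
            raise ValueError("specular_cut must sit above the top boundary")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "boundaries": self.boundaries.tolist(),
                "specular_cut": self.specular_cut,
                "provenance": self.provenance,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "LightThresholds":
        p = Path(text_or_path) if not str(text_or_path).lstrip().startswith("{") else None
        d = json.loads(p.read_text() if p else text_or_path)
        return cls(np.asarray(d["boundaries"]), d["specular_cut"], d["provenance"])


def _kmeans_1d(values: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    km.fit(values.reshape(-1, 1))
    return np.sort(km.cluster_centers_.ravel())


def derive_light_thresholds(
    brightness_samples: np.ndarray, seed: int = 0
) -> LightThresholds:
    """Derive fixed class thresholds from pooled training brightness values.

    Nested clustering: k=3 splits the training pixels into low / intermediate /
    high light; the low and high clusters are each re-split k=2 into ex-low /
    low and high / ex-high.  Boundaries are midpoints between adjacent sorted
    centroids, and the specular cut is the 99.5th percentile of the ex-high
    cluster's brightness.
    """
    b = np.asarray(brightness_samples, dtype=float).ravel()
    b = b[np.isfinite(b)]
    if b.size < 1000:
        raise ValueError("need at least 1000 training pixels")
    if np.ptp(b) == 0:
        raise ValueError("degenerate training data: brightness is constant")
    c3 = _kmeans_1d(b, 3, seed)
    edges3 = (c3[:-1] + c3[1:]) / 2.0
    low = b[b <= edges3[0]]
    high = b[b > edges3[1]]
    c_low = _kmeans_1d(low, 2, seed) if np.ptp(low) > 0 else np.array([c3[0], c3[0]])
    c_high = _kmeans_1d(high, 2, seed) if np.ptp(high) > 0 else np.array([c3[2], c3[2]])
    centroids = np.sort(np.concatenate([c_low, [c3[1]], c_high]))
    boundaries = (centroids[:-1] + centroids[1:]) / 2.0
    if np.any(np.diff(boundaries) <= 0):  # merged sub-clusters: nudge apart
        eps = 1e-9 * max(np.ptp(b), 1.0)
        for i in range(1, boundaries.size):
            boundaries[i] = max(boundaries[i], boundaries[i - 1] + eps)
    ex_high = b[b > boundaries[-1]]
    specular_cut = float(
        np.percentile(ex_high, 99.5) if ex_high.size else boundaries[-1]
    )
    specular_cut = max(specular_cut, float(boundaries[-1]))
    return LightThresholds(
        boundaries,
        specular_cut,
        provenance={
            "n_pixels": int(b.size),
            "centroids": centroids.tolist(),
            "seed": seed,
        },
    )


@dataclass
class LightClassMap:
    """Per-pixel labels: 0 background, 1..5 light classes, 6 specular."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)

    def class_mask(self, name: str) -> np.ndarray:
        if name == "specular":
            return self.labels == SPECULAR_LABEL
        return self.labels == LIGHT_CLASS_NAMES.index(name) + 1

    def counts(self) -> dict[str, int]:
        out = {n: int(np.sum(self.labels == i + 1))
               for i, n in enumerate(LIGHT_CLASS_NAMES)}
        out["specular"] = int(np.sum(self.labels == SPECULAR_LABEL))
        return out


def classify_pixels(
    brightness: np.ndarray,
    plant_mask: PlantMask | np.ndarray,
    thresholds: LightThresholds,
) -> LightClassMap:
    """Bin plant pixels into the five light classes plus specular.

    The partition is exhaustive and exclusive: every plant pixel gets exactly
    one label; everything off the plant mask is background.
    """
    b = np.asarray(brightness, dtype=float)
    mask = plant_mask.labels if isinstance(plant_mask, PlantMask) else np.asarray(
        plant_mask, bool
    )
    if b.shape != mask.shape:
        raise ValueError("brightness and plant mask shapes differ")
    labels = np.zeros(b.shape, dtype=np.int8)
    bins = np.searchsorted(thresholds.boundaries, b[mask], side="left") + 1
    labels[mask] = bins
    spec = mask & (b > thresholds.specular_cut)
    labels[spec] = SPECULAR_LABEL
    return LightClassMap(labels)


def class_mean_spectra(
    cube: SpectralCube,
    classmap: LightClassMap,
    plant_id: str = "plant",
    timestamp=None,
    treatment: str | None = None,
) -> pd.DataFrame:
    """Per-class mean spectrum records for one plant.

    One row per populated class.  Specular rows are emitted with
    ``analysis=False`` (counted, excluded from analysis); the pixel-count-
    weighted mean of all emitted class means equals the whole-plant mean.
    Long-format columns: plant_id, light_class, analysis, pixel_count,
    timestamp, treatment, then one column per wavelength.
    """
    if classmap.labels.shape != cube.values.shape[:2]:
        raise ValueError("class map shape does not match cube")
    if not np.any(classmap.labels > 0):
        raise ValueError("empty plant mask: no classified pixels")
    rows = []
    flat = cube.values.reshape(-1, cube.n_bands)
    lab = classmap.labels.ravel()
    for code, name in list(enumerate(LIGHT_CLASS_NAMES, start=1)) + [
        (SPECULAR_LABEL, "specular")
    ]:
        sel = lab == code
        n = int(sel.sum())
        if n == 0:
            continue
        mean = flat[sel].mean(axis=0)
        rows.append(
            {
                "plant_id": plant_id,
                "light_class": name,
                "analysis": name != "specular",
                "pixel_count": n,
                "timestamp": timestamp,
                "treatment": treatment,
                **{float(w): v for w, v in zip(cube.wavelengths, mean)},
            }
        )
    return pd.DataFrame(rows)


def variance_reduction(cube: SpectralCube, classmap: LightClassMap) -> float:
    """Fraction of within-plant reflectance variance removed by classification.

    Per band: 1 - (pixel-weighted mean within-class variance)/(whole-plant
    variance); the reported value is the average over bands.  Needs at least
    two populated (non-specular) classes and non-zero whole-plant variance.
    """
    lab = classmap.labels.ravel()
    flat = cube.values.reshape(-1, cube.n_bands)
    analysis = (lab >= 1) & (lab <= len(LIGHT_CLASS_NAMES))
    codes = np.unique(lab[analysis])
    if codes.size < 2:
        raise ValueError("need at least two populated light classes")
    plant_vals = flat[analysis]
    total_var = plant_vals.var(axis=0)
    if np.all(total_var == 0):
        raise ValueError("whole-plant variance is zero")
    within = np.zeros(cube.n_bands)
    for code in codes:
        sel = lab == code
        within += sel.sum() * flat[sel].var(axis=0)
    within /= analysis.sum()
    ok = total_var > 0
    return float(np.mean(1.0 - within[ok] / total_var[ok]))
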