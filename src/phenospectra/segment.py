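"""Plant segmentation and VNIR->SWIR co-registration.

VNIR plant pixels are found with a red-edge normalized difference index
(bands 705 and 750 nm, threshold 0.35); SWIR plant pixels with a random-forest
pixel classifier trained on labelled cubes.  The two sensors view the same
scene through different optics, so VNIR masks are mapped onto the SWIR grid
with an affine transform fitted by least squares to corresponding control
points (chessboard corners in the original calibration procedure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .cube import SpectralCube

__all__ = [
    "PlantMask",
    "RegistrationTransform",
    "PixelClassifier",
    "red_edge_nvi",
    "segment_vnir",
    "train_swir_classifier",
    "segment_swir",
    "fit_registration",
    "warp_mask",
]

RED_EDGE_BANDS_NM = (705.0, 750.0)
VNIR_SEGMENTATION_THRESHOLD = 0.35


@dataclass
class PlantMask:
    labels: np.ndarray  # boolean, lines x samples
    source_sensor: str = "VNIR"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2-D (lines x samples)")


@dataclass
class RegistrationTransform:
    """Affine pixel mapping s' = a s + b l + c, l' = d s + e l + f.

    Coordinates are 0-based (sample, line) with pixel centres at integers.
    """

    sample_coeffs: tuple[float, float, float]
    line_coeffs: tuple[float, float, float]
    rmse_fit: float = 0.0

    def __post_init__(self) -> None:
        a, b, _ = self.sample_coeffs
        d, e, _ = self.line_coeffs
        if abs(a * e - b * d) < 1e-12:
            raise ValueError("degenerate (non-invertible) transform")

    def apply(self, s, l):
        a, b, c = self.sample_coeffs
        d, e, f = self.line_coeffs
        return a * s + b * l + c, d * s + e * l + f

    def inverse(self) -> "RegistrationTransform":
        a, b, c = self.sample_coeffs
        d, e, f = self.line_coeffs
        det = a * e - b * d
        return RegistrationTransform(
            (e / det, -b / det, (b * f - e * c) / det),
            (-d / det, a / det, (d * c - a * f) / det),
        )


def red_edge_nvi(cube: SpectralCube) -> np.ndarray:
    """Red-edge NDVI image: (rho750 - rho705)/(rho750 + rho705).

    Green vegetation scores roughly 0.2-0.9; the nearest grid bands to 705 and
    750 nm are used.  Zero-denominator pixels come out NaN.
    """
    if not cube.calibrated:
        raise ValueError("red-edge NDVI needs a calibrated cube")
    r705 = cube.band_image(RED_EDGE_BANDS_NM[0])
    r750 = cube.band_image(RED_EDGE_BANDS_NM[1])
    denom = r750 + r705
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (r750 - r705) / denom
    out = np.where(denom == 0, np.nan, out)
    return out


def segment_vnir(
    cube: SpectralCube, threshold: float = VNIR_SEGMENTATION_THRESHOLD
) -> PlantMask:
    """Plant pixels = red-edge NDVI strictly above the threshold (NaN excluded)."""
    idx = red_edge_nvi(cube)
    with np.errstate(invalid="ignore"):
        labels = idx > threshold
    return PlantMask(labels, "VNIR")


@dataclass
class PixelClassifier:
    """Random-forest plant/background pixel classifier for SWIR spectra."""

    model: RandomForestClassifier
    feature_bands: np.ndarray
    n_train_per_class: dict[str, int]
    seed: int
    holdout_accuracy: float = float("nan")

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        return self.model.predict(spectra).astype(bool)


def train_swir_classifier(
    cubes: list[SpectralCube],
    truth_masks: list[np.ndarray],
    seed: int = 0,
    n_estimators: int = 100,
    max_pixels_per_class: int = 5000,
    holdout_fraction: float = 0.25,
) -> PixelClassifier:
    """Train the plant/background forest on labelled SWIR cubes.

    Pixels are pooled over cubes and subsampled per class; a held-out fraction
    reports the confusion-matrix accuracy.  Requires at least two cubes and
    both classes present.
    """
    if len(cubes) < 2:
        raise ValueError("need at least 2 labelled cubes")
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for cube, mask in zip(cubes, truth_masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != cube.values.shape[:2]:
            raise ValueError("truth mask shape does not match cube")
        flat = cube.values.reshape(-1, cube.n_bands)
        labels = mask.ravel()
        X_parts.append(flat)
        y_parts.append(labels)
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    keep = []
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        if idx.size > max_pixels_per_class:
            idx = rng.choice(idx, size=max_pixels_per_class, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    X, y = X[keep], y[keep]
    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    model.fit(X_tr, y_tr)
    acc = float(np.mean(model.predict(X_ho) == y_ho))
    counts = {"background": int((~y).sum()), "plant": int(y.sum())}
    return PixelClassifier(model, cubes[0].wavelengths.copy(), counts, seed, acc)


def segment_swir(cube: SpectralCube, classifier: PixelClassifier) -> PlantMask:
    """Per-pixel plant/background prediction over a SWIR cube."""
    flat = cube.values.reshape(-1, cube.n_bands)
    labels = classifier.predict(flat).reshape(cube.lines, cube.samples)
    return PlantMask(labels, "SWIR")


def fit_registration(points_src, points_dst) -> RegistrationTransform:
    """Least-squares affine fit from >= 3 non-collinear (sample, line) pairs."""
    src = np.asarray(points_src, dtype=float)
    dst = np.asarray(points_dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("point lists must both be (n, 2) arrays")
    if src.shape[0] < 3:
        raise ValueError("need at least 3 point pairs")
    A = np.column_stack([src[:, 0], src[:, 1], np.ones(src.shape[0])])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("control points are collinear")
    coef_s, *_ = np.linalg.lstsq(A, dst[:, 0], rcond=None)
    coef_l, *_ = np.linalg.lstsq(A, dst[:, 1], rcond=None)
    pred = A @ np.column_stack([coef_s, coef_l])
    rmse = float(np.sqrt(np.mean(np.sum((pred - dst) ** 2, axis=1))))
    return RegistrationTransform(tuple(coef_s), tuple(coef_l), rmse)


def warp_mask(
    mask: PlantMask | np.ndarray,
    transform: RegistrationTransform,
    target_shape: tuple[int, int],
) -> PlantMask:
    """Resample a boolean mask onto the target grid (nearest neighbour).

    Uses pull-back sampling through the inverse transform; exact half-pixel
    ties round toward the lower index; out-of-bounds pixels are background.
    """
    labels = mask.labels if isinstance(mask, PlantMask) else np.asarray(mask, bool)
    inv = transform.inverse()
    tl, ts = np.mgrid[0 : target_shape[0], 0 : target_shape[1]]
    src_s, src_l = inv.apply(ts.astype(float), tl.astype(float))
    si = np.ceil(src_s - 0.5).astype(int)  # round half down
    li = np.ceil(src_l - 0.5).astype(int)
    inside = (si >= 0) & (si < labels.shape[1]) & (li >= 0) & (li < labels.shape[0])
    out = np.zeros(target_shape, dtype=bool)
    out[inside] = labels[li[inside], si[inside]]
    sensor = mask.source_sensor if isinstance(mask, PlantMask) else "VNIR"
    return PlantMask(out, sensor)
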