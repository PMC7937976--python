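"""Hyperspectral cube container, ENVI I/O and reflectance calibration.

A pushbroom line scanner builds an image line by line; each exposure records one
spatial line across all spectral bands.  Raw digital numbers are converted to
relative reflectance with a white reference surface (scanned at the plant's
height) and a dark reference (shutter closed):

    rho = (raw - dark) / (white - dark)

applied per sample column and per band, which removes pixel-to-pixel sensor
response differences and spatial non-uniformity of the illumination along the
scan line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpectralCube",
    "ReferencePair",
    "read_envi_cube",
    "write_envi_cube",
    "calibrate_reflectance",
    "bin_spectral",
]

# ENVI numeric "data type" codes <-> numpy dtypes (little-endian, byte order 0)
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class SpectralCube:
    """Line-scan image: ``values[line, sample, band]`` with per-band wavelengths.

    ``calibrated`` distinguishes raw digital numbers from reflectance fractions.
    Reflectance is stored as a fraction in [0, 1]; conversion to percent happens
    only at presentation time.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    sensor_id: str = "VNIR"
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be lines x samples x bands")
        if self.values.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band count {self.values.shape[2]} does not match "
                f"{self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size > 1 and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def lines(self) -> int:
        return self.values.shape[0]

    @property
    def samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def band_index(self, nm: float) -> int:
        """Index of the band nearest to ``nm`` (error outside the covered range)."""
        w = self.wavelengths
        half_step = 0.5 * float(np.median(np.diff(w))) if w.size > 1 else 0.0
        if nm < w[0] - half_step or nm > w[-1] + half_step:
            raise ValueError(
                f"{nm} nm outside {self.sensor_id} range {w[0]:.0f}-{w[-1]:.0f} nm"
            )
        return int(np.argmin(np.abs(w - nm)))

    def band_image(self, nm: float) -> np.ndarray:
        return self.values[:, :, self.band_index(nm)]


@dataclass
class ReferencePair:
    """White/dark reference frames, per (sample, band).

    ``invalid_mask`` flags reference pixels whose dynamic range ``white - dark``
    is at or below the guard ``eps`` (a fraction of the global dynamic range);
    calibrated values there are reported missing instead of exploding.
    """

    white: np.ndarray
    dark: np.ndarray
    eps_fraction: float = 1e-6
    invalid_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must share a shape")
        span = float(np.max(self.white - self.dark, initial=0.0))
        eps = self.eps_fraction * max(span, 0.0)
        self.invalid_mask = (self.white - self.dark) <= eps


def calibrate_reflectance(raw: SpectralCube, refs: ReferencePair) -> SpectralCube:
    """Convert raw counts to relative reflectance ``(raw - dark)/(white - dark)``.

    The references are applied per sample column (pushbroom geometry).  Pixels
    under ``refs.invalid_mask`` become NaN.  Raises on already-calibrated input
    or an all-invalid reference pair.
    """
    if raw.calibrated:
        raise ValueError("cube is already calibrated")
    if refs.white.shape != (raw.samples, raw.n_bands):
        raise ValueError(
            f"reference shape {refs.white.shape} does not match cube "
            f"(samples, bands)=({raw.samples}, {raw.n_bands})"
        )
    if np.all(refs.invalid_mask):
        raise ValueError("all reference pixels invalid (white <= dark everywhere)")
    denom = (refs.white - refs.dark)[np.newaxis, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (raw.values.astype(float) - refs.dark[np.newaxis]) / denom
    rho[:, refs.invalid_mask] = np.nan
    return SpectralCube(rho, raw.wavelengths, raw.sensor_id, calibrated=True)


def bin_spectral(cube: SpectralCube, factor: int) -> SpectralCube:
    """Average ``factor`` consecutive bands (sensor-style spectral binning).

    A trailing remainder of fewer than ``factor`` bands is dropped.  Output
    wavelengths are the means of the member wavelengths.
    """
    if factor <= 0:
        raise ValueError("binning factor must be >= 1")
    if factor == 1:
        return cube
    n_out = cube.n_bands // factor
    if n_out == 0:
        raise ValueError("binning factor exceeds band count")
    keep = n_out * factor
    vals = cube.values[:, :, :keep].reshape(cube.lines, cube.samples, n_out, factor)
    wl = cube.wavelengths[:keep].reshape(n_out, factor)
    return SpectralCube(
        vals.mean(axis=3), wl.mean(axis=1), cube.sensor_id, cube.calibrated
    )


# --------------------------------------------------------------------------
# ENVI I/O (header text file + flat binary in BIL/BSQ/BIP interleave)
# --------------------------------------------------------------------------

def write_envi_cube(cube: SpectralCube, path: str | Path, interleave: str = "bil",
                    dtype: str = "float64") -> Path:
    """Write a cube as an ENVI binary image with a ``.hdr`` sidecar.

    ``path`` is the binary file; the header is written next to it.
    """
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    path = Path(path)
    arr = np.ascontiguousarray(cube.values, dtype=np.dtype(dtype))
    code = _DTYPE_CODES[arr.dtype]
    # internal layout is (line, sample, band) == BIP ordering
    if interleave == "bil":
        out = arr.transpose(0, 2, 1)
    elif interleave == "bsq":
        out = arr.transpose(2, 0, 1)
    else:
        out = arr
    out.tofile(path)
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"description = {{{cube.sensor_id} cube, "
        f"calibrated = {int(cube.calibrated)}}}\n"
        f"samples = {cube.samples}\n"
        f"lines = {cube.lines}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"sensor type = {cube.sensor_id}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(hdr)
    return path


def _parse_envi_header(text: str) -> dict:
    # collapse {...} blocks onto one line, then parse key = value pairs
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi_cube(path: str | Path) -> SpectralCube:
    """Read an ENVI cube written by :func:`write_envi_cube` or compatible tools."""
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"no ENVI header found for {path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields.get("interleave", "bil").lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header missing field {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing wavelength metadata")
    wl = np.array(
        [float(x) for x in fields["wavelength"].strip("{} ").split(",") if x.strip()]
    )
    if wl.size != bands:
        raise ValueError(f"header lists {wl.size} wavelengths for {bands} bands")
    dtype = np.dtype(_ENVI_DTYPES[code])
    offset = int(fields.get("header offset", 0))
    data = np.fromfile(path, dtype=dtype, offset=offset)
    if data.size != lines * samples * bands:
        raise ValueError(
            f"file holds {data.size} values, header implies {lines * samples * bands}"
        )
    if interleave == "bil":
        arr = data.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        arr = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bip":
        arr = data.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    sensor = fields.get("sensor type", "VNIR").upper()
    calibrated = "calibrated = 1" in fields.get("description", "")
    return SpectralCube(np.ascontiguousarray(arr), wl, sensor, calibrated)
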