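"""Emission and reflectance spectra, chromaticity, and sRGB rendering.

The measurement model of the strip reader is: a lamp with spectral power
distribution P(lambda) illuminates the reacted test paper with reflectance
R(lambda); the camera sees the product P(lambda) * R(lambda) and integrates it
against per-channel sensitivities into linear RGB signals, which the image
file stores sRGB-encoded as 8-bit counts.

Three stylised lamp presets are provided, matching the peak wavelengths and
wavelength ranges of the deuterium arc (D2) lamp, halogen (H2) lamp and
Mini-LED sources used for strip imaging:

``d2``
    narrow UV emission peaked at 238.8 nm plus deuterium's structured visible
    output (blue continuum, a cyan band, and a red emission feature near the
    Balmer/Fulcher region), support 190-780 nm;
``h2``
    smooth thermal (Planck) curve peaked at 583.8 nm, support 380-930 nm;
``mini_led``
    small blue pump lobe near 450 nm plus a dominant phosphor lobe peaked at
    580.4 nm, support 380-780 nm.

Chromaticity uses the CIE 1931 2-degree standard observer.  The packaged
colour-matching-function table (``data/cie1931_cmf_2deg_synthetic.csv``) is a
synthetic stand-in generated from the Wyman-Sloan-Shirley multi-lobe Gaussian
analytic approximation; its equal-energy white point agrees with (1/3, 1/3)
to better than 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateSpectrumError,
    NoOverlapError,
    PresetNotFoundError,
)

__all__ = [
    "SpectralPowerDistribution",
    "ReflectanceSpectrum",
    "CameraResponse",
    "Chromaticity",
    "spd_preset",
    "peak_wavelength",
    "spectral_product",
    "cie_xy",
    "spd_to_srgb",
    "srgb_encode",
    "srgb_decode",
    "default_camera",
    "load_cmf",
    "load_spectrum_csv",
    "save_spectrum_csv",
    "VISIBLE_GRID_NM",
]

#: Internal 1-nm visible-band grid used for all radiometric integrals.
VISIBLE_GRID_NM = np.arange(380.0, 781.0, 1.0)

_CMF_RESOURCE = "cie1931_cmf_2deg_synthetic.csv"


def _as_grid(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    return arr


@dataclass(frozen=True)
class SpectralPowerDistribution:
    """Relative emission power per wavelength, on a strictly increasing grid."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    name: str = ""

    def __post_init__(self):
        w = _as_grid(self.wavelengths_nm, "wavelengths_nm")
        i = _as_grid(self.intensities, "intensities")
        if w.size != i.size:
            raise ValueError("wavelengths_nm and intensities must have equal length")
        if w.size > 1 and not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "intensities", i)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def resample(self, grid_nm: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``grid_nm``; zero outside the support."""
        return np.interp(grid_nm, self.wavelengths_nm, self.intensities,
                         left=0.0, right=0.0)


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Fraction of incident light reflected per wavelength, in [0, 1]."""

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        w = _as_grid(self.wavelengths_nm, "wavelengths_nm")
        r = _as_grid(self.reflectance, "reflectance")
        if w.size != r.size:
            raise ValueError("wavelengths_nm and reflectance must have equal length")
        if w.size > 1 and not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if np.any((r < 0) | (r > 1)):
            raise ValueError("reflectance must lie in [0, 1]")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "reflectance", r)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def resample(self, grid_nm: np.ndarray) -> np.ndarray:
        return np.interp(grid_nm, self.wavelengths_nm, self.reflectance,
                         left=0.0, right=0.0)


@dataclass(frozen=True)
class CameraResponse:
    """Per-channel spectral sensitivities plus an exposure scale.

    ``exposure_scale`` maps the integrated linear signal to the [0, 1]
    linear-light range before sRGB encoding; it is the single free
    radiometric parameter and is normally set by
    :func:`bilistrip.synthetic.calibrated_exposure`.
    """

    wavelengths_nm: np.ndarray
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    exposure_scale: float = 1.0

    def __post_init__(self):
        w = _as_grid(self.wavelengths_nm, "wavelengths_nm")
        chans = []
        for nm, ch in (("red", self.red), ("green", self.green), ("blue", self.blue)):
            c = _as_grid(ch, nm)
            if c.size != w.size:
                raise ValueError(f"{nm} sensitivity length mismatch")
            if np.any(c < 0):
                raise ValueError(f"{nm} sensitivity must be non-negative")
            chans.append(c)
        if w.size > 1 and not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", w)
        for nm, c in zip(("red", "green", "blue"), chans):
            object.__setattr__(self, nm, c)
        vis = (w >= 380.0) & (w <= 780.0)
        for nm, c in zip(("red", "green", "blue"), chans):
            if not np.any(vis) or np.trapezoid(c[vis], w[vis]) <= 0:
                raise ValueError(f"{nm} sensitivity must integrate to a positive "
                                 "value over 380-780 nm")

    def channels(self):
        return {"R": self.red, "G": self.green, "B": self.blue}

    def resample(self, grid_nm: np.ndarray) -> dict[str, np.ndarray]:
        return {k: np.interp(grid_nm, self.wavelengths_nm, v, left=0.0, right=0.0)
                for k, v in self.channels().items()}

    def with_exposure(self, exposure_scale: float) -> "CameraResponse":
        return CameraResponse(self.wavelengths_nm, self.red, self.green,
                              self.blue, exposure_scale)


@dataclass(frozen=True)
class Chromaticity:
    """CIE 1931 (x, y) chromaticity coordinates."""

    x: float
    y: float

    def __post_init__(self):
        if not (self.x >= 0 and self.y > 0 and self.x + self.y <= 1 + 1e-12):
            raise ValueError(f"invalid chromaticity ({self.x}, {self.y})")


def _gauss(lam: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - mu) / sigma) ** 2)


def _supergauss(lam: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    # quartic super-Gaussian: flat-ish top, fast-decaying tails
    return np.exp(-(((lam - mu) / sigma) ** 4))


def _grid_with(lo: float, hi: float, extra: float) -> np.ndarray:
    """1-nm grid over [lo, hi] with ``extra`` inserted as an exact sample."""
    g = np.arange(lo, hi + 0.5, 1.0)
    return np.unique(np.concatenate([g, [extra]]))


# Position of the D2 cyan band, calibrated once so that the rendered
# noiseless green-channel series under the D2 preset follows the shallow
# D2 calibration line; see bilistrip.synthetic.
_D2_CYAN_MU_NM = 540.03


def spd_preset(name: str) -> SpectralPowerDistribution:
    """Parametric synthetic lamp spectrum for ``d2``, ``h2`` or ``mini_led``.

    Each preset reproduces the catalogued peak wavelength and wavelength
    range of the corresponding physical source (D2: 238.8 nm / 190-780 nm;
    H2: 583.8 nm / 380-930 nm; Mini-LED: 580.4 nm / 380-780 nm).  The peak
    wavelength is inserted as an exact grid sample so that
    :func:`peak_wavelength` returns it exactly.
    """
    key = str(name).lower()
    if key == "mini_led":
        lam = _grid_with(380.0, 780.0, 580.4)
        inten = 0.28 * _gauss(lam, 450.0, 10.0) + _gauss(lam, 580.4, 55.0)
        return SpectralPowerDistribution(lam, inten, name="mini_led")
    if key == "h2":
        lam = _grid_with(380.0, 930.0, 583.8)
        # Planck radiator whose spectral peak sits at 583.8 nm
        T = 2.8977719e6 / 583.8
        h, c, kB = 6.62607015e-34, 2.99792458e8, 1.380649e-23
        lm = lam * 1e-9
        inten = 1.0 / (lm ** 5 * (np.exp(h * c / (lm * kB * T)) - 1.0))
        return SpectralPowerDistribution(lam, inten / inten.max(), name="h2")
    if key == "d2":
        lam = _grid_with(190.0, 780.0, 238.8)
        inten = (_gauss(lam, 238.8, 7.0)
                 + 0.30 * _gauss(lam, 432.0, 28.0)
                 + 0.75 * _supergauss(lam, _D2_CYAN_MU_NM, 18.0)
                 + 0.18 * _gauss(lam, 596.0, 6.0))
        return SpectralPowerDistribution(lam, inten, name="d2")
    raise PresetNotFoundError(f"unknown light-source preset {name!r}; "
                              "expected one of 'd2', 'h2', 'mini_led'")


def peak_wavelength(spd: SpectralPowerDistribution) -> float:
    """Grid wavelength of maximum intensity; ties break to the smallest."""
    if not np.any(spd.intensities > 0):
        raise DegenerateSpectrumError("all-zero spectrum has no peak")
    return float(spd.wavelengths_nm[int(np.argmax(spd.intensities))])


def _common_grid(a, b) -> np.ndarray:
    lo = max(a.support[0], b.support[0])
    hi = min(a.support[1], b.support[1])
    if lo > hi:
        raise NoOverlapError(
            f"wavelength ranges {a.support} and {b.support} do not overlap")
    pts = np.concatenate([a.wavelengths_nm, b.wavelengths_nm])
    pts = pts[(pts >= lo) & (pts <= hi)]
    return np.unique(pts)


def spectral_product(p: SpectralPowerDistribution,
                     r: ReflectanceSpectrum) -> SpectralPowerDistribution:
    """Pointwise product P(lambda) * R(lambda) on the common grid.

    This is the spectrum the camera actually sees: the lamp emission
    filtered by the reacted test paper's reflectance.  Both inputs are
    linearly interpolated onto the union of their sample wavelengths
    restricted to the overlapping range.
    """
    grid = _common_grid(p, r)
    out = p.resample(grid) * r.resample(grid)
    return SpectralPowerDistribution(grid, out,
                                     name=f"{p.name}*reflectance" if p.name else "")


def load_cmf() -> tuple[np.ndarray, np.ndarray]:
    """Packaged CIE 1931 2-degree CMF table on the 1-nm visible grid.

    Returns ``(wavelengths_nm, cmf)`` with ``cmf`` of shape (n, 3) holding
    xbar, ybar, zbar columns.
    """
    with resources.files("bilistrip.data").joinpath(_CMF_RESOURCE).open("rb") as fh:
        raw = np.genfromtxt(fh, delimiter=",", skip_header=1)
    return raw[:, 0], raw[:, 1:4]


_CMF_CACHE: tuple[np.ndarray, np.ndarray] | None = None


def _cmf() -> tuple[np.ndarray, np.ndarray]:
    global _CMF_CACHE
    if _CMF_CACHE is None:
        _CMF_CACHE = load_cmf()
    return _CMF_CACHE


def cie_xy(spd: SpectralPowerDistribution) -> Chromaticity:
    """CIE 1931 (x, y) chromaticity of an emission spectrum.

    Tristimulus X, Y, Z are trapezoidal integrals of the spectrum against
    the packaged 2-degree observer on the 1-nm grid; the spectrum is
    linearly interpolated, with zero power outside its support.
    """
    lam, cmf = _cmf()
    s = spd.resample(lam)
    X, Y, Z = (np.trapezoid(s * cmf[:, k], lam) for k in range(3))
    total = X + Y + Z
    if total <= 0:
        raise DegenerateSpectrumError("no visible-band power in 380-780 nm")
    return Chromaticity(float(X / total), float(Y / total))


def srgb_encode(linear):
    """Linear light in [0, 1] -> sRGB-encoded value in [0, 1]."""
    v = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    out = np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1 / 2.4) - 0.055)
    return out if out.ndim else float(out)


def srgb_decode(encoded):
    """sRGB-encoded value in [0, 1] -> linear light in [0, 1]."""
    v = np.asarray(encoded, dtype=float)
    out = np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)
    return out if out.ndim else float(out)


def _linear_rgb(spd: SpectralPowerDistribution, cam: CameraResponse) -> np.ndarray:
    """Exposure-scaled linear channel signals (unclipped)."""
    if cam.exposure_scale <= 0:
        raise ConfigurationError("exposure_scale must be positive")
    lo = max(spd.support[0], float(cam.wavelengths_nm[0]), 380.0)
    hi = min(spd.support[1], float(cam.wavelengths_nm[-1]), 780.0)
    if lo > hi:
        raise NoOverlapError("spectrum and camera response do not overlap")
    grid = VISIBLE_GRID_NM[(VISIBLE_GRID_NM >= lo) & (VISIBLE_GRID_NM <= hi)]
    if grid.size < 2:
        grid = np.array([lo, hi]) if hi > lo else np.array([lo])
    s = spd.resample(grid)
    sens = cam.resample(grid)
    if grid.size == 1:
        sig = np.array([s[0] * sens[ch][0] for ch in "RGB"])
    else:
        sig = np.array([np.trapezoid(s * sens[ch], grid) for ch in "RGB"])
    return cam.exposure_scale * sig


def spd_to_srgb(spd: SpectralPowerDistribution, cam: CameraResponse) -> np.ndarray:
    """Render a spectrum to an 8-bit sRGB triple through the camera model.

    Per channel: linear signal = trapezoidal integral of spectrum times
    sensitivity, scaled by ``exposure_scale``, clipped to [0, 1], sRGB
    encoded and quantised to 0-255 with round-half-up.
    """
    counts = 255.0 * srgb_encode(np.clip(_linear_rgb(spd, cam), 0.0, 1.0))
    return np.floor(counts + 0.5).astype(np.uint8)


def default_camera(exposure_scale: float = 1.0) -> CameraResponse:
    """Stylised three-channel camera with Gaussian sensitivities.

    Channels are centred at 620 / 540 / 435 nm with 40 / 40 / 30 nm FWHM.
    The red band sits on the long-wave shoulder of the biliverdin
    absorption band and the blue band inside the violet absorption band,
    which reproduces the strongly saturating red/blue responses observed
    for the real strips; only relative channel behaviour matters for the
    pipeline.
    """
    lam = VISIBLE_GRID_NM
    f = 2.0 * np.sqrt(2.0 * np.log(2.0))
    return CameraResponse(
        lam,
        _gauss(lam, 620.0, 40.0 / f),
        _gauss(lam, 540.0, 40.0 / f),
        _gauss(lam, 435.0, 30.0 / f),
        exposure_scale,
    )


def load_spectrum_csv(path, kind: str = "spd"):
    """Read a two-column ``wavelength_nm,value`` CSV.

    ``kind`` selects the returned type: ``"spd"`` for an emission spectrum,
    ``"reflectance"`` for a reflectance spectrum.
    """
    arr = np.genfromtxt(Path(path), delimiter=",", skip_header=1)
    arr = np.atleast_2d(arr)
    if kind == "spd":
        return SpectralPowerDistribution(arr[:, 0], arr[:, 1], name=Path(path).stem)
    if kind == "reflectance":
        return ReflectanceSpectrum(arr[:, 0], arr[:, 1])
    raise ValueError(f"unknown spectrum kind {kind!r}")


def save_spectrum_csv(path, spectrum) -> None:
    """Write a spectrum as a two-column ``wavelength_nm,value`` CSV."""
    values = (spectrum.intensities if isinstance(spectrum, SpectralPowerDistribution)
              else spectrum.reflectance)
    with open(path, "w") as fh:
        fh.write("wavelength_nm,value\n")
        for w, v in zip(spectrum.wavelengths_nm, values):
            fh.write(f"{w:g},{v:.8g}\n")
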