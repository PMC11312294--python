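"""Deterministic color-science core.

Everything downstream (camera calibration, spectral reconstruction,
narrow-band synthesis) is built on the CIE 1931 colorimetric system:

* the sRGB electro-optical transfer function (piecewise linear/power law),
* the fixed sRGB/D65 primary matrix between linear RGB and XYZ,
* CIE L*a*b* against an explicit reference white,
* integration of reflectance spectra against an illuminant and the
  standard-observer color-matching functions, and
* the CIEDE2000 perceptual color difference (the quantity the narrow-band
  mapping fit minimizes).

Conventions: tristimulus XYZ is kept on the 0-100 luminance scale (the
reference white has Y = 100); spectra live on a uniform wavelength grid
covering 380-780 nm.  All operations are vectorized over leading axes, so a
"color" argument may be a single triplet or an (H, W, 3) image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthGrid",
    "DEFAULT_GRID",
    "GridMismatchError",
    "srgb_decode",
    "srgb_encode",
    "linear_rgb_to_xyz",
    "xyz_to_linear_rgb",
    "xyz_to_lab",
    "lab_to_xyz",
    "spectrum_to_xyz",
    "ciede2000",
    "SRGB_TO_XYZ",
    "XYZ_TO_SRGB",
]


class GridMismatchError(ValueError):
    """Raised when spectra that must share a wavelength grid do not."""


@dataclass(frozen=True)
class WavelengthGrid:
    """A uniform wavelength axis in nanometres, inclusive of both ends."""

    start_nm: float = 380.0
    stop_nm: float = 780.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not (self.start_nm < self.stop_nm):
            raise ValueError("start_nm must be below stop_nm")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        n = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError("step_nm must divide the interval evenly")

    def __len__(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(len(self))

    def resample(self, wavelength_nm: np.ndarray, values: np.ndarray) -> np.ndarray:
        """Linearly interpolate a tabulated curve onto this grid.

        Outside the tabulated range the end values are held constant.
        ``values`` may be 1-D or (n, k); interpolation runs along axis 0.
        """
        wavelength_nm = np.asarray(wavelength_nm, dtype=float)
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            return np.interp(self.wavelengths, wavelength_nm, values)
        return np.stack(
            [np.interp(self.wavelengths, wavelength_nm, values[:, j]) for j in range(values.shape[1])],
            axis=1,
        )


DEFAULT_GRID = WavelengthGrid(380.0, 780.0, 1.0)

# sRGB (IEC 61966-2-1) primaries under D65, linear RGB -> XYZ, Y in 0..1.
SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
XYZ_TO_SRGB = np.linalg.inv(SRGB_TO_XYZ)


def _as_triplets(c, name: str) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if c.shape[-1] != 3:
        raise ValueError(f"{name} must have a trailing axis of length 3")
    if not np.all(np.isfinite(c)):
        raise ValueError(f"{name} contains non-finite values")
    return c


def srgb_decode(rgb) -> np.ndarray:
    """Encoded sRGB in [0, 1] -> linear RGB in [0, 1].

    The standard piecewise transfer function: a linear toe below 0.04045
    and a 2.4-exponent power law above it.
    """
    rgb = np.asarray(rgb, dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 1):
        raise ValueError("encoded sRGB channels must lie in [0, 1]")
    return np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)


def srgb_encode(rgb_linear) -> np.ndarray:
    """Linear RGB in [0, 1] -> encoded sRGB in [0, 1] (inverse of decode)."""
    rgb = np.asarray(rgb_linear, dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 1):
        raise ValueError("linear RGB channels must lie in [0, 1]")
    return np.where(rgb <= 0.0031308, rgb * 12.92, 1.055 * rgb ** (1.0 / 2.4) - 0.055)


def linear_rgb_to_xyz(rgb_linear) -> np.ndarray:
    """Linear sRGB -> CIE 1931 XYZ on the 0-100 luminance scale."""
    rgb = _as_triplets(rgb_linear, "linear RGB")
    return 100.0 * (rgb @ SRGB_TO_XYZ.T)


def xyz_to_linear_rgb(xyz) -> np.ndarray:
    """Inverse of :func:`linear_rgb_to_xyz`; may leave the [0, 1] gamut."""
    xyz = _as_triplets(xyz, "XYZ")
    return (xyz / 100.0) @ XYZ_TO_SRGB.T


_LAB_DELTA = 6.0 / 29.0


def _lab_f(t: np.ndarray) -> np.ndarray:
    d3 = _LAB_DELTA**3
    return np.where(t > d3, np.cbrt(t), t / (3 * _LAB_DELTA**2) + 4.0 / 29.0)


def _lab_f_inv(u: np.ndarray) -> np.ndarray:
    return np.where(u > _LAB_DELTA, u**3, 3 * _LAB_DELTA**2 * (u - 4.0 / 29.0))


def xyz_to_lab(xyz, white) -> np.ndarray:
    """CIE XYZ -> L*a*b* relative to the given reference white."""
    xyz = _as_triplets(xyz, "XYZ")
    white = _as_triplets(white, "white")
    if np.any(white <= 0):
        raise ValueError("reference white must have strictly positive XYZ")
    f = _lab_f(xyz / white)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def lab_to_xyz(lab, white) -> np.ndarray:
    """Inverse of :func:`xyz_to_lab`."""
    lab = _as_triplets(lab, "Lab")
    white = _as_triplets(white, "white")
    if np.any(white <= 0):
        raise ValueError("reference white must have strictly positive XYZ")
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    f = np.stack([fx, fy, fz], axis=-1)
    return _lab_f_inv(f) * white


def spectrum_to_xyz(reflectance, illuminant, cmf) -> np.ndarray:
    """Integrate reflectance x illuminant against the observer functions.

    Parameters
    ----------
    reflectance : (..., n) array
        Unitless spectral reflectance on the shared grid.
    illuminant : (n,) array
        Relative spectral power of the illuminant.
    cmf : (n, 3) array
        Columns are the xbar, ybar, zbar observer weightings.

    Returns XYZ normalized so that a perfect reflector has Y = 100.
    """
    reflectance = np.asarray(reflectance, dtype=float)
    illuminant = np.asarray(illuminant, dtype=float)
    cmf = np.asarray(cmf, dtype=float)
    n = illuminant.shape[0]
    if cmf.shape != (n, 3) or reflectance.shape[-1] != n:
        raise GridMismatchError(
            f"grid lengths disagree: reflectance {reflectance.shape[-1]}, "
            f"illuminant {n}, cmf {cmf.shape}"
        )
    k = 100.0 / np.sum(illuminant * cmf[:, 1])
    return k * (reflectance * illuminant) @ cmf


def white_point(illuminant, cmf) -> np.ndarray:
    """XYZ of the illuminant (a perfect reflector), Y = 100 by construction."""
    n = np.asarray(illuminant).shape[0]
    return spectrum_to_xyz(np.ones(n), illuminant, cmf)


def ciede2000(lab1, lab2) -> np.ndarray:
    """CIEDE2000 color difference with parametric factors kL = kC = kH = 1.

    Implements the full formula: the a*-axis rescaling via G, the weighted
    lightness/chroma/hue terms, and the blue-region rotation term RT.
    Vectorized; broadcasting applies over leading axes.
    """
    lab1 = _as_triplets(lab1, "lab1")
    lab2 = _as_triplets(lab2, "lab2")
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1 + G) * a1
    a2p = (1 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where(C1p == 0, 0.0, h1p)
    h2p = np.where(C2p == 0, 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p

    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where((C1p * C2p) == 0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        habs <= 180.0,
        0.5 * hsum,
        np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
    )
    hbp = np.where((C1p * C2p) == 0, hsum, hbp)

    T = (
        1
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1 + 0.045 * Cbp
    SH = 1 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    return np.sqrt(
        (dLp / SL) ** 2
        + (dCp / SC) ** 2
        + (dHp / SH) ** 2
        + RT * (dCp / SC) * (dHp / SH)
    )
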