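"""Self-contained fixture data: observer/illuminant tables, a synthetic
24-patch reflectance chart, a parametric synthetic camera, and a toy
pigmented-lesion image generator.

Nothing here touches the network.  The observer (CIE 1931 2 degree) and
daylight illuminant (D65) are shipped as 10 nm CSV tables and interpolated
to the working grid.  The 24-patch chart is a *synthetic* stand-in for a
measured color-calibration chart: each patch reflectance is a clipped linear
combination of a small shared set of smooth pigment-like primitives (cut-on
sigmoids and Gaussian bands), mimicking how physical charts are painted from
a limited pigment palette.  That shared palette is what gives the chart the
low-dimensional spectral structure that principal-component reconstruction
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .colorimetry import (
    DEFAULT_GRID,
    WavelengthGrid,
    linear_rgb_to_xyz,
    spectrum_to_xyz,
    srgb_decode,
    srgb_encode,
    xyz_to_linear_rgb,
)

__all__ = [
    "load_cmf",
    "load_illuminant",
    "load_reference_chart",
    "load_calibration_xyz_table",
    "CameraDistortion",
    "SyntheticChartCapture",
    "simulate_capture",
    "generate_lesion_image",
    "CHART_PATCH_NAMES",
]


def _read_table(name: str) -> pd.DataFrame:
    with resources.files("save_hsi.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_cmf(grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    """CIE 1931 2-degree color-matching functions as an (n, 3) array."""
    tab = _read_table("cie_1931_2deg_cmf_10nm.csv")
    return grid.resample(tab["wavelength_nm"].to_numpy(), tab[["xbar", "ybar", "zbar"]].to_numpy())


def load_illuminant(grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    """Relative spectral power of the D65 daylight illuminant, length n."""
    tab = _read_table("illuminant_d65_10nm.csv")
    return grid.resample(tab["wavelength_nm"].to_numpy(), tab["power"].to_numpy())


def load_calibration_xyz_table() -> pd.DataFrame:
    """Published before/after-calibration XYZ coordinates of a 24-patch chart.

    Columns: patch_id, before_X/Y/Z, after_X/Y/Z, rmse_reported, sd_reported.
    Used to validate the per-patch RMSE arithmetic of the calibration report.
    """
    return _read_table("chart_calibration_xyz_reference.csv")


# ---------------------------------------------------------------------------
# Synthetic 24-patch chart
# ---------------------------------------------------------------------------

CHART_PATCH_NAMES = [
    "dark skin", "light skin", "blue sky", "foliage", "blue flower",
    "bluish green", "orange", "purplish blue", "moderate red", "purple",
    "yellow green", "orange yellow", "blue", "green", "red", "yellow",
    "magenta", "cyan", "white", "neutral 8", "neutral 6.5", "neutral 5",
    "neutral 3.5", "black",
]


def _sigmoid(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(lam - center) / width))


def _gauss(lam: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def load_reference_chart(grid: WavelengthGrid = DEFAULT_GRID):
    """Synthetic 24-patch chart reflectances.

    Returns ``(reflectances, names)`` where ``reflectances`` is a (24, n)
    array on ``grid``.  The layout follows the classic chart: natural tones
    in rows 1-2, the six chromatic primaries blue/green/red/yellow/magenta/
    cyan at positions 13-18, white at 19 and black at 24.  These spectra are
    synthetic (pigment-primitive mixtures), not spectrometer measurements.
    """
    lam = grid.wavelengths
    # shared pigment-like primitives
    violet = _gauss(lam, 435.0, 32.0)
    blue = _gauss(lam, 465.0, 38.0)
    green = _gauss(lam, 545.0, 48.0)
    yellow_on = _sigmoid(lam, 510.0, 18.0)   # cut-on -> yellow
    orange_on = _sigmoid(lam, 565.0, 20.0)   # cut-on -> orange
    red_on = _sigmoid(lam, 605.0, 16.0)      # cut-on -> red
    cyan_off = 1.0 - _sigmoid(lam, 590.0, 22.0)  # short-pass -> cyan
    nir_rise = _sigmoid(lam, 700.0, 28.0)    # common pigment NIR upturn
    flat = np.ones_like(lam)

    # base + weighted primitives per patch
    recipes = [
        0.07 * flat + 0.10 * orange_on + 0.05 * red_on + 0.04 * green,      # dark skin
        0.23 * flat + 0.30 * orange_on + 0.14 * green,                      # light skin
        0.11 * flat + 0.24 * blue + 0.06 * cyan_off + 0.04 * nir_rise,      # blue sky
        0.05 * flat + 0.17 * green + 0.10 * nir_rise,                       # foliage
        0.14 * flat + 0.30 * blue + 0.14 * red_on,                          # blue flower
        0.16 * flat + 0.32 * green + 0.22 * cyan_off,                       # bluish green
        0.06 * flat + 0.52 * orange_on,                                     # orange
        0.06 * flat + 0.28 * violet + 0.14 * blue + 0.06 * nir_rise,        # purplish blue
        0.06 * flat + 0.42 * red_on + 0.05 * blue,                          # moderate red
        0.05 * flat + 0.14 * violet + 0.12 * red_on,                        # purple
        0.06 * flat + 0.26 * green + 0.26 * yellow_on,                      # yellow green
        0.06 * flat + 0.44 * orange_on + 0.20 * yellow_on,                  # orange yellow
        0.05 * flat + 0.26 * violet + 0.18 * blue,                          # blue
        0.05 * flat + 0.32 * green,                                         # green
        0.04 * flat + 0.52 * red_on,                                        # red
        0.06 * flat + 0.62 * yellow_on,                                     # yellow
        0.08 * flat + 0.22 * blue + 0.42 * red_on,                          # magenta
        0.05 * flat + 0.26 * blue + 0.22 * green + 0.14 * cyan_off,         # cyan
        0.90 * flat,                                                        # white
        0.59 * flat,                                                        # neutral 8
        0.36 * flat,                                                        # neutral 6.5
        0.20 * flat,                                                        # neutral 5
        0.09 * flat,                                                        # neutral 3.5
        0.031 * flat,                                                       # black
    ]
    refl = np.clip(np.stack(recipes, axis=0), 0.01, 0.97)
    return refl, list(CHART_PATCH_NAMES)


# ---------------------------------------------------------------------------
# Synthetic camera
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraDistortion:
    """Parametric model of the error sources a real camera introduces.

    crosstalk
        3x3 channel-mixing matrix applied in linear RGB; should be
        diagonally dominant for a realistic camera (identity = none).
    dark_offset
        Additive per-channel term in linear RGB (dark current).
    gamma_error
        Per-channel exponent perturbation g: the linear value v becomes
        v ** (1 + g), emulating a mis-set transfer function.
    noise_sd
        Standard deviation of additive Gaussian noise in linear RGB.
    seed
        Seed for the noise generator; same seed, same capture.
    """

    crosstalk: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    dark_offset: tuple = (0.0, 0.0, 0.0)
    gamma_error: tuple = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @staticmethod
    def default(seed: int = 1672) -> "CameraDistortion":
        """The stock test distortion: mild crosstalk, dark current, gamma
        error of alternating sign, and a little sensor noise."""
        ct = 0.05
        return CameraDistortion(
            crosstalk=(
                (1.0 - 2 * ct, ct, ct),
                (ct, 1.0 - 2 * ct, ct),
                (ct, ct, 1.0 - 2 * ct),
            ),
            dark_offset=(0.02, 0.02, 0.02),
            gamma_error=(0.1, -0.1, 0.1),
            noise_sd=0.002,
            seed=seed,
        )


@dataclass(frozen=True)
class SyntheticChartCapture:
    """A simulated photograph of the chart plus the generating truth."""

    camera_xyz: np.ndarray       # (24, 3) distorted XYZ, as decoded from the image
    reference_xyz: np.ndarray    # (24, 3) true XYZ integrated from the spectra
    reference_spectra: np.ndarray  # (24, n)
    distortion: CameraDistortion
    patch_names: list = field(default_factory=list)


def _signed_power(v: np.ndarray, exponent) -> np.ndarray:
    return np.sign(v) * np.abs(v) ** exponent


def _signed_encode(v: np.ndarray) -> np.ndarray:
    # sRGB encode extended symmetrically to negatives (scRGB-style), so the
    # simulated signal chain stays invertible for slightly out-of-range values
    a = np.abs(v)
    enc = np.where(a <= 0.0031308, a * 12.92, 1.055 * a ** (1.0 / 2.4) - 0.055)
    return np.sign(v) * enc


def _signed_decode(v: np.ndarray) -> np.ndarray:
    a = np.abs(v)
    dec = np.where(a <= 0.04045, a / 12.92, ((a + 0.055) / 1.055) ** 2.4)
    return np.sign(v) * dec


def simulate_capture(
    chart_spectra: np.ndarray,
    distortion: CameraDistortion,
    grid: WavelengthGrid = DEFAULT_GRID,
    illuminant: np.ndarray | None = None,
    cmf: np.ndarray | None = None,
    patch_names: list | None = None,
) -> SyntheticChartCapture:
    """Photograph the chart with a distorted synthetic camera.

    Signal chain: true XYZ (spectral integration) -> linear RGB ->
    crosstalk -> dark offset -> per-channel gamma perturbation -> noise ->
    encode -> decode by an ideal sRGB observer -> camera XYZ.  Deterministic
    given ``distortion.seed``.
    """
    if illuminant is None:
        illuminant = load_illuminant(grid)
    if cmf is None:
        cmf = load_cmf(grid)
    chart_spectra = np.asarray(chart_spectra, dtype=float)
    true_xyz = spectrum_to_xyz(chart_spectra, illuminant, cmf)

    rgb = xyz_to_linear_rgb(true_xyz)
    ct = np.asarray(distortion.crosstalk, dtype=float)
    rgb = rgb @ ct.T
    rgb = rgb + np.asarray(distortion.dark_offset, dtype=float)
    rgb = _signed_power(rgb, 1.0 + np.asarray(distortion.gamma_error, dtype=float))
    if distortion.noise_sd > 0:
        rng = np.random.default_rng(distortion.seed)
        rgb = rgb + rng.normal(0.0, distortion.noise_sd, size=rgb.shape)

    encoded = _signed_encode(rgb)
    camera_xyz = linear_rgb_to_xyz(_signed_decode(encoded))
    return SyntheticChartCapture(
        camera_xyz=camera_xyz,
        reference_xyz=true_xyz,
        reference_spectra=chart_spectra,
        distortion=distortion,
        patch_names=list(patch_names) if patch_names else list(CHART_PATCH_NAMES),
    )


# ---------------------------------------------------------------------------
# Toy lesion image
# ---------------------------------------------------------------------------


def generate_lesion_image(
    size: tuple[int, int] = (64, 64),
    lesion_fraction: float = 0.15,
    melanin_density: float = 1.2,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid: WavelengthGrid = DEFAULT_GRID,
):
    """Render a skin-toned field with one elliptical pigmented lesion.

    The background reflectance is the chart's light-skin patch; lesion
    pixels attenuate it by a melanin-like absorption that grows toward
    short wavelengths (so the lesion darkens most strongly around 415 nm).
    Returns ``(image, mask)``: an 8-bit sRGB array (H, W, 3) and a boolean
    ground-truth mask.  ``lesion_fraction`` is the target area fraction of
    the ellipse; 0 yields a uniform background and an empty mask.
    """
    h, w = size
    if h < 16 or w < 16:
        raise ValueError("image must be at least 16x16")
    if not (0.0 <= lesion_fraction < 1.0):
        raise ValueError("lesion_fraction must be in [0, 1)")

    lam = grid.wavelengths
    chart, _ = load_reference_chart(grid)
    skin = chart[1]  # light skin
    # melanin-like absorbance, steeply decreasing with wavelength
    absorbance = (500.0 / lam) ** 3.0
    lesion_refl = skin * np.exp(-melanin_density * absorbance)

    illuminant = load_illuminant(grid)
    cmf = load_cmf(grid)
    skin_rgb = np.clip(xyz_to_linear_rgb(spectrum_to_xyz(skin, illuminant, cmf)), 0, 1)
    lesion_rgb = np.clip(xyz_to_linear_rgb(spectrum_to_xyz(lesion_refl, illuminant, cmf)), 0, 1)

    rng = np.random.default_rng(seed)
    mask = np.zeros((h, w), dtype=bool)
    if lesion_fraction > 0:
        # ellipse with jittered center/axes sized to the requested area
        area = lesion_fraction * h * w
        aspect = rng.uniform(0.6, 1.4)
        ry = np.sqrt(area / np.pi * aspect)
        rx = np.sqrt(area / np.pi / aspect)
        cy = h / 2 + rng.uniform(-0.1, 0.1) * h
        cx = w / 2 + rng.uniform(-0.1, 0.1) * w
        yy, xx = np.mgrid[0:h, 0:w]
        mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    rgb = np.where(mask[..., None], lesion_rgb, skin_rgb)
    if noise_sd > 0:
        rgb = np.clip(rgb + rng.normal(0.0, noise_sd, size=rgb.shape), 0, 1)
    image = np.round(srgb_encode(rgb) * 255.0).astype(np.uint8)
    return image, mask
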