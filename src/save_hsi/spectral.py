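"""PCA spectral basis and per-pixel analog-spectrum reconstruction.

The 24 chart reflectance spectra are summarized by a mean-centered
principal-component basis (default K = 6 components, which on chart-like
data carry essentially all of the variance).  Each training patch has a
score vector (its projection onto the basis).  A transformation matrix M is
then regressed so that the polynomial feature expansion of a patch's
*corrected* XYZ predicts its scores:

    M = Score @ pinv(V_color),   V_color = expansion(XYZ_correct) per patch.

At inference a pixel's analog spectrum is

    S = mean_spectrum + EVM^T @ (M @ V(xyz_correct)),

with EVM the K x n eigenvector matrix; values are clipped to [0, 1.2]
(negative reflectance is unphysical, a little headroom allows specular
overshoot).  Applying this per pixel converts an sRGB image into a
hyperspectral cube.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .calibration import (
    CorrectionMatrix,
    FeatureExpansion,
    PINV_RCOND,
    apply_correction,
    expand_features,
)
from .colorimetry import (
    DEFAULT_GRID,
    GridMismatchError,
    WavelengthGrid,
    linear_rgb_to_xyz,
    srgb_decode,
)

__all__ = [
    "SpectralBasis",
    "TransformationMatrix",
    "SpectralModel",
    "HyperspectralCube",
    "DegenerateSpectraError",
    "fit_basis",
    "fit_transformation",
    "reconstruct_spectrum",
    "convert_image",
    "spectral_rmse",
]

CLIP_RANGE = (0.0, 1.2)


class DegenerateSpectraError(ValueError):
    """Raised when the training spectra carry no variance to decompose."""


@dataclass(frozen=True)
class SpectralBasis:
    """Mean spectrum + K orthonormal principal directions (EVM)."""

    mean_spectrum: np.ndarray            # (n,)
    eigenvectors: np.ndarray             # (K, n), rows orthonormal
    explained_variance_ratio: np.ndarray  # (K,), non-increasing

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass(frozen=True)
class TransformationMatrix:
    """K x dimension regression matrix M predicting scores from features."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.ndim != 2 or not np.all(np.isfinite(entries)):
            raise ValueError("M must be a finite 2-D matrix")
        object.__setattr__(self, "entries", entries)


@dataclass(frozen=True)
class SpectralModel:
    """Everything needed to turn an sRGB pixel into an analog spectrum."""

    grid: WavelengthGrid
    expansion: FeatureExpansion
    correction: CorrectionMatrix
    basis: SpectralBasis
    transformation: TransformationMatrix

    def __post_init__(self) -> None:
        n = len(self.grid)
        if self.basis.mean_spectrum.shape != (n,):
            raise ValueError("mean spectrum length does not match the grid")
        K = self.basis.n_components
        if self.basis.eigenvectors.shape != (K, n):
            raise ValueError("eigenvector matrix shape mismatch")
        if self.transformation.entries.shape != (K, self.expansion.dimension):
            raise ValueError("M shape does not match basis / expansion")

    # -- serialization (single structured-text document) -----------------

    SCHEMA_VERSION = 1

    def to_json(self) -> str:
        doc = {
            "schema_version": self.SCHEMA_VERSION,
            "grid": {
                "start_nm": self.grid.start_nm,
                "stop_nm": self.grid.stop_nm,
                "step_nm": self.grid.step_nm,
            },
            "expansion_terms": list(self.expansion.terms),
            "correction": self.correction.entries.tolist(),
            "mean_spectrum": self.basis.mean_spectrum.tolist(),
            "eigenvectors": self.basis.eigenvectors.tolist(),
            "explained_variance_ratio": self.basis.explained_variance_ratio.tolist(),
            "transformation": self.transformation.entries.tolist(),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SpectralModel":
        doc = json.loads(text)
        version = doc.get("schema_version")
        if version != cls.SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version {version!r} "
                f"(this build reads version {cls.SCHEMA_VERSION})"
            )
        grid = WavelengthGrid(**doc["grid"])
        expansion = FeatureExpansion(tuple(doc["expansion_terms"]))
        correction = CorrectionMatrix(
            entries=np.asarray(doc["correction"], dtype=float), expansion=expansion
        )
        basis = SpectralBasis(
            mean_spectrum=np.asarray(doc["mean_spectrum"], dtype=float),
            eigenvectors=np.asarray(doc["eigenvectors"], dtype=float),
            explained_variance_ratio=np.asarray(
                doc["explained_variance_ratio"], dtype=float
            ),
        )
        transformation = TransformationMatrix(
            entries=np.asarray(doc["transformation"], dtype=float)
        )
        return cls(grid, expansion, correction, basis, transformation)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "SpectralModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass(frozen=True)
class HyperspectralCube:
    """H x W x n cube of analog spectral intensities with its grid."""

    intensities: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3 or arr.shape[2] != len(self.grid):
            raise ValueError("cube must be (H, W, n) with n = grid length")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self):
        return self.intensities.shape


def fit_basis(spectra, n_components: int = 6):
    """Mean-centered PCA of the training reflectances via SVD.

    Returns ``(basis, scores)`` where ``scores`` is the K x n_spectra
    projection matrix (the Score matrix of the regression step).
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2:
        raise ValueError("spectra must be (n_spectra, n_wavelengths)")
    n_spectra = spectra.shape[0]
    if n_components < 1 or n_components > n_spectra - 1:
        raise ValueError(
            f"n_components must be in [1, {n_spectra - 1}], got {n_components}"
        )
    mean = spectra.mean(axis=0)
    centered = spectra - mean
    total_var = float(np.sum(centered**2))
    if total_var <= 1e-20:
        raise DegenerateSpectraError("training spectra are identical; no variance")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    if n_components > np.sum(s > s[0] * 1e-12):
        raise ValueError("n_components exceeds the rank of the spectra")
    evr = (s**2 / np.sum(s**2))[:n_components]
    eigenvectors = Vt[:n_components]           # (K, n)
    scores = eigenvectors @ centered.T         # (K, n_spectra)
    basis = SpectralBasis(
        mean_spectrum=mean,
        eigenvectors=eigenvectors,
        explained_variance_ratio=evr,
    )
    return basis, scores


def fit_transformation(
    scores, xyz_correct, expansion: FeatureExpansion
) -> TransformationMatrix:
    """M = Score @ pinv(V_color) with V_color the expanded corrected XYZ."""
    import warnings

    scores = np.asarray(scores, dtype=float)
    xyz_correct = np.asarray(xyz_correct, dtype=float)
    if scores.ndim != 2 or xyz_correct.shape != (scores.shape[1], 3):
        raise ValueError("scores must be (K, n) and xyz_correct (n, 3)")
    V = expand_features(xyz_correct, expansion).T  # (dim, n)
    rank = np.linalg.matrix_rank(V, tol=PINV_RCOND * np.linalg.norm(V, 2))
    if rank < expansion.dimension:
        warnings.warn(
            f"V_color rank {rank} < dimension {expansion.dimension}",
            RuntimeWarning,
            stacklevel=2,
        )
    return TransformationMatrix(entries=scores @ np.linalg.pinv(V, rcond=PINV_RCOND))


def reconstruct_spectrum(model: SpectralModel, xyz_correct) -> np.ndarray:
    """Analog spectrum of one corrected XYZ triplet (or (..., 3) of them)."""
    V = expand_features(xyz_correct, model.expansion)
    scores = V @ model.transformation.entries.T
    spectra = model.basis.mean_spectrum + scores @ model.basis.eigenvectors
    return np.clip(spectra, *CLIP_RANGE)


def build_model(
    camera_xyz,
    reference_xyz,
    reference_spectra,
    grid: WavelengthGrid = DEFAULT_GRID,
    expansion: FeatureExpansion | None = None,
    n_components: int = 6,
) -> SpectralModel:
    """Full training pass: correction fit, PCA basis, transformation fit."""
    from .calibration import fit_correction

    expansion = expansion or FeatureExpansion()
    correction = fit_correction(camera_xyz, reference_xyz, expansion)
    xyz_correct = apply_correction(correction, camera_xyz)
    basis, scores = fit_basis(reference_spectra, n_components)
    transformation = fit_transformation(scores, xyz_correct, expansion)
    return SpectralModel(grid, expansion, correction, basis, transformation)


def convert_image(model: SpectralModel, image: np.ndarray) -> HyperspectralCube:
    """Convert an 8-bit sRGB image into a hyperspectral cube.

    Pipeline per pixel: decode sRGB -> XYZ -> polynomial correction ->
    analog-spectrum reconstruction.  Distinct colors are memoized: each
    unique RGB triplet's spectrum is computed once and scattered back, which
    is bit-identical to evaluating every pixel because the per-color
    arithmetic is the same.
    """
    image = np.asarray(image)
    if image.dtype != np.uint8 or image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an 8-bit RGB image of shape (H, W, 3)")
    h, w, _ = image.shape
    flat = image.reshape(-1, 3)
    unique, inverse = np.unique(flat, axis=0, return_inverse=True)
    spectra = _spectra_for_colors(model, unique)
    cube = spectra[inverse].reshape(h, w, -1).astype(np.float32)
    return HyperspectralCube(intensities=cube, grid=model.grid)


def _spectra_for_colors(model: SpectralModel, rgb_u8: np.ndarray) -> np.ndarray:
    rgb = srgb_decode(rgb_u8.astype(float) / 255.0)
    xyz = linear_rgb_to_xyz(rgb)
    xyz_correct = apply_correction(model.correction, xyz)
    return reconstruct_spectrum(model, xyz_correct)


def convert_image_naive(model: SpectralModel, image: np.ndarray) -> HyperspectralCube:
    """Reference path without memoization (used to verify equivalence)."""
    image = np.asarray(image)
    if image.dtype != np.uint8 or image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an 8-bit RGB image of shape (H, W, 3)")
    h, w, _ = image.shape
    flat = image.reshape(-1, 3)
    spectra = np.empty((flat.shape[0], len(model.grid)))
    for i in range(flat.shape[0]):
        spectra[i] = _spectra_for_colors(model, flat[i : i + 1])[0]
    return HyperspectralCube(
        intensities=spectra.reshape(h, w, -1).astype(np.float32), grid=model.grid
    )


def spectral_rmse(a, b) -> np.ndarray:
    """Root mean square pointwise difference of spectra on a common grid."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[-1] != b.shape[-1]:
        raise GridMismatchError("spectra are on different grids")
    return np.sqrt(np.mean((a - b) ** 2, axis=-1))
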