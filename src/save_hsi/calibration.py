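"""Camera color calibration against a 24-patch chart.

A photographed chart gives one camera-side XYZ triplet per patch; the same
patches' reflectance spectra give reference XYZ triplets.  The camera error
(nonlinear response, dark current, channel crosstalk, color shift) is
absorbed by a polynomial regression: each camera XYZ is expanded into a
feature vector V of monomials, and a 3 x dim correction matrix C is fitted
by least squares,

    C = XYZ_reference @ pinv(V),        XYZ_correct = C @ V(xyz).

The default expansion is the 11-term set
[1, X, Y, Z, XY, XZ, YZ, X^2, Y^2, Z^2, XYZ]: the constant absorbs dark
current, the linear block absorbs crosstalk/color shift, and the quadratic
and cross terms absorb smooth nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .colorimetry import ciede2000, xyz_to_lab

__all__ = [
    "FeatureExpansion",
    "DEFAULT_EXPANSION_TERMS",
    "CorrectionMatrix",
    "ExpansionTermError",
    "fit_correction",
    "apply_correction",
    "patch_rmse",
    "evaluate_calibration",
]

DEFAULT_EXPANSION_TERMS = (
    "1", "X", "Y", "Z", "XY", "XZ", "YZ", "XX", "YY", "ZZ", "XYZ",
)

PINV_RCOND = 1e-10


class ExpansionTermError(ValueError):
    """Raised for a term symbol the expansion grammar does not know."""


@dataclass(frozen=True)
class FeatureExpansion:
    """An ordered list of monomial terms in (X, Y, Z).

    Each term is either ``"1"`` (the constant) or a string over the letters
    X, Y, Z whose product is the monomial, e.g. ``"XY"`` or ``"XX"`` (X^2).
    """

    terms: Sequence[str] = DEFAULT_EXPANSION_TERMS

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if len(self.terms) < 4:
            raise ValueError("expansion needs at least the constant + linear terms")
        if self.terms[0] != "1":
            raise ValueError("first expansion term must be the constant '1'")
        for t in self.terms:
            if t != "1" and (not t or any(ch not in "XYZ" for ch in t)):
                raise ExpansionTermError(f"unknown expansion term {t!r}")

    @property
    def dimension(self) -> int:
        return len(self.terms)

    def __call__(self, xyz) -> np.ndarray:
        return expand_features(xyz, self)


def expand_features(xyz, expansion: FeatureExpansion) -> np.ndarray:
    """Evaluate the expansion terms; output shape is (..., dimension)."""
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[-1] != 3:
        raise ValueError("xyz must have trailing axis of length 3")
    if not np.all(np.isfinite(xyz)):
        raise ValueError("xyz contains non-finite values")
    idx = {"X": 0, "Y": 1, "Z": 2}
    cols = []
    for term in expansion.terms:
        if term == "1":
            cols.append(np.ones(xyz.shape[:-1]))
        else:
            v = np.ones(xyz.shape[:-1])
            for ch in term:
                v = v * xyz[..., idx[ch]]
            cols.append(v)
    return np.stack(cols, axis=-1)


@dataclass(frozen=True)
class CorrectionMatrix:
    """The fitted 3 x dimension matrix C, tied to its expansion."""

    entries: np.ndarray
    expansion: FeatureExpansion

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.shape != (3, self.expansion.dimension):
            raise ValueError(
                f"C must be 3x{self.expansion.dimension}, got {entries.shape}"
            )
        if not np.all(np.isfinite(entries)):
            raise ValueError("C contains non-finite entries")
        object.__setattr__(self, "entries", entries)


def fit_correction(
    camera_xyz,
    reference_xyz,
    expansion: FeatureExpansion | None = None,
) -> CorrectionMatrix:
    """Least-squares fit of C mapping expanded camera XYZ onto references.

    ``camera_xyz`` and ``reference_xyz`` are (n_patches, 3); n_patches must
    be at least the expansion dimension.  The pseudo-inverse uses an SVD
    with relative singular-value cutoff 1e-10; rank deficiency beyond that
    produces a warning but still returns the minimum-norm fit.
    """
    import warnings

    expansion = expansion or FeatureExpansion()
    camera_xyz = np.asarray(camera_xyz, dtype=float)
    reference_xyz = np.asarray(reference_xyz, dtype=float)
    if camera_xyz.shape != reference_xyz.shape or camera_xyz.ndim != 2:
        raise ValueError("camera and reference XYZ must both be (n, 3)")
    n = camera_xyz.shape[0]
    if n < expansion.dimension:
        raise ValueError(
            f"need at least {expansion.dimension} patches, got {n}"
        )
    V = expand_features(camera_xyz, expansion).T  # (dim, n)
    rank = np.linalg.matrix_rank(V, tol=PINV_RCOND * np.linalg.norm(V, 2))
    if rank < expansion.dimension:
        warnings.warn(
            f"feature matrix rank {rank} < dimension {expansion.dimension}; "
            "fit is rank-deficient",
            RuntimeWarning,
            stacklevel=2,
        )
    C = reference_xyz.T @ np.linalg.pinv(V, rcond=PINV_RCOND)
    return CorrectionMatrix(entries=C, expansion=expansion)


def apply_correction(correction: CorrectionMatrix, xyz) -> np.ndarray:
    """XYZ_correct = C @ V(xyz); vectorized over leading axes."""
    V = expand_features(xyz, correction.expansion)
    return V @ correction.entries.T


def patch_rmse(a, b) -> np.ndarray:
    """Root mean square difference of two XYZ triplets (or arrays of them).

    For triplets p and q this is sqrt(((pX-qX)^2 + (pY-qY)^2 + (pZ-qZ)^2)/3),
    the per-row RMSE convention of chart calibration reports.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape[-1] != 3:
        raise ValueError("inputs must be matching (..., 3) arrays")
    return np.sqrt(np.mean((a - b) ** 2, axis=-1))


def evaluate_calibration(
    camera_xyz,
    reference_xyz,
    correction: CorrectionMatrix,
    white,
    patch_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-patch calibration report.

    Columns: camera/corrected/reference XYZ, ``rmse`` between camera and
    corrected XYZ (the printed-report convention), and CIEDE2000 against the
    reference color before (camera) and after (corrected) correction, in Lab
    under ``white``.  The DataFrame's ``attrs['means']`` holds the column
    means of rmse / delta_e_before / delta_e_after.
    """
    camera_xyz = np.asarray(camera_xyz, dtype=float)
    reference_xyz = np.asarray(reference_xyz, dtype=float)
    corrected = apply_correction(correction, camera_xyz)

    lab_ref = xyz_to_lab(reference_xyz, white)
    de_before = ciede2000(xyz_to_lab(camera_xyz, white), lab_ref)
    de_after = ciede2000(xyz_to_lab(corrected, white), lab_ref)
    rmse = patch_rmse(camera_xyz, corrected)

    n = camera_xyz.shape[0]
    report = pd.DataFrame(
        {
            "patch_id": np.arange(1, n + 1),
            "patch_name": list(patch_names) if patch_names else [""] * n,
            "camera_X": camera_xyz[:, 0],
            "camera_Y": camera_xyz[:, 1],
            "camera_Z": camera_xyz[:, 2],
            "corrected_X": corrected[:, 0],
            "corrected_Y": corrected[:, 1],
            "corrected_Z": corrected[:, 2],
            "reference_X": reference_xyz[:, 0],
            "reference_Y": reference_xyz[:, 1],
            "reference_Z": reference_xyz[:, 2],
            "rmse": rmse,
            "delta_e_before": de_before,
            "delta_e_after": de_after,
        }
    )
    report.attrs["means"] = {
        "rmse": float(np.mean(rmse)),
        "delta_e_before": float(np.mean(de_before)),
        "delta_e_after": float(np.mean(de_after)),
    }
    return report
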