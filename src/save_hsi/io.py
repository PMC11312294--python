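"""File formats: hyperspectral cubes, chart CSVs, reflectance tables,
run configuration.

Cubes are written as multi-page 32-bit float TIFF (one page per wavelength,
ascending) with the wavelength axis in the image description and a JSON
sidecar header; an ENVI-style flat-binary dialect (.raw + text .hdr) is
also supported for interoperability with spectral-imaging tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .colorimetry import WavelengthGrid
from .spectral import HyperspectralCube

__all__ = [
    "write_cube_tiff",
    "read_cube_tiff",
    "write_cube_envi",
    "read_cube_envi",
    "read_chart_csv",
    "read_reflectance_csv",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# Cubes
# ---------------------------------------------------------------------------


def _grid_doc(grid: WavelengthGrid) -> dict:
    return {
        "start_nm": grid.start_nm,
        "stop_nm": grid.stop_nm,
        "step_nm": grid.step_nm,
    }


def write_cube_tiff(cube: HyperspectralCube, path) -> None:
    """Multi-page float32 TIFF, wavelengths ascending, plus JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(cube.intensities.astype(np.float32), 2, 0)
    desc = json.dumps({"wavelength_nm": cube.grid.wavelengths.tolist()})
    tifffile.imwrite(path, pages, description=desc, metadata=None)
    sidecar = {
        "format": "save-hsi cube",
        "version": 1,
        "grid": _grid_doc(cube.grid),
        "shape": list(cube.intensities.shape),
        "dtype": "float32",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_cube_tiff(path) -> HyperspectralCube:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = WavelengthGrid(**sidecar["grid"])
    pages = tifffile.imread(path)
    return HyperspectralCube(intensities=np.moveaxis(pages, 0, 2), grid=grid)


def write_cube_envi(cube: HyperspectralCube, path) -> None:
    """Flat binary (BSQ float32, little-endian) with an ENVI-style .hdr."""
    path = Path(path)
    h, w, n = cube.intensities.shape
    data = np.moveaxis(cube.intensities.astype("<f4"), 2, 0)  # band-sequential
    data.tofile(path)
    wavelengths = ", ".join(f"{v:.1f}" for v in cube.grid.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {n}\n"
        "header offset = 0\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wavelengths} }}\n"
    )
    path.with_suffix(".hdr").write_text(hdr)


def read_cube_envi(path) -> HyperspectralCube:
    path = Path(path)
    hdr = {}
    text = path.with_suffix(".hdr").read_text()
    for line in text.splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            hdr[key.strip()] = value.strip()
    h, w, n = int(hdr["lines"]), int(hdr["samples"]), int(hdr["bands"])
    wl = [float(v) for v in hdr["wavelength"].strip("{} ").split(",")]
    step = wl[1] - wl[0] if n > 1 else 1.0
    grid = WavelengthGrid(wl[0], wl[-1], step)
    data = np.fromfile(path, dtype="<f4").reshape(n, h, w)
    return HyperspectralCube(intensities=np.moveaxis(data, 0, 2), grid=grid)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def read_chart_csv(path):
    """Chart measurement CSV -> (camera_xyz, reference_xyz) as (n, 3) arrays.

    Expected columns: patch_id, camera_X, camera_Y, camera_Z,
    ref_X, ref_Y, ref_Z.
    """
    tab = pd.read_csv(path)
    required = ["patch_id", "camera_X", "camera_Y", "camera_Z", "ref_X", "ref_Y", "ref_Z"]
    missing = [c for c in required if c not in tab.columns]
    if missing:
        raise ValueError(f"chart CSV missing columns: {missing}")
    tab = tab.sort_values("patch_id")
    camera = tab[["camera_X", "camera_Y", "camera_Z"]].to_numpy(dtype=float)
    reference = tab[["ref_X", "ref_Y", "ref_Z"]].to_numpy(dtype=float)
    for name, arr in (("camera", camera), ("reference", reference)):
        bad = np.nonzero(~np.isfinite(arr).all(axis=1))[0]
        if bad.size:
            raise ValueError(f"non-finite {name} XYZ in chart CSV row {bad[0] + 2}")
    return camera, reference


def read_reflectance_csv(path, grid: WavelengthGrid):
    """Reflectance table CSV -> (spectra, names) resampled to ``grid``.

    First column ``wavelength_nm``, then one column per patch.
    """
    tab = pd.read_csv(path)
    if tab.columns[0] != "wavelength_nm":
        raise ValueError("first column of a reflectance CSV must be wavelength_nm")
    names = list(tab.columns[1:])
    if not names:
        raise ValueError("reflectance CSV has no patch columns")
    values = grid.resample(
        tab["wavelength_nm"].to_numpy(dtype=float), tab[names].to_numpy(dtype=float)
    )
    return values.T, names  # (n_patches, n_wavelengths)


def write_reflectance_csv(spectra, names, grid: WavelengthGrid, path) -> None:
    spectra = np.asarray(spectra, dtype=float)
    tab = pd.DataFrame({"wavelength_nm": grid.wavelengths})
    for name, row in zip(names, spectra):
        tab[name] = row
    tab.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "schema_version",
    "grid",
    "expansion_terms",
    "n_components",
    "bands",
    "mapping",
    "seed",
    "verbosity",
}


@dataclass
class RunConfig:
    """Validated runtime configuration for the conversion workflow."""

    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    expansion_terms: tuple = (
        "1", "X", "Y", "Z", "XY", "XZ", "YZ", "XX", "YY", "ZZ", "XYZ",
    )
    n_components: int = 6
    bands: tuple = ((415.0, 30.0), (540.0, 20.0), (600.0, 20.0), (700.0, 20.0), (780.0, 20.0))
    mapping: dict | None = None
    seed: int = 1672
    verbosity: int = 1

    SCHEMA_VERSION = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        version = doc.get("schema_version", cls.SCHEMA_VERSION)
        if version != cls.SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version!r}")
        kwargs = {}
        if "grid" in doc:
            kwargs["grid"] = WavelengthGrid(**doc["grid"])
        for key in ("n_components", "seed", "verbosity", "mapping"):
            if key in doc:
                kwargs[key] = doc[key]
        if "expansion_terms" in doc:
            kwargs["expansion_terms"] = tuple(doc["expansion_terms"])
        if "bands" in doc:
            kwargs["bands"] = tuple((float(c), float(f)) for c, f in doc["bands"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        doc = {
            "schema_version": self.SCHEMA_VERSION,
            "grid": _grid_doc(self.grid),
            "expansion_terms": list(self.expansion_terms),
            "n_components": self.n_components,
            "bands": [list(b) for b in self.bands],
            "mapping": self.mapping,
            "seed": self.seed,
            "verbosity": self.verbosity,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
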