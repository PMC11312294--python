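import numpy as np
import pytest

from save_hsi.colorimetry import DEFAULT_GRID, spectrum_to_xyz
from save_hsi.fixtures import (
    CameraDistortion,
    load_cmf,
    load_illuminant,
    load_reference_chart,
    simulate_capture,
)
from save_hsi.spectral import build_model


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def illuminant(grid):
    return load_illuminant(grid)


@pytest.fixture(scope="session")
def cmf(grid):
    return load_cmf(grid)


@pytest.fixture(scope="session")
def white(illuminant, cmf):
    return spectrum_to_xyz(np.ones(illuminant.shape[0]), illuminant, cmf)


@pytest.fixture(scope="session")
def chart(grid):
    spectra, names = load_reference_chart(grid)
    return spectra, names


@pytest.fixture(scope="session")
def default_capture(chart, grid, illuminant, cmf):
    spectra, names = chart
    return simulate_capture(
        spectra, CameraDistortion.default(), grid, illuminant, cmf, names
    )


@pytest.fixture(scope="session")
def identity_capture(chart, grid, illuminant, cmf):
    spectra, names = chart
    return simulate_capture(
        spectra, CameraDistortion(), grid, illuminant, cmf, names
    )


@pytest.fixture(scope="session")
def default_model(default_capture, chart, grid):
    spectra, _ = chart
    return build_model(
        default_capture.camera_xyz, default_capture.reference_xyz, spectra, grid
    )


@pytest.fixture(scope="session")
def identity_model(identity_capture, chart, grid):
    spectra, _ = chart
    return build_model(
        identity_capture.camera_xyz, identity_capture.reference_xyz, spectra, grid
    )
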