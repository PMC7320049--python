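import numpy as np
import pytest

from nmrcal import (
    MixtureModel,
    PseudoVoigtPeak,
    PureComponentModel,
    SpectralGrid,
    make_toy_library,
)


@pytest.fixture(scope="session")
def toy_lib():
    """Deterministic 4-component study system shared across the suite."""
    return make_toy_library(seed=0)


@pytest.fixture(scope="session")
def fine_grid():
    """Wide, high-resolution grid so analytic peak areas are fully captured."""
    return SpectralGrid(ppm_start=0.0, ppm_end=14.0, n_points=14001, spectrometer_freq=43.3)


@pytest.fixture
def two_component_mixture():
    """A small, well-separated mixture for fast fitting tests."""
    a = PureComponentModel.from_peaks(
        "A",
        [
            PseudoVoigtPeak(omega=6.8, alpha=3.0, gamma=0.02, beta=0.7),
            PseudoVoigtPeak(omega=6.9, alpha=2.0, gamma=0.02, beta=0.7),
        ],
    )
    b = PureComponentModel.from_peaks(
        "B",
        [
            PseudoVoigtPeak(omega=7.8, alpha=1.5, gamma=0.025, beta=0.4),
            PseudoVoigtPeak(omega=8.1, alpha=2.5, gamma=0.02, beta=0.5),
        ],
    )
    return MixtureModel((a, b))


def brute_force_mixture(mixture, grid, params):
    """Independent oracle: evaluate every peak of every component one by one."""
    ln2 = np.log(2.0)
    nu = grid.ppm
    out = np.zeros(grid.n_points)
    for k, comp in enumerate(mixture.components):
        for i, p in enumerate(comp.peaks):
            jit = params.peak_jitter[k][i] if params.peak_jitter else 0.0
            pos = p.omega + jit + params.group_shift[k][p.group_id] + params.component_shift[k]
            gam = p.gamma * params.peak_broadening[k]
            t = (nu - pos) / gam
            out += params.weights[k] * p.alpha * (
                p.beta / (1 + t * t) + (1 - p.beta) * np.exp(-ln2 * t * t)
            )
    return out
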