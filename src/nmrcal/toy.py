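"""A self-contained synthetic study system for tests, examples and benchmarks.

:func:`make_toy_library` builds, deterministically from one seed, everything
the pipeline needs and that would normally come from the lab:

* a 4-component aromatic mixture model (pseudo-Voigt peak tables for the
  reaction species of a lithiation coupling: the aryl fluoride reactant, the
  amine reactant, its lithiated form, and the lithiated product), with
  overlapping multiplets as seen at low field;
* rendered pure-component spectra with realistic white measurement noise;
* an empirical baseline-noise pool;
* a simulated process trajectory (plateaus joined by ramps) observed by a
  precise "high-field" reference channel and a noisy "low-field" channel with
  a few injected outliers, for exercising the curation pipeline.

The peak tables are hand-designed, not fitted to any measurement: positions
sit well inside the 5.6-9.0 ppm window so that integrated areas are conserved
on the grid, widths correspond to 0.5-1 Hz half width at 43.3 MHz, and the
Gauss-Lorentz weights are intermediate, as pseudo-Voigt fits of real lines
typically are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .augment import NoisePool, extract_noise_pool
from .curation import TimeSeriesTable
from .spectral import (
    MixtureModel,
    PseudoVoigtPeak,
    PureComponentModel,
    SpectralGrid,
    Spectrum,
    eval_component,
)

__all__ = ["ToyLibrary", "make_toy_library"]

# multiplet centers (ppm) and proton multiplicities per species; synthetic,
# chosen to overlap like a crowded aromatic region at low field
_SPECIES = {
    "o-FNB": [(7.28, 2), (7.46, 2), (7.76, 2), (8.06, 2)],
    "toluidine": [(6.58, 2), (6.96, 2)],
    "Li-toluidine": [(6.46, 2), (6.76, 2), (7.44, 1)],
    "Li-MNDPA": [(6.68, 1), (7.16, 2), (7.52, 2), (8.14, 1)],
}

#: ppm regions free of any toy signal, used for the baseline-noise pool
BASELINE_REGIONS = ((5.62, 6.10), (8.55, 8.98))


@dataclass
class ToyLibrary:
    """Everything needed to run the full pipeline without measurements."""

    grid: SpectralGrid
    mixture: MixtureModel
    pure_spectra: list[Spectrum]
    noise_pool: NoisePool
    trajectory_hf: TimeSeriesTable
    trajectory_lf: TimeSeriesTable
    seed: int


def _make_component(name: str, rng: np.random.Generator) -> PureComponentModel:
    peaks = []
    for center, mult in _SPECIES[name]:
        # split each multiplet into `mult`+1 lines around its center
        n_lines = mult + 1
        spread = 0.018 * (n_lines - 1)
        for i in range(n_lines):
            omega = center - spread / 2 + i * 0.018 + rng.uniform(-0.002, 0.002)
            gamma = rng.uniform(0.008, 0.012)
            beta = rng.uniform(0.3, 0.6)
            # binomial multiplet intensity pattern
            rel = math.comb(n_lines - 1, i)
            alpha = 600.0 * rel / (2 ** (n_lines - 1)) * mult
            peaks.append(PseudoVoigtPeak(omega=omega, alpha=alpha, gamma=gamma, beta=beta))
    return PureComponentModel.from_peaks(name, peaks)


def _truth_profiles(t: np.ndarray) -> np.ndarray:
    """Piecewise plateau/ramp concentration profiles (mol/L) for 4 species."""
    # breakpoints in hours: plateaus [0,1.75] [2.75,4.75] [5.75,7.75] [8.5,10]
    knots = np.array([0.0, 1.75, 2.75, 4.75, 5.75, 7.75, 8.5, 10.0])
    levels = np.array([
        [0.60, 0.60, 0.35, 0.35, 0.50, 0.50, 0.20, 0.20],  # aryl fluoride
        [0.45, 0.45, 0.20, 0.20, 0.10, 0.10, 0.40, 0.40],  # amine
        [0.10, 0.10, 0.30, 0.30, 0.15, 0.15, 0.45, 0.45],  # lithiated amine
        [0.05, 0.05, 0.25, 0.25, 0.55, 0.55, 0.15, 0.15],  # product
    ])
    return np.stack([np.interp(t, knots, lv) for lv in levels], axis=1)


def make_toy_library(seed: int = 0) -> ToyLibrary:
    """Build the deterministic toy study system for a given seed."""
    rng = np.random.default_rng(seed)
    grid = SpectralGrid()
    components = tuple(_make_component(name, rng) for name in _SPECIES)
    mixture = MixtureModel(components)

    pure_spectra = []
    for comp in components:
        clean = eval_component(comp, grid)
        noise = rng.normal(0.0, 0.005 * clean.max(), grid.n_points)
        pure_spectra.append(
            Spectrum(grid, clean + noise, meta={"name": comp.name, "kind": "pure"})
        )

    # a separate "measured blank" supplies the empirical noise pool
    blank = Spectrum(
        grid, rng.normal(0.0, 0.8, grid.n_points), meta={"kind": "baseline"}
    )
    noise_pool = extract_noise_pool(blank, BASELINE_REGIONS)

    names = tuple(_SPECIES)
    t_lf = np.arange(200) * 0.05  # 200 samples, 3-min cadence, 10 h
    t_hf = np.arange(0.011, 10.0, 0.13)  # slower, offset reference cadence
    truth_lf = _truth_profiles(t_lf)
    truth_hf = _truth_profiles(t_hf)
    lf_vals = truth_lf + rng.normal(0.0, 0.003, truth_lf.shape)
    # two short calibration-bias episodes: steady in the lf trace alone but
    # off by > 0.04 mol/L against the reference, so the outlier filter (not
    # the steady-state filter) has to catch them
    lf_vals[62:74, 0] += 0.06
    lf_vals[130:142, 0] -= 0.06
    # plus two isolated spikes, which break their steady-state windows instead
    spike_rows = rng.choice(len(t_lf), size=2, replace=False)
    lf_vals[spike_rows, 0] += rng.choice([-0.08, 0.08], size=2)

    trajectory_hf = TimeSeriesTable(t_hf, truth_hf, source="hf", component_names=names)
    trajectory_lf = TimeSeriesTable(t_lf, lf_vals, source="lf", component_names=names)

    return ToyLibrary(
        grid=grid,
        mixture=mixture,
        pure_spectra=pure_spectra,
        noise_pool=noise_pool,
        trajectory_hf=trajectory_hf,
        trajectory_lf=trajectory_lf,
        seed=seed,
    )
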