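"""Pseudo-Voigt line shapes, pure-component peak models, and the parametric mixture model.

A 1-D NMR spectrum of a mixture is modelled as a weighted sum of pure-component
models, each a sum of pseudo-Voigt peaks:

    chi(nu, w, theta) = sum_k  w_k * S_k(nu; theta_P,k, theta_S,k, theta_GS,k, theta_PB,k)

where for component ``k`` the parameters are the per-peak shape parameters
``theta_P = (gamma, alpha, omega, beta)``, a component-wide shift ``theta_S`` (ppm),
a per-group shift vector ``theta_GS`` (ppm), and a width multiplier ``theta_PB``.
Peaks of one component are clustered into groups of neighbouring positions that
shift together (emulating coupled multiplets drifting with e.g. pH or temperature),
while ``theta_S`` moves the whole component and ``theta_PB`` emulates field-homogeneity
line broadening.

Conventions
-----------
* ``gamma`` is the half width at half maximum (HWHM) in ppm. If you have a FWHM,
  divide by 2.
* ``beta`` interpolates Gaussian -> Lorentzian: ``beta = 1`` is a pure Lorentzian
  (the natural NMR line shape), ``beta = 0`` a pure Gaussian. Both primitives are
  normalized to unit *peak height*, so the value at ``nu = omega`` is exactly
  ``alpha``.
* The ppm axis is ascending internally; descending display order is a plotting
  concern only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralGrid",
    "PseudoVoigtPeak",
    "PureComponentModel",
    "MixtureModel",
    "MixtureParams",
    "Spectrum",
    "eval_peak",
    "eval_component",
    "eval_mixture",
    "assign_groups",
    "integrate_area",
    "DEFAULT_DELTA_NU",
]

#: Peaks further apart than this (ppm) start a new shift group.
DEFAULT_DELTA_NU = 0.12

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform chemical-shift axis.

    Parameters
    ----------
    ppm_start, ppm_end:
        Window bounds in ppm, ``ppm_start < ppm_end``. The default window
        5.6-9.0 ppm covers the aromatic region used for quantitative work at
        low field.
    n_points:
        Number of samples (>= 2).
    spectrometer_freq:
        Proton frequency in MHz; converts ppm to Hz (``Hz = ppm * MHz``).
        Default 43.3 MHz, a benchtop permanent-magnet instrument.
    """

    ppm_start: float = 5.6
    ppm_end: float = 9.0
    n_points: int = 1692
    spectrometer_freq: float = 43.3

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if not self.ppm_start < self.ppm_end:
            raise ValueError(
                f"ppm_start must be < ppm_end, got {self.ppm_start} >= {self.ppm_end}"
            )
        if self.spectrometer_freq <= 0:
            raise ValueError("spectrometer_freq must be positive")

    @property
    def ppm(self) -> np.ndarray:
        """Ascending ppm axis, shape ``(n_points,)``."""
        return np.linspace(self.ppm_start, self.ppm_end, self.n_points)

    @property
    def dppm(self) -> float:
        """Grid spacing in ppm."""
        return (self.ppm_end - self.ppm_start) / (self.n_points - 1)

    def ppm_to_hz(self, ppm: float) -> float:
        return ppm * self.spectrometer_freq

    def hz_to_ppm(self, hz: float) -> float:
        return hz / self.spectrometer_freq


@dataclass(frozen=True)
class PseudoVoigtPeak:
    """One pseudo-Voigt peak: position ``omega`` (ppm), height ``alpha`` (a.u.),
    HWHM ``gamma`` (ppm), Gauss-Lorentz weight ``beta`` in [0, 1] (1 = Lorentzian),
    and the shift-group id it belongs to."""

    omega: float
    alpha: float
    gamma: float
    beta: float = 1.0
    group_id: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")

    @property
    def analytic_area(self) -> float:
        """Closed-form area: ``beta * pi*alpha*gamma + (1-beta) * alpha*gamma*sqrt(pi/ln 2)``."""
        lor = np.pi * self.alpha * self.gamma
        gau = self.alpha * self.gamma * np.sqrt(np.pi / _LN2)
        return self.beta * lor + (1.0 - self.beta) * gau


@dataclass(frozen=True)
class PureComponentModel:
    """A named chemical species as an ordered (by ``omega``) list of peaks with
    contiguous group ids ``0..n_groups-1``."""

    name: str
    peaks: tuple[PseudoVoigtPeak, ...]

    def __post_init__(self) -> None:
        peaks = tuple(self.peaks)
        object.__setattr__(self, "peaks", peaks)
        if len(peaks) == 0:
            raise ValueError("a component needs at least one peak")
        omegas = [p.omega for p in peaks]
        if any(b < a for a, b in zip(omegas, omegas[1:])):
            raise ValueError("peaks must be sorted ascending by omega")
        gids = sorted({p.group_id for p in peaks})
        if gids != list(range(len(gids))):
            raise ValueError(f"group ids must be contiguous from 0, got {gids}")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def n_groups(self) -> int:
        return max(p.group_id for p in self.peaks) + 1

    @property
    def analytic_area(self) -> float:
        return float(sum(p.analytic_area for p in self.peaks))

    @classmethod
    def from_peaks(
        cls,
        name: str,
        peaks: Sequence[PseudoVoigtPeak],
        delta_nu: float = DEFAULT_DELTA_NU,
    ) -> "PureComponentModel":
        """Sort peaks by position and (re-)assign shift groups with the
        chain rule at spacing ``delta_nu``."""
        ordered = sorted(peaks, key=lambda p: p.omega)
        gids = assign_groups([p.omega for p in ordered], delta_nu)
        return cls(name, tuple(replace(p, group_id=g) for p, g in zip(ordered, gids)))


@dataclass(frozen=True)
class MixtureModel:
    """K pure-component models with unique names."""

    components: tuple[PureComponentModel, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if len(comps) == 0:
            raise ValueError("a mixture needs at least one component")
        names = [c.name for c in comps]
        if len(set(names)) != len(names):
            raise ValueError(f"component names must be unique, got {names}")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]


@dataclass(frozen=True)
class MixtureParams:
    """Realization parameters for one synthetic/fitted mixture spectrum.

    ``weights``: per-component scale w_k >= 0 (area scales linearly with it);
    ``component_shift``: theta_S,k in ppm; ``group_shift``: per-component vector
    theta_GS,k (one entry per peak group, ppm); ``peak_broadening``: width
    multiplier theta_PB,k > 0; ``peak_jitter``: per-peak position perturbation
    delta-omega (ppm), concatenated over components in component order.
    """

    weights: tuple[float, ...]
    component_shift: tuple[float, ...]
    group_shift: tuple[tuple[float, ...], ...]
    peak_broadening: tuple[float, ...]
    peak_jitter: tuple[tuple[float, ...], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        object.__setattr__(
            self, "component_shift", tuple(float(s) for s in self.component_shift)
        )
        object.__setattr__(
            self, "group_shift", tuple(tuple(float(g) for g in gs) for gs in self.group_shift)
        )
        object.__setattr__(
            self, "peak_broadening", tuple(float(b) for b in self.peak_broadening)
        )
        object.__setattr__(
            self, "peak_jitter", tuple(tuple(float(j) for j in pj) for pj in self.peak_jitter)
        )
        k = len(self.weights)
        if not (len(self.component_shift) == len(self.group_shift) == len(self.peak_broadening) == k):
            raise ValueError("per-component parameter vectors must share length K")
        if self.peak_jitter and len(self.peak_jitter) != k:
            raise ValueError("peak_jitter must have one tuple per component")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be >= 0")
        if any(b <= 0 for b in self.peak_broadening):
            raise ValueError("peak_broadening must be > 0")

    @classmethod
    def identity(cls, mixture: MixtureModel, weights: Sequence[float] | None = None) -> "MixtureParams":
        """No shifts, no broadening change, unit (or given) weights."""
        k = mixture.n_components
        w = tuple(weights) if weights is not None else (1.0,) * k
        return cls(
            weights=w,
            component_shift=(0.0,) * k,
            group_shift=tuple((0.0,) * c.n_groups for c in mixture.components),
            peak_broadening=(1.0,) * k,
            peak_jitter=tuple((0.0,) * c.n_peaks for c in mixture.components),
        )

    def validate_against(self, mixture: MixtureModel) -> None:
        if len(self.weights) != mixture.n_components:
            raise ValueError(
                f"params have {len(self.weights)} components, mixture has {mixture.n_components}"
            )
        for c, gs in zip(mixture.components, self.group_shift):
            if len(gs) != c.n_groups:
                raise ValueError(
                    f"component {c.name!r} has {c.n_groups} groups, got {len(gs)} group shifts"
                )
        if self.peak_jitter:
            for c, pj in zip(mixture.components, self.peak_jitter):
                if len(pj) != c.n_peaks:
                    raise ValueError(
                        f"component {c.name!r} has {c.n_peaks} peaks, got {len(pj)} jitters"
                    )


@dataclass
class Spectrum:
    """Intensity vector on a :class:`SpectralGrid` with free-form provenance."""

    grid: SpectralGrid
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.grid.n_points,):
            raise ValueError(
                f"intensity length {self.intensity.shape} does not match grid "
                f"({self.grid.n_points},)"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")

    def copy(self) -> "Spectrum":
        return Spectrum(self.grid, self.intensity.copy(), dict(self.meta))


# ---------------------------------------------------------------------------
# evaluation


def _pseudo_voigt(nu: np.ndarray, omega: float, alpha: float, gamma: float, beta: float) -> np.ndarray:
    x = (nu - omega) / gamma
    lor = 1.0 / (1.0 + x * x)
    gau = np.exp(-_LN2 * x * x)
    return alpha * (beta * lor + (1.0 - beta) * gau)


def eval_peak(peak: PseudoVoigtPeak, grid: SpectralGrid) -> np.ndarray:
    """Evaluate one pseudo-Voigt peak on the grid.

    ``V(nu) = alpha * [beta * L(nu) + (1 - beta) * G(nu)]`` with unit-height
    Lorentzian ``L`` and Gaussian ``G`` sharing HWHM ``gamma``; ``V(omega) = alpha``.
    """
    if peak.gamma <= 0:
        raise ValueError("gamma must be > 0")
    return _pseudo_voigt(grid.ppm, peak.omega, peak.alpha, peak.gamma, peak.beta)


def _warn_truncation(peak_area_on_grid: float, analytic: float, name: str) -> None:
    if analytic > 0 and peak_area_on_grid < 0.99 * analytic:
        logger.warning(
            "component %s: >1%% of analytic peak area falls outside the grid "
            "(on-grid %.4g vs analytic %.4g)",
            name, peak_area_on_grid, analytic,
        )


def eval_component(
    model: PureComponentModel,
    grid: SpectralGrid,
    component_shift: float = 0.0,
    group_shift: Sequence[float] | None = None,
    broadening: float = 1.0,
    peak_jitter: Sequence[float] | None = None,
) -> np.ndarray:
    """Evaluate one component with its distortion parameters applied.

    Effective position of peak ``i`` is ``omega_i + jitter_i +
    group_shift[group_id_i] + component_shift`` (all additive, order
    irrelevant); effective width is ``gamma_i * broadening``.
    """
    gs = np.zeros(model.n_groups) if group_shift is None else np.asarray(group_shift, float)
    if gs.shape != (model.n_groups,):
        raise ValueError(
            f"group_shift length {gs.shape} does not match n_groups {model.n_groups}"
        )
    pj = np.zeros(model.n_peaks) if peak_jitter is None else np.asarray(peak_jitter, float)
    if pj.shape != (model.n_peaks,):
        raise ValueError(
            f"peak_jitter length {pj.shape} does not match n_peaks {model.n_peaks}"
        )
    if broadening <= 0:
        raise ValueError("broadening must be > 0")

    nu = grid.ppm
    out = np.zeros(grid.n_points)
    for i, p in enumerate(model.peaks):
        pos = p.omega + pj[i] + gs[p.group_id] + component_shift
        out += _pseudo_voigt(nu, pos, p.alpha, p.gamma * broadening, p.beta)
    return out


def eval_mixture(mixture: MixtureModel, grid: SpectralGrid, params: MixtureParams) -> Spectrum:
    """Render the full mixture model ``chi(nu) = sum_k w_k S_k(nu, theta)``.

    Exactly linear in each weight.
    """
    params.validate_against(mixture)
    out = np.zeros(grid.n_points)
    for k, comp in enumerate(mixture.components):
        w = params.weights[k]
        if w == 0.0:
            continue
        pj = params.peak_jitter[k] if params.peak_jitter else None
        out += w * eval_component(
            comp,
            grid,
            component_shift=params.component_shift[k],
            group_shift=params.group_shift[k],
            broadening=params.peak_broadening[k],
            peak_jitter=pj,
        )
    return Spectrum(grid, out, meta={"kind": "model"})


def assign_groups(omegas: Sequence[float], delta_nu: float = DEFAULT_DELTA_NU) -> list[int]:
    """Cluster sorted peak positions into shift groups by a sequential chain rule.

    A peak joins the current group iff it lies within ``delta_nu`` ppm of the
    *previous* peak; otherwise it opens a new group. Ids are contiguous from 0.
    An empty list yields an empty result.
    """
    if delta_nu <= 0:
        raise ValueError("delta_nu must be > 0")
    omegas = list(omegas)
    if any(b < a for a, b in zip(omegas, omegas[1:])):
        raise ValueError("omegas must be sorted ascending")
    groups: list[int] = []
    current = 0
    for i, w in enumerate(omegas):
        if i > 0 and (w - omegas[i - 1]) > delta_nu:
            current += 1
        groups.append(current)
    return groups


def integrate_area(
    spectrum: Spectrum,
    region: tuple[float, float] | None = None,
) -> float:
    """Trapezoidal area (a.u. * ppm) of the spectrum over ``region`` (ppm
    interval) or the full window."""
    ppm = spectrum.grid.ppm
    y = spectrum.intensity
    if region is None:
        return float(np.trapezoid(y, ppm))
    lo, hi = min(region), max(region)
    if lo < ppm[0] - 1e-12 or hi > ppm[-1] + 1e-12:
        raise ValueError(f"region {region} outside grid [{ppm[0]}, {ppm[-1]}]")
    mask = (ppm >= lo) & (ppm <= hi)
    if mask.sum() < 2:
        raise ValueError(f"region {region} contains fewer than two grid points")
    return float(np.trapezoid(y[mask], ppm[mask]))
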