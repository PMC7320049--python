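"""Peak fitting and indirect-hard-modeling (IHM) style mixture quantification.

Two nonlinear least-squares problems:

* :func:`fit_pure_component` estimates a pseudo-Voigt peak set
  ``(omega, alpha, gamma, beta)`` per peak from a measured pure-component
  spectrum — the step that turns a measurement into a hard model.
* :func:`fit_mixture` fits the parametric mixture model to a measured mixture
  spectrum by releasing the component weights plus a configurable set of
  distortion parameters (component shift, group shifts, peak broadening) and
  reads per-component areas off the fitted model. This is a transparent
  re-implementation of the IHM *concept* used as a quantification baseline,
  not of any commercial package.

Both use SciPy's bounded trust-region-reflective least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, signal

from .spectral import (
    DEFAULT_DELTA_NU,
    MixtureModel,
    MixtureParams,
    PseudoVoigtPeak,
    PureComponentModel,
    Spectrum,
    eval_component,
    eval_mixture,
    integrate_area,
)

__all__ = ["FitResult", "fit_pure_component", "fit_mixture", "DEFAULT_MIXTURE_BOUNDS"]

#: Default release ranges for the mixture fit: component shift +-0.015 ppm,
#: group shift +-0.01 ppm, peak broadening +-15 %. Weights are [0, inf).
DEFAULT_MIXTURE_BOUNDS = {
    "component_shift": 0.015,
    "group_shift": 0.01,
    "peak_broadening": 0.15,
}


@dataclass
class FitResult:
    """Outcome of a least-squares fit.

    ``model`` is a :class:`PureComponentModel` (pure fit) or
    :class:`MixtureParams` (mixture fit); ``areas`` holds per-component
    integrated areas for mixture fits.
    """

    model: object
    residual_norm: float
    converged: bool
    n_iterations: int
    message: str = ""
    areas: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# pure-component fitting


def _pick_initial_peaks(spectrum: Spectrum, n_peaks: int) -> list[PseudoVoigtPeak]:
    """Initialize from local maxima above 5% of the spectrum maximum."""
    y = spectrum.intensity
    ppm = spectrum.grid.ppm
    height = 0.05 * float(y.max())
    idx, props = signal.find_peaks(y, height=height)
    if len(idx) == 0:
        raise ValueError("no peaks above 5% of maximum; supply initial peaks explicitly")
    # keep the n_peaks tallest, restore position order
    order = np.argsort(props["peak_heights"])[::-1][:n_peaks]
    idx = np.sort(idx[order])
    widths = signal.peak_widths(y, idx, rel_height=0.5)[0] * spectrum.grid.dppm
    peaks = []
    for i, w in zip(idx, widths):
        hwhm = max(w / 2.0, spectrum.grid.dppm)
        peaks.append(PseudoVoigtPeak(omega=float(ppm[i]), alpha=float(y[i]), gamma=hwhm, beta=1.0))
    return peaks


def fit_pure_component(
    spectrum: Spectrum,
    n_peaks: int | None = None,
    initial_peaks: Sequence[PseudoVoigtPeak] | None = None,
    name: str = "component",
    delta_nu: float = DEFAULT_DELTA_NU,
    max_iter: int = 500,
) -> FitResult:
    """Fit a sum of pseudo-Voigt peaks to a baseline-corrected pure-component
    spectrum and assign shift groups.

    Either ``n_peaks`` (automatic peak picking) or ``initial_peaks`` must be
    given. Bounds enforce ``alpha >= 0``, ``gamma > 0``, ``beta in [0, 1]``.
    Non-convergence is reported in the result, not raised.
    """
    if initial_peaks is None:
        if n_peaks is None or n_peaks < 1:
            raise ValueError("give n_peaks >= 1 or an initial peak list")
        initial_peaks = _pick_initial_peaks(spectrum, n_peaks)
    peaks0 = list(initial_peaks)
    m = len(peaks0)
    ppm = spectrum.grid.ppm
    y = spectrum.intensity
    span = ppm[-1] - ppm[0]

    x0 = np.empty(4 * m)
    lo = np.empty(4 * m)
    hi = np.empty(4 * m)
    for i, p in enumerate(peaks0):
        x0[4 * i : 4 * i + 4] = [p.omega, p.alpha, p.gamma, p.beta]
        lo[4 * i : 4 * i + 4] = [ppm[0] - 0.1 * span, 0.0, 1e-6, 0.0]
        hi[4 * i : 4 * i + 4] = [ppm[-1] + 0.1 * span, np.inf, span, 1.0]
    x0 = np.clip(x0, lo, hi)

    ln2 = np.log(2.0)

    def resid(x: np.ndarray) -> np.ndarray:
        model = np.zeros_like(y)
        for i in range(m):
            om, al, ga, be = x[4 * i : 4 * i + 4]
            t = (ppm - om) / ga
            model += al * (be / (1.0 + t * t) + (1.0 - be) * np.exp(-ln2 * t * t))
        return model - y

    res = optimize.least_squares(
        resid, x0, bounds=(lo, hi), method="trf", ftol=1e-10, xtol=1e-10, gtol=1e-10,
        max_nfev=max_iter * (4 * m + 1),
    )
    fitted = [
        PseudoVoigtPeak(
            omega=float(res.x[4 * i]),
            alpha=float(res.x[4 * i + 1]),
            gamma=float(max(res.x[4 * i + 2], 1e-12)),
            beta=float(np.clip(res.x[4 * i + 3], 0.0, 1.0)),
        )
        for i in range(m)
    ]
    model = PureComponentModel.from_peaks(name, fitted, delta_nu=delta_nu)
    return FitResult(
        model=model,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.status > 0),
        n_iterations=int(res.nfev),
        message=res.message,
    )


# ---------------------------------------------------------------------------
# mixture fitting (IHM baseline)


def _pack_bounds(mixture: MixtureModel, bounds: dict, release: set[str]):
    """Build the flat parameter vector layout:
    [w_0..w_{K-1}, theta_S (if released), theta_GS flat (if released),
     theta_PB (if released)].
    """
    k = mixture.n_components
    n_groups = [c.n_groups for c in mixture.components]
    layout = {"w": (0, k)}
    pos = k
    if "component_shift" in release:
        layout["theta_s"] = (pos, pos + k)
        pos += k
    if "group_shift" in release:
        layout["theta_gs"] = (pos, pos + sum(n_groups))
        pos += sum(n_groups)
    if "peak_broadening" in release:
        layout["theta_pb"] = (pos, pos + k)
        pos += k
    return layout, pos, n_groups


def fit_mixture(
    spectrum: Spectrum,
    mixture: MixtureModel,
    bounds: dict | None = None,
    release: Sequence[str] = ("component_shift", "group_shift", "peak_broadening"),
    max_iter: int = 500,
) -> FitResult:
    """Quantify a mixture spectrum by constrained least squares on the
    parametric mixture model.

    Minimizes ``sum_nu (spectrum - chi(nu, w, theta))^2`` over the weights and
    the released distortion parameters. Weights start from a non-negative
    linear least-squares warm start with all distortions at identity; shifts
    start at 0 and broadening at 1. Per-component areas are the trapezoidal
    integrals of each fitted weighted component.

    Parameters
    ----------
    bounds:
        Symmetric release ranges, keys as in :data:`DEFAULT_MIXTURE_BOUNDS`.
    release:
        Which distortion parameter families to free; weights are always free.
    """
    b = dict(DEFAULT_MIXTURE_BOUNDS)
    if bounds:
        b.update(bounds)
    release = set(release)
    grid = spectrum.grid
    y = spectrum.intensity
    k = mixture.n_components
    layout, n_params, n_groups = _pack_bounds(mixture, b, release)

    # warm start: NNLS on the undistorted component shapes
    basis = np.stack([eval_component(c, grid) for c in mixture.components], axis=1)
    w0, _ = optimize.nnls(basis, y)

    if not np.any(y):
        params = MixtureParams(
            weights=(0.0,) * k,
            component_shift=(0.0,) * k,
            group_shift=tuple((0.0,) * g for g in n_groups),
            peak_broadening=(1.0,) * k,
        )
        areas = {c.name: 0.0 for c in mixture.components}
        return FitResult(params, 0.0, True, 0, "zero spectrum", areas)

    x0 = np.zeros(n_params)
    lo = np.full(n_params, -np.inf)
    hi = np.full(n_params, np.inf)
    s, e = layout["w"]
    x0[s:e] = w0
    lo[s:e] = 0.0
    if "theta_s" in layout:
        s, e = layout["theta_s"]
        lo[s:e], hi[s:e] = -b["component_shift"], b["component_shift"]
    if "theta_gs" in layout:
        s, e = layout["theta_gs"]
        lo[s:e], hi[s:e] = -b["group_shift"], b["group_shift"]
    if "theta_pb" in layout:
        s, e = layout["theta_pb"]
        x0[s:e] = 1.0
        lo[s:e], hi[s:e] = 1.0 - b["peak_broadening"], 1.0 + b["peak_broadening"]

    def unpack(x: np.ndarray) -> MixtureParams:
        s, e = layout["w"]
        w = tuple(np.clip(x[s:e], 0.0, None))
        if "theta_s" in layout:
            s, e = layout["theta_s"]
            ts = tuple(x[s:e])
        else:
            ts = (0.0,) * k
        if "theta_gs" in layout:
            s, _ = layout["theta_gs"]
            tgs = []
            pos = s
            for g in n_groups:
                tgs.append(tuple(x[pos : pos + g]))
                pos += g
            tgs = tuple(tgs)
        else:
            tgs = tuple((0.0,) * g for g in n_groups)
        if "theta_pb" in layout:
            s, e = layout["theta_pb"]
            tpb = tuple(np.clip(x[s:e], 1e-6, None))
        else:
            tpb = (1.0,) * k
        return MixtureParams(weights=w, component_shift=ts, group_shift=tgs, peak_broadening=tpb)

    def resid(x: np.ndarray) -> np.ndarray:
        return eval_mixture(mixture, grid, unpack(x)).intensity - y

    res = optimize.least_squares(
        resid, x0, bounds=(lo, hi), method="trf", ftol=1e-10, xtol=1e-10, gtol=1e-10,
        max_nfev=max_iter,
    )
    params = unpack(res.x)
    areas = {}
    for i, comp in enumerate(mixture.components):
        contrib = params.weights[i] * eval_component(
            comp,
            grid,
            component_shift=params.component_shift[i],
            group_shift=params.group_shift[i],
            broadening=params.peak_broadening[i],
        )
        areas[comp.name] = integrate_area(Spectrum(grid, contrib))
    return FitResult(
        model=params,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.status > 0),
        n_iterations=int(res.nfev),
        message=res.message,
        areas=areas,
    )
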