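"""Fit a pure-component peak model, then quantify a mixture by nonlinear fitting.

This is the model-based route (the indirect-hard-modeling concept): first turn
each measured pure spectrum into a parametric peak model, then fit the mixture
model — weights plus shift/broadening distortions — to a mixture spectrum and
read component areas off the fit.
"""

import numpy as np

from nmrcal import (
    MixtureParams,
    eval_mixture,
    fit_mixture,
    fit_pure_component,
    make_toy_library,
)

lib = make_toy_library(seed=0)

# 1. peak-model construction from a (noisy) measured pure spectrum; at low
# field the multiplet lines overlap, so peak picking resolves fewer maxima
# than underlying lines — the fitted envelope still captures the area
spec = lib.pure_spectra[1]  # toluidine
res = fit_pure_component(spec, n_peaks=6, name="toluidine-refit")
print(f"Pure fit: picked {res.model.n_peaks} resolvable peaks, "
      f"converged={res.converged}, residual norm {res.residual_norm:.3g}")
print(f"  refit area {sum(p.analytic_area for p in res.model.peaks):.2f} a.u. "
      f"vs true model {lib.mixture.components[1].analytic_area:.2f} a.u.")

# 2. mixture quantification with known ground truth
w_true = (1.0, 0.5, 0.25, 0.0)
mix_spec = eval_mixture(lib.mixture, lib.grid,
                        MixtureParams.identity(lib.mixture, w_true))
fit = fit_mixture(mix_spec, lib.mixture)
print("\nMixture quantification (noiseless synthetic mixture):")
for name, wt, wf in zip(lib.mixture.names, w_true, fit.model.weights):
    print(f"  {name:14s} true w={wt:5.3f}  fitted w={wf:8.6f}  "
          f"area={fit.areas[name]:7.2f} a.u.")
err = np.max(np.abs(np.array(fit.model.weights) - np.array(w_true)))
print(f"Max weight error: {err:.2e} — the fit recovers the composition exactly")
print("when the data follow the model; real spectra add noise and mismatch.")
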