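"""Full fitting pipeline on a synthetic longitudinal assay.

Generates an individual-based cohort (n = 1146, the reference size),
estimates the phase-2 death rate k from the pooled phase-2 survival
curve, then fits the hazard slope a and onset age t0 with k fixed, and
compares against the Gompertz and Weibull comparators.
"""

import numpy as np

from twopac import (
    AssayDesign,
    ModelParams,
    fit_2pac,
    fit_gompertz,
    fit_k,
    fit_weibull,
    sample_cohort,
    smurf_survival_table,
    to_life_table,
)

truth = ModelParams(a=0.0039, b=-0.019, k=0.1911)
events = sample_cohort(truth, AssayDesign(n_individuals=1146, n_vials=4, seed=20150))

k_fit = fit_k(smurf_survival_table(events), lifetimes=events.smurf_lifetimes(),
              n_boot=500, seed=1)
lo, hi = k_fit.ci["k"]
print(f"step 1  k = {k_fit.params['k']:.4f}/day  (true {truth.k}),"
      f" 95% CI [{lo:.4f}, {hi:.4f}], R^2 = {k_fit.r_squared:.4f}")

table = to_life_table(events, np.arange(0.0, 70.0))
fit = fit_2pac(table, k_fixed=k_fit.params["k"])
print(f"step 2  a = {fit.params['a']:.5f}/day^2 (true {truth.a}),"
      f" t0 = {fit.params['t0']:.2f} d (true {truth.t0:.2f}), R^2 = {fit.r_squared:.4f}")

g = fit_gompertz(table)
w = fit_weibull(table)
print(f"comparators  Gompertz A={g.scale:.4f}, k={g.shape:.4f}, R^2={g.r_squared:.4f}")
print(f"             Weibull  a={w.scale:.2e}, k={w.shape:.4f}, R^2={w.r_squared:.4f}")
print("All three families fit the sigmoidal curve closely; only the")
print("two-phase parameters have a direct biological reading.")
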