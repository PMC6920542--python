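"""Weighted median and Egger regression on the same dataset.

Each instrument contributes a ratio estimate beta_Yj / beta_Xj of the causal
effect.  The weighted median is robust as long as at least half of the weight
lies on valid (non-pleiotropic) instruments; the Egger slope estimates the
effect while the intercept estimates average directional pleiotropy (near
zero here because pleiotropy is balanced).
"""

import numpy as np

from bayesmr import (
    draw_structural_params,
    egger_regression,
    per_instrument_associations,
    ratio_estimates,
    simulate_dataset,
    simulate_genotypes,
    benchmark_scenario,
    weighted_median,
    wme_with_ci,
)

spec = benchmark_scenario(3)
rng = np.random.default_rng(1)
G = simulate_genotypes(spec.n_individuals, spec.J, seed=rng)
params = draw_structural_params(spec, "alternative", rng)
data = simulate_dataset(params, G, rng)

summary = per_instrument_associations(data)
ratios, weights = ratio_estimates(summary)
print(f"true theta                 : {params.theta}")
print(f"median of ratio estimates  : {np.median(ratios):.3f}")
print(f"weighted median            : {weighted_median(ratios, weights):.3f}")

est = wme_with_ci(data, n_boot=1000, rng=rng, scheme="summary")
print(f"WME with bootstrap CI      : {est.point:.3f} [{est.lower:.3f}, {est.upper:.3f}]")

slope, intercept = egger_regression(summary)
print(f"Egger slope (causal)       : {slope.point:.3f} [{slope.lower:.3f}, {slope.upper:.3f}]")
print(f"Egger intercept (pleiotropy): {intercept.point:.4f} [{intercept.lower:.4f}, {intercept.upper:.4f}]")
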