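"""Replicate one benchmark scenario and tabulate coverage, power and bias.

Runs the scenario-11 experiment (strong instruments, balanced pleiotropy,
independent variants) at a desk scale of 100 replicates per regime for the
weighted median estimator.  Coverage should be near the nominal 95%, power
near 100% (the causal effect 0.35 is large relative to the estimator's
precision here), and bias near zero.
"""

from bayesmr import evaluate_scenario, benchmark_scenario
from bayesmr.evaluation import make_wme_adapter, metrics_table

results, log = evaluate_scenario(
    benchmark_scenario(11),
    {"WME": make_wme_adapter(n_boot=1000)},
    n_reps=100,
    master_seed=1,
)
print(metrics_table(results).to_string(index=False))
m = results["WME"]
print(
    f"\nMonte-Carlo SEs: coverage_null ±{m.mc_se['coverage_null']:.1f}pp, "
    f"power ±{m.mc_se['power']:.1f}pp over {m.n_reps} replicates per regime"
)
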