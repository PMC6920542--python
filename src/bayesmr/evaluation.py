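"""Replication harness: bias, coverage and power of MR estimators over simulated scenarios.

For a scenario, each replicate draws fresh structural parameters, simulates an
individual-level dataset on a genotype matrix held fixed across replicates
(matching how a single set of real genotypes underlies all replications), and
applies each estimator.  Coverage is the percentage of nominal-95% intervals
containing the generating causal effect, power the percentage of intervals
excluding zero under the alternative (theta = 0.35), and bias the mean of
point estimate minus truth.  Intervals are treated as closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import PosteriorSummary, PriorSpec, fit_single_exposure, summarize_posterior
from .frequentist import EstimateWithInterval, egger_regression, per_instrument_associations, wme_with_ci
from .genotypes import simulate_genotypes
from .scenarios import THETA_ALTERNATIVE, ScenarioSpec, draw_structural_params, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicationMetrics",
    "coverage",
    "evaluate_scenario",
    "make_wme_adapter",
    "make_egger_adapter",
    "make_bayes_adapter",
    "metrics_table",
]


def coverage(intervals: list[tuple[float, float]], truth: float) -> float:
    """Percentage of closed intervals [lower, upper] containing the truth."""
    if len(intervals) == 0:
        raise ValueError("empty interval list")
    hits = sum(1 for lo, hi in intervals if lo <= truth <= hi)
    return 100.0 * hits / len(intervals)


@dataclass
class ReplicationMetrics:
    """Aggregate performance of one estimator over the replicates of one scenario."""

    method: str
    scenario_id: int
    n_reps: int
    coverage_null: float
    coverage_alt: float
    power: float
    bias_null: float
    bias_alt: float
    mc_se: dict[str, float] = field(default_factory=dict)
    n_failures: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("coverage_null", "coverage_alt", "power"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be a percentage in [0, 100]")

    @property
    def type2_percent(self) -> float:
        """Type-II error rate under the alternative; power + type-II = 100."""
        return 100.0 - self.power


def _proportion_se(p_percent: float, n: int) -> float:
    p = p_percent / 100.0
    return 100.0 * float(np.sqrt(p * (1.0 - p) / n)) if n > 0 else float("nan")


def make_wme_adapter(n_boot: int = 1000, level: float = 0.95, scheme: str = "summary"):
    """Adapter: weighted median estimator with bootstrapped interval.

    The default ``scheme="summary"`` is the standard WME recipe (parametric
    bootstrap from per-instrument summary statistics) used in the benchmark
    replication; ``"individual"`` resamples individuals instead.
    """

    def run(data, seed: int) -> EstimateWithInterval:
        return wme_with_ci(
            data, n_boot=n_boot, level=level, rng=np.random.default_rng(seed), scheme=scheme
        )

    run.label = f"WME[{scheme}]"
    return run


def make_egger_adapter(level: float = 0.95):
    """Adapter: Egger regression slope with normal-theory interval."""

    def run(data, seed: int) -> EstimateWithInterval:
        slope, _ = egger_regression(per_instrument_associations(data), level=level)
        return slope

    run.label = "Egger"
    return run


def make_bayes_adapter(
    prior: PriorSpec | None = None,
    chains: int = 2,
    warmup: int = 500,
    iterations: int = 500,
    level: float = 0.95,
):
    """Adapter: posterior mean and central credible interval for theta."""
    prior = prior or PriorSpec()

    def run(data, seed: int) -> PosteriorSummary:
        samples = fit_single_exposure(
            data, prior=prior, chains=chains, warmup=warmup, iterations=iterations, seed=seed
        )
        return summarize_posterior(samples, "theta", level)

    run.label = f"Bayes-{prior.beta_prior}"
    return run


def _point_of(est) -> float:
    return est.mean if isinstance(est, PosteriorSummary) else est.point


def evaluate_scenario(
    spec: ScenarioSpec,
    methods: dict[str, object],
    n_reps: int,
    master_seed: int,
    regimes: tuple[str, ...] = ("null", "alternative"),
    redraw_genotypes: bool = False,
) -> tuple[dict[str, ReplicationMetrics], pd.DataFrame]:
    """Run a scenario's replication experiment for one or more estimators.

    Returns per-method aggregate metrics and the per-replicate log.  Fully
    reproducible from ``master_seed``; a method failure on a replicate is
    recorded and that replicate excluded from the failing method's metrics.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    root = np.random.SeedSequence(master_seed)
    geno_ss, rep_ss, method_ss = root.spawn(3)
    G = simulate_genotypes(
        spec.n_individuals,
        spec.J,
        maf_range=spec.maf_range,
        target_r2=spec.target_r2,
        seed=np.random.default_rng(geno_ss),
        mafs=np.full(spec.J, spec.fixed_maf) if spec.fixed_maf else None,
    )
    rep_children = rep_ss.spawn(len(regimes) * n_reps)
    method_children = method_ss.spawn(len(regimes) * n_reps * len(methods))
    records: list[dict] = []
    idx = 0
    for r, regime in enumerate(regimes):
        truth = 0.0 if regime == "null" else THETA_ALTERNATIVE
        for rep in range(n_reps):
            rng = np.random.default_rng(rep_children[r * n_reps + rep])
            params = draw_structural_params(spec, regime, rng)
            if redraw_genotypes:
                G_rep = simulate_genotypes(
                    spec.n_individuals,
                    spec.J,
                    maf_range=spec.maf_range,
                    target_r2=spec.target_r2,
                    seed=rng,
                    mafs=np.full(spec.J, spec.fixed_maf) if spec.fixed_maf else None,
                )
            else:
                G_rep = G
            data = simulate_dataset(params, G_rep, rng)
            for name, adapter in methods.items():
                seed = int(method_children[idx].generate_state(1)[0] % (2**31))
                idx += 1
                rec = {
                    "scenario": spec.scenario_id,
                    "regime": regime,
                    "rep": rep,
                    "method": name,
                    "theta_true": truth,
                }
                try:
                    est = adapter(data, seed)
                    rec.update(point=_point_of(est), lower=est.lower, upper=est.upper)
                except Exception as exc:  # noqa: BLE001 - failures are data, not crashes
                    logger.warning("%s failed on %s rep %d: %s", name, regime, rep, exc)
                    rec.update(point=np.nan, lower=np.nan, upper=np.nan, error=str(exc))
                records.append(rec)
    log = pd.DataFrame(records)

    results: dict[str, ReplicationMetrics] = {}
    for name in methods:
        sub = log[(log["method"] == name) & log["point"].notna()]
        null = sub[sub["regime"] == "null"]
        alt = sub[sub["regime"] == "alternative"]
        cov_null = (
            coverage(list(zip(null["lower"], null["upper"])), 0.0) if len(null) else float("nan")
        )
        cov_alt = (
            coverage(list(zip(alt["lower"], alt["upper"])), THETA_ALTERNATIVE)
            if len(alt)
            else float("nan")
        )
        power = (
            100.0 * float(np.mean((alt["lower"] > 0.0) | (alt["upper"] < 0.0)))
            if len(alt)
            else float("nan")
        )
        fails = {
            regime: int(n_reps - len(sub[sub["regime"] == regime]))
            for regime in regimes
        }
        results[name] = ReplicationMetrics(
            method=name,
            scenario_id=spec.scenario_id,
            n_reps=n_reps,
            coverage_null=cov_null,
            coverage_alt=cov_alt,
            power=power,
            bias_null=float(np.mean(null["point"])) if len(null) else float("nan"),
            bias_alt=float(np.mean(alt["point"] - THETA_ALTERNATIVE)) if len(alt) else float("nan"),
            mc_se={
                "coverage_null": _proportion_se(cov_null, len(null)),
                "coverage_alt": _proportion_se(cov_alt, len(alt)),
                "power": _proportion_se(power, len(alt)),
            },
            n_failures=fails,
        )
    return results, log


def metrics_table(results: dict[str, ReplicationMetrics]) -> pd.DataFrame:
    """Flatten per-method metrics into a benchmark-style table."""
    rows = []
    for m in results.values():
        rows.append(
            {
                "scenario": m.scenario_id,
                "method": m.method,
                "n_reps": m.n_reps,
                "coverage_null": m.coverage_null,
                "coverage_alt": m.coverage_alt,
                "power": m.power,
                "bias_null": m.bias_null,
                "bias_alt": m.bias_alt,
            }
        )
    return pd.DataFrame(rows)
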