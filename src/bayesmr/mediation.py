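"""Two-exposure Mendelian randomization: direct, indirect and total causal effects.

The structural model has exposures X1 and X2 instrumented by non-overlapping,
mutually independent variant sets I1 and I2, a shared standard-normal
confounder U, and causal parameters theta1 (direct effect of X1 on Y
controlling for X2), theta2 (X1 on X2) and theta3 (X2 on Y); the indirect
effect of X1 on Y is theta2*theta3 and the total effect
theta_TOT = theta1 + theta2*theta3.

When every pleiotropic effect is zero and the instruments are scalar, the
model is identified in closed form: with all variables standardized, each
node-pair correlation is the sum over unblocked paths of the products of the
path coefficients, giving a triangular system that
:func:`moment_solve_no_pleiotropy` solves exactly.  That solver is the
moment oracle against which the MCMC fit is validated; the general fit
handles nonzero pleiotropy with the same shrinkage priors as the
single-exposure model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._gibbs import Equation, GibbsSEM, GroupSpec
from .bayes import PosteriorSamples, PosteriorSummary, PriorSpec, shrinkage_weight, summarize_posterior
from .scenarios import MediationData

logger = logging.getLogger(__name__)

__all__ = [
    "MomentSolution",
    "fit_mediation",
    "moment_solve_no_pleiotropy",
    "moment_estimates_from_data",
    "path_tracing_correlations",
    "derived_effects",
    "sequential_relevance_screen",
]

#: cross-instrument-set mean R2 above which the I1 independent-of-I2 assumption is doubtful
CROSS_LD_WARN = 0.05


@dataclass
class MomentSolution:
    """Standardized path coefficients identified from the six node correlations."""

    alpha1: float
    alpha3: float
    alpha2: float
    theta2: float
    theta1: float
    theta3: float


def path_tracing_correlations(
    alpha1: float, alpha3: float, alpha2: float, theta2: float, theta1: float, theta3: float
) -> dict[str, float]:
    """Node correlations implied by the standardized path coefficients.

    Each correlation is the sum, over unblocked paths joining the two nodes,
    of the products of the standardized effects along the path.
    """
    return {
        "rho_X1I1": alpha1,
        "rho_X1I2": alpha3,
        "rho_I1X2": alpha1 * theta2,
        "rho_I2X2": alpha2 + alpha3 * theta2,
        "rho_I1Y": alpha1 * theta1 + alpha1 * theta2 * theta3,
        "rho_I2Y": alpha3 * theta1 + (alpha3 * theta2 + alpha2) * theta3,
    }


def moment_solve_no_pleiotropy(
    rho_X1I1: float,
    rho_X1I2: float,
    rho_I1X2: float,
    rho_I2X2: float,
    rho_I1Y: float,
    rho_I2Y: float,
    tol: float = 1e-10,
) -> MomentSolution:
    """Solve the zero-pleiotropy scalar-instrument system for the path coefficients.

    Solved sequentially: alpha1 and alpha3 directly; then the 2x2 system for
    (alpha2, theta2); then the 2x2 system for (theta1, theta3), whose
    determinant is alpha1*alpha2.  Raises a singularity error naming the
    identification condition that fails.
    """
    alpha1 = rho_X1I1
    alpha3 = rho_X1I2
    if abs(alpha1) < tol:
        raise np.linalg.LinAlgError(
            "identification condition (i) fails: alpha1 = corr(X1, I1) is zero"
        )
    theta2 = rho_I1X2 / alpha1
    alpha2 = rho_I2X2 - alpha3 * theta2
    if abs(alpha1 * alpha2) < tol:
        raise np.linalg.LinAlgError(
            "identification condition (ii) fails: alpha2 (direct I2-X2 effect) is zero"
        )
    A = np.array([[alpha1, alpha1 * theta2], [alpha3, alpha3 * theta2 + alpha2]])
    theta1, theta3 = np.linalg.solve(A, [rho_I1Y, rho_I2Y])
    return MomentSolution(
        alpha1=float(alpha1),
        alpha3=float(alpha3),
        alpha2=float(alpha2),
        theta2=float(theta2),
        theta1=float(theta1),
        theta3=float(theta3),
    )


def moment_estimates_from_data(data: MediationData) -> dict[str, float]:
    """Moment-solver causal-effect estimates on the original variable scale.

    Requires scalar instrument sets (J1 = J2 = 1) and assumes zero
    pleiotropy.  Sample correlations are fed to the standardized solver and
    the path coefficients are rescaled by the sample SD ratios.
    """
    if data.J1 != 1 or data.J2 != 1:
        raise ValueError("the closed-form solver applies to scalar instrument sets only")
    i1 = data.I1[:, 0].astype(float)
    i2 = data.I2[:, 0].astype(float)
    r = lambda a, b: float(np.corrcoef(a, b)[0, 1])  # noqa: E731
    sol = moment_solve_no_pleiotropy(
        r(data.X1, i1), r(data.X1, i2), r(i1, data.X2), r(i2, data.X2),
        r(i1, data.Y), r(i2, data.Y),
    )
    s1, s2, sy = data.X1.std(), data.X2.std(), data.Y.std()
    return {
        "theta1": sol.theta1 * sy / s1,
        "theta2": sol.theta2 * s2 / s1,
        "theta3": sol.theta3 * sy / s2,
    }


def fit_mediation(
    data: MediationData,
    prior: PriorSpec = PriorSpec(),
    chains: int = 4,
    warmup: int = 1000,
    iterations: int = 1000,
    seed: int | None = None,
    overdispersed_init: bool = False,
) -> PosteriorSamples:
    """Sample the posterior of the two-exposure model.

    The three beta-vectors (beta1: I1 -> Y, beta2: I2 -> Y, beta3: I1 -> X2)
    each carry their own shrinkage hierarchy; the alphas, thetas, intercepts
    and confounder loadings are flat; the confounder is marginalized into a
    rank-one-plus-diagonal trivariate error covariance.
    """
    J1, J2 = data.J1, data.J2
    I1 = np.asarray(data.I1, dtype=float)
    I2 = np.asarray(data.I2, dtype=float)
    for j in range(J1):
        for k in range(J2):
            if np.array_equal(I1[:, j], I2[:, k]):
                raise ValueError(f"instrument sets overlap: I1 column {j} equals I2 column {k}")
    if J1 >= 1 and J2 >= 1:
        C = np.corrcoef(np.hstack([I1, I2]), rowvar=False)
        cross = C[:J1, J1:] ** 2
        if float(cross.mean()) > CROSS_LD_WARN:
            logger.warning(
                "mean cross-set R²=%.3f exceeds %.2f: I1 ⟂ I2 assumption doubtful",
                float(cross.mean()),
                CROSS_LD_WARN,
            )

    n = data.n
    ones = np.ones((n, 1))
    shrink_kind = "zero" if prior.beta_prior == "point_zero" else "shrink"
    eq0 = Equation(data.X1, np.hstack([ones, I1, I2]))
    eq1 = Equation(data.X2, np.hstack([ones, data.X1[:, None], I1, I2]))
    eq2 = Equation(data.Y, np.hstack([ones, data.X1[:, None], data.X2[:, None], I1, I2]))
    groups = [
        GroupSpec("omega1", 0, [0], "flat"),
        GroupSpec("alpha1", 0, np.arange(1, J1 + 1), "flat"),
        GroupSpec("alpha3", 0, np.arange(J1 + 1, J1 + J2 + 1), "flat"),
        GroupSpec("omega2", 1, [0], "flat"),
        GroupSpec("theta2", 1, [1], "flat"),
        GroupSpec("beta3", 1, np.arange(2, J1 + 2), shrink_kind),
        GroupSpec("alpha2", 1, np.arange(J1 + 2, J1 + J2 + 2), "flat"),
        GroupSpec("omegaY", 2, [0], "flat"),
        GroupSpec("theta1", 2, [1], "flat"),
        GroupSpec("theta3", 2, [2], "flat"),
        GroupSpec("beta1", 2, np.arange(3, J1 + 3), shrink_kind),
        GroupSpec("beta2", 2, np.arange(J1 + 3, J1 + J2 + 3), shrink_kind),
    ]
    engine = GibbsSEM(
        equations=[eq0, eq1, eq2],
        groups=groups,
        beta_prior="horseshoe" if prior.beta_prior == "point_zero" else prior.beta_prior,
        global_scale=prior.global_scale,
        sigma_upper=prior.sigma_upper,
        delta_bounds=prior.delta_bounds,
    )
    raw = engine.run(
        chains=chains,
        warmup=warmup,
        iterations=iterations,
        seed=seed,
        overdispersed_init=overdispersed_init,
    )
    draws: dict[str, np.ndarray] = {}
    for key, val in raw.items():
        if key == "delta":
            draws["delta1"], draws["delta2"], draws["delta3"] = (
                val[..., 0], val[..., 1], val[..., 2],
            )
        elif key == "sigma":
            draws["sigma1"], draws["sigma2"], draws["sigmaY"] = (
                val[..., 0], val[..., 1], val[..., 2],
            )
        else:
            draws[key] = val
    for bname in ("beta1", "beta2", "beta3"):
        if f"{bname}_phi" in draws:
            draws[f"{bname}_kappa"] = shrinkage_weight(draws[f"{bname}_phi"])
    # vector groups of size 1 come back as scalars; keep thetas scalar-shaped
    return PosteriorSamples(draws)


def derived_effects(samples: PosteriorSamples, level: float = 0.95) -> dict[str, PosteriorSummary]:
    """Posterior summaries of the direct, indirect and total effects of X1 on Y.

    Products and sums are evaluated draw-wise before summarizing, preserving
    the posterior dependence among theta1, theta2 and theta3.
    """
    for name in ("theta1", "theta2", "theta3"):
        if name not in samples:
            raise KeyError(f"samples lack parameter {name!r}")
    return {
        "direct": summarize_posterior(samples, "theta1", level),
        "indirect": summarize_posterior(samples, "theta2*theta3", level),
        "total": summarize_posterior(samples, "theta1 + theta2*theta3", level),
    }


def sequential_relevance_screen(data: MediationData, level: float = 0.05):
    """Conditional-relevance diagnostic for the two instrument sets.

    For each I1 instrument: its association with X1 conditional on all other
    instruments.  For each I2 instrument: its association with X2 conditional
    on X1 and all other instruments.  Returns a DataFrame with the
    conditional estimate, SE, p-value and a ``flagged`` column for
    instruments without evidence of conditional relevance.  This is a report,
    never an automatic filter.
    """
    import pandas as pd
    import statsmodels.api as sm

    I1 = np.asarray(data.I1, dtype=float)
    I2 = np.asarray(data.I2, dtype=float)
    allZ = np.hstack([I1, I2])
    rows = []
    fit1 = sm.OLS(data.X1, sm.add_constant(allZ)).fit()
    for j in range(data.J1):
        rows.append(
            {
                "instrument": f"I1_{j + 1}",
                "exposure": "X1",
                "estimate": fit1.params[1 + j],
                "se": fit1.bse[1 + j],
                "p_value": fit1.pvalues[1 + j],
            }
        )
    X_design = sm.add_constant(np.hstack([data.X1[:, None], allZ]))
    fit2 = sm.OLS(data.X2, X_design).fit()
    for k in range(data.J2):
        col = 2 + data.J1 + k
        rows.append(
            {
                "instrument": f"I2_{k + 1}",
                "exposure": "X2",
                "estimate": fit2.params[col],
                "se": fit2.bse[col],
                "p_value": fit2.pvalues[col],
            }
        )
    df = pd.DataFrame(rows)
    df["flagged"] = df["p_value"] >= level
    return df
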