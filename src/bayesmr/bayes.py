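"""Single-exposure Bayesian MR model with shrinkage priors on pleiotropic effects.

The sampling target is the marginalized likelihood: given the doses Z_i,
(X_i, Y_i) is bivariate normal with means (omega_X + alpha.Z_i,
omega_Y + theta X_i + beta.Z_i) and error covariance

    [[delta_X^2 + sigma_X^2,  delta_X delta_Y     ],
     [delta_X delta_Y,        delta_Y^2 + sigma_Y^2]],

which is the latent-confounder model with U integrated out; no per-individual
U is ever sampled.  The pleiotropic effects beta carry a horseshoe (default)
or Laplace shrinkage prior; instrument strengths alpha are exchangeable
N(mu_alpha, sigma_alpha^2) with flat hyperpriors; theta, the intercepts and
the confounder loadings are flat; residual SDs are flat on the positive
reals.  An optional binary covariate W enters both equations, with an
exposure-covariate interaction term in the outcome equation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._gibbs import Equation, GibbsSEM, GroupSpec
from .scenarios import ObservedData, StructuralParams

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "HorseshoeLocals",
    "PosteriorSamples",
    "PosteriorSummary",
    "fit_single_exposure",
    "shrinkage_weight",
    "summarize_posterior",
    "prior_predictive_beta",
    "draw_horseshoe_locals",
    "marginal_loglik",
]

RHAT_ALERT = 1.05


@dataclass(frozen=True)
class PriorSpec:
    """Prior configuration for the Bayesian MR models.

    beta_prior selects the sparsity family for the pleiotropic effects:
    ``horseshoe`` (default), ``laplace``, or ``point_zero`` (standard IV
    analysis with all direct effects fixed at zero).  ``global_scale`` is the
    scale of the half-Cauchy hyperprior on the global shrinkage parameter.
    Remaining parameters have flat priors; optional finite bounds can be
    placed on the residual SDs, confounder loadings, and on
    delta_X^2 + sigma_X^2 (an upper bound on tau_X^2 elicited externally).
    """

    beta_prior: str = "horseshoe"
    global_scale: float = 1.0
    alpha_hierarchical: bool = True
    sigma_upper: float | None = None
    delta_bounds: tuple[float, float] | None = None
    tau_x_sq_upper: float | None = None

    def __post_init__(self) -> None:
        if self.beta_prior not in ("horseshoe", "laplace", "point_zero"):
            raise ValueError("beta_prior must be horseshoe, laplace or point_zero")
        if self.global_scale <= 0:
            raise ValueError("global_scale must be positive")


def shrinkage_weight(phi: float | np.ndarray) -> float | np.ndarray:
    """Horseshoe shrinkage weight kappa = 1 / (1 + phi^2), decreasing in phi."""
    phi = np.asarray(phi, dtype=float)
    if (phi < 0).any():
        raise ValueError("phi must be non-negative")
    out = 1.0 / (1.0 + phi**2)
    return float(out) if out.ndim == 0 else out


@dataclass
class HorseshoeLocals:
    """Local scales phi, global scale gamma, and induced shrinkage weights kappa."""

    phi: np.ndarray
    gamma: float
    kappa: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if (self.phi < 0).any() or self.gamma <= 0:
            raise ValueError("scales must be non-negative (gamma strictly positive)")
        self.kappa = shrinkage_weight(self.phi)


def draw_horseshoe_locals(
    J: int, rng: np.random.Generator, gamma: float | None = None, global_scale: float = 1.0
) -> HorseshoeLocals:
    """Forward-draw the horseshoe local scales (and gamma unless fixed)."""
    if gamma is None:
        gamma = global_scale * abs(rng.standard_cauchy())
    phi = gamma * np.abs(rng.standard_cauchy(size=J))
    return HorseshoeLocals(phi=phi, gamma=float(gamma))


@dataclass
class PosteriorSummary:
    """Posterior mean and central credible interval, with mixing diagnostics."""

    mean: float
    lower: float
    upper: float
    level: float = 0.95
    rhat: float | None = None
    ess: float | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower must not exceed upper")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


class PosteriorSamples:
    """MCMC draws keyed by parameter name, shaped (chains, draws[, dim])."""

    def __init__(self, draws: dict[str, np.ndarray], warnings: list[str] | None = None):
        self.draws = draws
        self.warnings = warnings or []
        n_draws = {v.shape[:2] for v in draws.values()}
        if len(n_draws) != 1:
            raise ValueError("all parameters must share (chains, draws)")
        self.chains, self.n_draws = n_draws.pop()

    def __contains__(self, name: str) -> bool:
        return name in self.draws

    def names(self) -> list[str]:
        return sorted(self.draws)

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled over chains: (chains*draws,) or (chains*draws, dim)."""
        if name not in self.draws:
            raise KeyError(f"unknown parameter {name!r}")
        v = self.draws[name]
        return v.reshape(self.chains * self.n_draws, *v.shape[2:])

    def _scalar_names(self) -> list[str]:
        return [k for k, v in self.draws.items() if v.ndim == 2]

    def diagnostics(self):
        """Split-Rhat and bulk ESS per scalar parameter (pandas DataFrame)."""
        import pandas as pd

        from ._diag import ess as _ess
        from ._diag import split_rhat

        rows = []
        for name in self._scalar_names():
            arr = self.draws[name]
            rows.append(
                {
                    "parameter": name,
                    "rhat": split_rhat(arr) if self.chains > 1 else np.nan,
                    "ess": _ess(arr),
                }
            )
        df = pd.DataFrame(rows).set_index("parameter")
        bad = df.index[df["rhat"] > RHAT_ALERT].tolist()
        if bad:
            logger.warning("R-hat above %.2f for: %s", RHAT_ALERT, bad)
        return df


def summarize_posterior(
    samples: PosteriorSamples, parameter: str, level: float = 0.95
) -> PosteriorSummary:
    """Posterior mean and central credible interval of a parameter or expression.

    ``parameter`` is either a stored parameter name or a Python expression in
    the stored names (evaluated draw-wise, e.g. ``"theta2*theta3"``).
    """
    if parameter in samples.draws:
        vals = samples.pooled(parameter)
        if vals.ndim != 1:
            raise ValueError(
                f"{parameter!r} is vector-valued; summarize components via an expression"
            )
    else:
        namespace = {name: samples.pooled(name) for name in samples.draws}
        namespace["np"] = np
        try:
            vals = eval(parameter, {"__builtins__": {}}, namespace)  # noqa: S307
        except NameError as exc:
            raise KeyError(f"unknown parameter in expression {parameter!r}: {exc}") from exc
        vals = np.asarray(vals, dtype=float)
        if vals.shape != (samples.chains * samples.n_draws,):
            raise ValueError(f"expression {parameter!r} must evaluate draw-wise to a scalar")
    a = (1.0 - level) / 2.0
    lower, upper = np.quantile(vals, [a, 1.0 - a])
    rhat = ess = None
    if parameter in samples.draws and samples.draws[parameter].ndim == 2:
        from ._diag import ess as _ess
        from ._diag import split_rhat

        if samples.chains > 1:
            rhat = split_rhat(samples.draws[parameter])
        ess = _ess(samples.draws[parameter])
    return PosteriorSummary(
        mean=float(vals.mean()), lower=float(lower), upper=float(upper), level=level,
        rhat=rhat, ess=ess,
    )


def fit_single_exposure(
    data: ObservedData,
    prior: PriorSpec = PriorSpec(),
    chains: int = 4,
    warmup: int = 1000,
    iterations: int = 1000,
    seed: int | None = None,
    interaction: bool = False,
    overdispersed_init: bool = False,
) -> PosteriorSamples:
    """Sample the posterior of the single-exposure MR model.

    With ``interaction=True`` (requires ``data.W``), the covariate enters the
    exposure equation additively (psi_XW) and the outcome equation both
    additively (psi_YW) and as an exposure-covariate interaction (psi_YXW),
    so the causal effect is theta for W=0 and theta + psi_YXW for W=1.
    """
    n, J = data.n, data.J
    if n < J:
        logger.warning("n=%d < J=%d: posterior driven largely by the prior", n, J)
    Z = np.asarray(data.Z, dtype=float)
    if (Z.std(axis=0) == 0).any():
        raise ValueError("constant dose column(s) present")
    if interaction and data.W is None:
        raise ValueError("interaction=True requires data.W")

    ones = np.ones((n, 1))
    dx_cols = [ones, Z]
    dy_cols = [ones, data.X[:, None], Z]
    groups = [
        GroupSpec("omega_X", 0, [0], "flat"),
        GroupSpec(
            "alpha",
            0,
            np.arange(1, J + 1),
            "hnormal" if (prior.alpha_hierarchical and J >= 4) else "flat",
        ),
        GroupSpec("omega_Y", 1, [0], "flat"),
        GroupSpec("theta", 1, [1], "flat"),
        GroupSpec(
            "beta",
            1,
            np.arange(2, J + 2),
            "zero" if prior.beta_prior == "point_zero" else "shrink",
        ),
    ]
    if prior.alpha_hierarchical and J < 4:
        logger.warning("J=%d too small for hierarchical alpha prior; using flat", J)
    if interaction:
        W = np.asarray(data.W, dtype=float)[:, None]
        dx_cols.append(W)
        dy_cols.extend([W, W * data.X[:, None]])
        groups.append(GroupSpec("psi_XW", 0, [J + 1], "flat"))
        groups.append(GroupSpec("psi_YW", 1, [J + 2], "flat"))
        groups.append(GroupSpec("psi_YXW", 1, [J + 3], "flat"))

    engine = GibbsSEM(
        equations=[
            Equation(data.X, np.hstack(dx_cols)),
            Equation(data.Y, np.hstack(dy_cols)),
        ],
        groups=groups,
        beta_prior="horseshoe" if prior.beta_prior == "point_zero" else prior.beta_prior,
        global_scale=prior.global_scale,
        sigma_upper=prior.sigma_upper,
        delta_bounds=prior.delta_bounds,
        tau_sq_upper={0: prior.tau_x_sq_upper} if prior.tau_x_sq_upper else None,
    )
    raw = engine.run(
        chains=chains,
        warmup=warmup,
        iterations=iterations,
        seed=seed,
        overdispersed_init=overdispersed_init,
    )

    draws: dict[str, np.ndarray] = {}
    rename = {"beta_phi": "phi", "beta_gamma": "gamma", "beta_tau": "tau"}
    for key, val in raw.items():
        if key == "delta":
            draws["delta_X"] = val[..., 0]
            draws["delta_Y"] = val[..., 1]
        elif key == "sigma":
            draws["sigma_X"] = val[..., 0]
            draws["sigma_Y"] = val[..., 1]
        else:
            draws[rename.get(key, key)] = val
    if "phi" in draws:
        draws["kappa"] = shrinkage_weight(draws["phi"])
    if prior.beta_prior == "point_zero" and "beta" not in draws:
        shape = draws["theta"].shape
        draws["beta"] = np.zeros(shape + (J,))

    samples = PosteriorSamples(draws)
    if chains > 1:
        from ._diag import split_rhat

        rhat_theta = split_rhat(draws["theta"])
        if rhat_theta > RHAT_ALERT:
            msg = f"R-hat on theta = {rhat_theta:.3f} exceeds {RHAT_ALERT}"
            logger.warning(msg)
            samples.warnings.append(msg)
    return samples


def prior_predictive_beta(
    prior: PriorSpec,
    J: int,
    n_draws: int,
    rng: np.random.Generator | int | None = None,
    fixed_scale: float | None = None,
) -> np.ndarray:
    """Forward draws (n_draws x J) of the pleiotropic effects from their prior.

    ``fixed_scale`` pins the top-level scale (tau for Laplace, gamma for the
    horseshoe) instead of drawing it from its half-Cauchy hyperprior.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if prior.beta_prior == "point_zero":
        return np.zeros((n_draws, J))
    if fixed_scale is not None:
        scale = np.full((n_draws, 1), float(fixed_scale))
    else:
        scale = prior.global_scale * np.abs(rng.standard_cauchy(size=(n_draws, 1)))
    if prior.beta_prior == "laplace":
        return rng.laplace(0.0, scale, size=(n_draws, J))
    phi = scale * np.abs(rng.standard_cauchy(size=(n_draws, J)))
    return rng.normal(0.0, phi)


def marginal_loglik(params: StructuralParams, data: ObservedData) -> float:
    """Log-likelihood of the marginalized (confounder-integrated) bivariate model."""
    e_x = data.X - params.omega_X - data.Z @ params.alpha
    e_y = data.Y - params.omega_Y - params.theta * data.X - data.Z @ params.beta
    v_x = params.delta_X**2 + params.sigma_X**2
    v_y = params.delta_Y**2 + params.sigma_Y**2
    c = params.delta_X * params.delta_Y
    det = v_x * v_y - c**2
    quad = (v_y * e_x**2 - 2.0 * c * e_x * e_y + v_x * e_y**2) / det
    n = data.n
    return float(-n * math.log(2.0 * math.pi) - 0.5 * n * math.log(det) - 0.5 * quad.sum())
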