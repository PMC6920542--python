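"""Simulation scenarios for the structural Mendelian-randomization model.

A scenario fixes the sample size, instrument count, mean pleiotropic effect,
instrument-strength dispersion and average LD between instruments.  For each
replicate, true structural parameters are drawn afresh and individual-level
(U, X, Y) data are generated from the linear structural equations

    U ~ N(0, 1)
    X | Z, U ~ N(omega_X + sum_j alpha_j Z_j + delta_X U, sigma_X^2)
    Y | X, Z, U ~ N(omega_Y + theta X + sum_j beta_j Z_j + delta_Y U, sigma_Y^2)

where alpha are instrument strengths, beta pleiotropic (direct) effects and
theta the causal effect of interest.  The two-exposure (mediation) variant
adds a second exposure with its own instrument set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .genotypes import Genotypes

__all__ = [
    "ScenarioSpec",
    "StructuralParams",
    "MediationParams",
    "ObservedData",
    "MediationData",
    "benchmark_scenario",
    "draw_structural_params",
    "simulate_dataset",
    "draw_mediation_params",
    "simulate_mediation_dataset",
]

#: causal effect under the alternative regime in the benchmark experiment
THETA_ALTERNATIVE = 0.35

#: shape of the "sharp" inverse-gamma law for residual SDs (CV ~ 14%)
_SIGMA_IG_SHAPE = 50.0


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the 21-scenario benchmark grid (plus generator defaults)."""

    scenario_id: int
    n_individuals: int
    mu_beta: float | tuple[float, float]  # scalar, or a (lo, hi) range re-drawn per replicate
    sigma_alpha: float
    J: int
    target_r2: float
    pleiotropy_fraction: float = 0.40
    mu_alpha: float = -0.07
    sigma_beta_within: float = 0.05
    alpha_sparse: bool = False
    alpha_zero_fraction: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.4)
    fixed_maf: float | None = None  # common MAF (LD scenarios use 0.3)
    sigma_x_mean: float = 0.1
    sigma_y_mean: float = 0.3

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.J < 1:
            raise ValueError("need n_individuals >= 2 and J >= 1")
        if not 0.0 <= self.pleiotropy_fraction <= 1.0:
            raise ValueError("pleiotropy_fraction must lie in [0, 1]")
        if not 0.0 <= self.target_r2 < 1.0:
            raise ValueError("target_r2 must lie in [0, 1)")


# scenario_id -> (n, mu_beta, sigma_alpha, J, target_r2)
_BENCHMARK_ROWS: dict[int, tuple] = {
    1: (500, 0.012, 0.02, 60, 0.0),
    2: (500, 0.006, 0.02, 60, 0.0),
    3: (500, 0.0, 0.02, 60, 0.0),
    4: (500, -0.006, 0.02, 60, 0.0),
    5: (500, -0.012, 0.02, 60, 0.0),
    6: (500, 0.012, 0.02, 20, 0.0),
    7: (500, 0.0, 0.02, 20, 0.0),
    8: (500, -0.012, 0.02, 20, 0.0),
    9: (500, 0.012, 1.0, 60, 0.0),
    10: (500, 0.006, 1.0, 60, 0.0),
    11: (500, 0.0, 1.0, 60, 0.0),
    12: (500, -0.006, 1.0, 60, 0.0),
    13: (500, -0.012, 1.0, 60, 0.0),
    14: (500, (-0.012, 0.012), 0.02, 60, 0.33),
    15: (500, (-0.012, 0.012), 0.02, 60, 0.54),
    16: (500, (-0.012, 0.012), 0.02, 60, 0.63),
    17: (500, (-0.012, 0.012), 0.02, 60, 0.70),
    18: (300, (-0.012, 0.012), 0.02, 60, 0.33),
    19: (300, (-0.012, 0.012), 0.02, 60, 0.53),
    20: (300, (-0.012, 0.012), 0.02, 60, 0.62),
    21: (300, (-0.012, 0.012), 0.02, 60, 0.70),
}


def benchmark_scenario(scenario_id: int) -> ScenarioSpec:
    """The benchmark scenario with the given id (1..21).

    Scenarios 14-21 (correlated instruments) re-draw the mean pleiotropic
    effect per replicate, give every instrument a nonzero pleiotropic effect,
    and zero out the majority of the instrument strengths; they use a common
    MAF so that high LD targets are attainable.
    """
    if scenario_id not in _BENCHMARK_ROWS:
        raise ValueError(f"scenario_id must be in 1..21, got {scenario_id}")
    n, mu_beta, sigma_alpha, J, r2 = _BENCHMARK_ROWS[scenario_id]
    spec = ScenarioSpec(
        scenario_id=scenario_id,
        n_individuals=n,
        mu_beta=mu_beta,
        sigma_alpha=sigma_alpha,
        J=J,
        target_r2=r2,
    )
    if scenario_id >= 14:
        spec = replace(spec, alpha_sparse=True, pleiotropy_fraction=1.0, fixed_maf=0.3)
    return spec


@dataclass
class StructuralParams:
    """True generative parameters of one simulated dataset."""

    theta: float
    alpha: np.ndarray
    beta: np.ndarray
    omega_X: float
    omega_Y: float
    delta_X: float
    delta_Y: float
    sigma_X: float
    sigma_Y: float

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha and beta must have equal length")
        if self.sigma_X <= 0 or self.sigma_Y <= 0:
            raise ValueError("residual SDs must be positive")

    @property
    def tau_X(self) -> float:
        """Total residual SD of X given Z: sqrt(delta_X² + sigma_X²)."""
        return float(np.hypot(self.delta_X, self.sigma_X))

    @property
    def tau_Y(self) -> float:
        return float(np.hypot(self.delta_Y, self.sigma_Y))

    @property
    def lam(self) -> float:
        """Residual covariance between the X and Y equations, delta_X * delta_Y."""
        return self.delta_X * self.delta_Y


@dataclass
class ObservedData:
    """Individual-level data: outcome Y, exposure X, dose matrix Z, optional covariate W.

    U is the latent confounder, retained only for simulated data diagnostics.
    """

    Y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    W: np.ndarray | None = None
    U: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z)
        n = self.Y.size
        if self.X.size != n or self.Z.shape[0] != n:
            raise ValueError("Y, X and Z must share the number of individuals")
        if not np.isin(self.Z, (0, 1, 2)).all():
            raise ValueError("Z entries must be allele doses in {0, 1, 2}")
        if self.W is not None:
            self.W = np.asarray(self.W)
            if self.W.size != n or not np.isin(self.W, (0, 1)).all():
                raise ValueError("W must be a length-n binary covariate")
        if self.U is not None:
            self.U = np.asarray(self.U, dtype=float)
            if self.U.size != n:
                raise ValueError("U must have length n")

    @property
    def n(self) -> int:
        return self.Y.size

    @property
    def J(self) -> int:
        return self.Z.shape[1]


def _draw_sigma(mean: float, rng: np.random.Generator, shape: float = _SIGMA_IG_SHAPE) -> float:
    scale = mean * (shape - 1.0)
    return float(stats.invgamma.rvs(shape, scale=scale, random_state=rng))


def draw_structural_params(
    spec: ScenarioSpec,
    theta_regime: str,
    rng: np.random.Generator,
) -> StructuralParams:
    """Draw true structural parameters for one replicate of a scenario.

    ``theta_regime`` is ``"null"`` (theta = 0) or ``"alternative"``
    (theta = 0.35).  Instrument strengths alpha_j ~ N(mu_alpha, sigma_alpha²);
    a random ``pleiotropy_fraction`` of the beta components are drawn from
    N(mu_beta, sigma_beta_within²) and the rest are exactly zero.  In
    alpha-sparse scenarios mu_beta is re-drawn uniformly on its range and most
    alpha components are then set to zero.
    """
    if theta_regime not in ("null", "alternative"):
        raise ValueError("theta_regime must be 'null' or 'alternative'")
    theta = 0.0 if theta_regime == "null" else THETA_ALTERNATIVE
    J = spec.J
    alpha = rng.normal(spec.mu_alpha, spec.sigma_alpha, size=J)
    if spec.alpha_sparse:
        n_zero = int(round(spec.alpha_zero_fraction * J))
        zero_idx = rng.choice(J, size=n_zero, replace=False)
        alpha[zero_idx] = 0.0
    mu_beta = spec.mu_beta
    if isinstance(mu_beta, tuple):
        mu_beta = float(rng.uniform(*mu_beta))
    beta = np.zeros(J)
    n_pleio = int(round(spec.pleiotropy_fraction * J))
    if n_pleio > 0:
        idx = rng.choice(J, size=n_pleio, replace=False)
        beta[idx] = rng.normal(mu_beta, spec.sigma_beta_within, size=n_pleio)
    return StructuralParams(
        theta=theta,
        alpha=alpha,
        beta=beta,
        omega_X=float(rng.normal(3.3, 0.2)),
        omega_Y=float(rng.normal(0.9, 0.2)),
        delta_X=float(rng.normal(-0.1, 0.02)),
        delta_Y=float(rng.normal(-0.1, 0.02)),
        sigma_X=_draw_sigma(spec.sigma_x_mean, rng),
        sigma_Y=_draw_sigma(spec.sigma_y_mean, rng),
    )


def simulate_dataset(
    params: StructuralParams,
    G: Genotypes,
    rng: np.random.Generator,
) -> ObservedData:
    """Generate one individual-level dataset from the structural equations."""
    if params.alpha.size != G.J:
        raise ValueError("alpha/beta length must equal the number of variants")
    n = G.n
    Z = G.doses
    U = rng.standard_normal(n)
    X = (
        params.omega_X
        + Z @ params.alpha
        + params.delta_X * U
        + params.sigma_X * rng.standard_normal(n)
    )
    Y = (
        params.omega_Y
        + params.theta * X
        + Z @ params.beta
        + params.delta_Y * U
        + params.sigma_Y * rng.standard_normal(n)
    )
    return ObservedData(Y=Y, X=X, Z=Z, U=U)


# ---------------------------------------------------------------------------
# two-exposure (mediation) generator
# ---------------------------------------------------------------------------


@dataclass
class MediationParams:
    """True parameters of the two-exposure structural model.

    theta1: direct effect of X1 on Y controlling for X2; theta2: effect of X1
    on X2; theta3: effect of X2 on Y.  Instrument set I1 (length J1) targets
    X1 with strengths alpha1; I2 (length J2) targets X2 with strengths alpha2
    and may affect X1 with strengths alpha3.  beta1 (J1) and beta2 (J2) are
    pleiotropic effects on Y; beta3 (J1) are direct I1 -> X2 effects.
    """

    theta1: float
    theta2: float
    theta3: float
    alpha1: np.ndarray
    alpha2: np.ndarray
    alpha3: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    beta3: np.ndarray
    omega1: float = 0.0
    omega2: float = 0.0
    omegaY: float = 0.0
    delta1: float = 0.0
    delta2: float = 0.0
    delta3: float = 0.0
    sigma1: float = 1.0
    sigma2: float = 1.0
    sigmaY: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3", "beta1", "beta2", "beta3"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        J1, J2 = self.alpha1.size, self.alpha2.size
        if self.alpha3.size != J2 or self.beta2.size != J2:
            raise ValueError("alpha3 and beta2 must have length J2")
        if self.beta1.size != J1 or self.beta3.size != J1:
            raise ValueError("beta1 and beta3 must have length J1")
        if min(self.sigma1, self.sigma2, self.sigmaY) <= 0:
            raise ValueError("residual SDs must be positive")

    @property
    def J1(self) -> int:
        return self.alpha1.size

    @property
    def J2(self) -> int:
        return self.alpha2.size


@dataclass
class MediationData:
    """Individual-level two-exposure data: Y, X1, X2 and the two dose blocks."""

    Y: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    I1: np.ndarray
    I2: np.ndarray
    U: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.X1 = np.asarray(self.X1, dtype=float)
        self.X2 = np.asarray(self.X2, dtype=float)
        self.I1 = np.asarray(self.I1)
        self.I2 = np.asarray(self.I2)
        n = self.Y.size
        if not (self.X1.size == self.X2.size == n == self.I1.shape[0] == self.I2.shape[0]):
            raise ValueError("all fields must share the number of individuals")
        for M in (self.I1, self.I2):
            if not np.isin(M, (0, 1, 2)).all():
                raise ValueError("instrument doses must lie in {0, 1, 2}")

    @property
    def n(self) -> int:
        return self.Y.size

    @property
    def J1(self) -> int:
        return self.I1.shape[1]

    @property
    def J2(self) -> int:
        return self.I2.shape[1]


def draw_mediation_params(
    J1: int,
    J2: int,
    rng: np.random.Generator,
    theta1: float = 0.3,
    theta2: float = 0.5,
    theta3: float = 0.4,
    pleiotropy_fraction: float = 0.0,
    mu_alpha: float = 0.15,
    sigma_alpha: float = 0.05,
    sigma_beta: float = 0.05,
) -> MediationParams:
    """Draw plausible mediation parameters (defaults: no pleiotropy, modest effects)."""

    def sparse_beta(J: int) -> np.ndarray:
        b = np.zeros(J)
        k = int(round(pleiotropy_fraction * J))
        if k > 0:
            idx = rng.choice(J, size=k, replace=False)
            b[idx] = rng.normal(0.0, sigma_beta, size=k)
        return b

    return MediationParams(
        theta1=theta1,
        theta2=theta2,
        theta3=theta3,
        alpha1=rng.normal(mu_alpha, sigma_alpha, size=J1),
        alpha2=rng.normal(mu_alpha, sigma_alpha, size=J2),
        alpha3=rng.normal(0.0, sigma_alpha, size=J2),
        beta1=sparse_beta(J1),
        beta2=sparse_beta(J2),
        beta3=sparse_beta(J1),
        omega1=float(rng.normal(0.0, 0.2)),
        omega2=float(rng.normal(0.0, 0.2)),
        omegaY=float(rng.normal(0.0, 0.2)),
        delta1=-0.1,
        delta2=-0.1,
        delta3=-0.1,
        sigma1=0.3,
        sigma2=0.3,
        sigmaY=0.3,
    )


def simulate_mediation_dataset(
    params: MediationParams,
    G1: Genotypes,
    G2: Genotypes,
    rng: np.random.Generator,
) -> MediationData:
    """Generate (X1, X2, Y) from the two-exposure structural equations.

    G1 and G2 are independently generated dose matrices (the model assumes
    the two instrument sets are non-overlapping and mutually independent).
    """
    if params.J1 != G1.J or params.J2 != G2.J:
        raise ValueError("instrument-strength lengths must match the dose matrices")
    if G1.n != G2.n:
        raise ValueError("G1 and G2 must cover the same individuals")
    n = G1.n
    I1, I2 = G1.doses, G2.doses
    U = rng.standard_normal(n)
    X1 = (
        params.omega1
        + I1 @ params.alpha1
        + I2 @ params.alpha3
        + params.delta1 * U
        + params.sigma1 * rng.standard_normal(n)
    )
    X2 = (
        params.omega2
        + params.theta2 * X1
        + I1 @ params.beta3
        + I2 @ params.alpha2
        + params.delta2 * U
        + params.sigma2 * rng.standard_normal(n)
    )
    Y = (
        params.omegaY
        + params.theta1 * X1
        + params.theta3 * X2
        + I1 @ params.beta1
        + I2 @ params.beta2
        + params.delta3 * U
        + params.sigmaY * rng.standard_normal(n)
    )
    return MediationData(Y=Y, X1=X1, X2=X2, I1=I1, I2=I2, U=U)
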