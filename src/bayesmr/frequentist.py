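"""Frequentist comparator estimators: per-instrument ratios, weighted median, Egger.

The weighted median estimator (WME) takes the per-instrument ratio estimates
beta_Yj / beta_Xj, orders them, and interpolates the weighted empirical CDF at
probability one half; it is consistent when at least half of the total weight
lies on valid (non-pleiotropic) instruments.  Egger regression regresses the
instrument-outcome associations on the instrument-exposure associations
(after recoding alleles so all exposure associations are positive); the slope
estimates the causal effect and the intercept the average directional
pleiotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentSummary",
    "EstimateWithInterval",
    "per_instrument_associations",
    "ratio_estimates",
    "weighted_median",
    "wme_with_ci",
    "egger_regression",
    "write_summary",
    "read_summary",
]


@dataclass
class InstrumentSummary:
    """Marginal OLS slopes (and SEs) of X on each Z_j and of Y on each Z_j."""

    beta_X: np.ndarray
    se_X: np.ndarray
    beta_Y: np.ndarray
    se_Y: np.ndarray
    variant_ids: list[str] | None = None

    def __post_init__(self) -> None:
        for name in ("beta_X", "se_X", "beta_Y", "se_Y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        J = self.beta_X.size
        if not (self.se_X.size == self.beta_Y.size == self.se_Y.size == J):
            raise ValueError("all four vectors must have equal length")
        if (self.se_X <= 0).any() or (self.se_Y <= 0).any():
            raise ValueError("standard errors must be positive")
        if self.variant_ids is None:
            self.variant_ids = [f"V{j + 1}" for j in range(J)]

    @property
    def J(self) -> int:
        return self.beta_X.size


@dataclass
class EstimateWithInterval:
    """A point estimate with a (lower, upper) interval at a nominal level."""

    point: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = ""

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval must satisfy lower <= upper")
        if not (self.lower <= self.point <= self.upper):
            # percentile bootstrap intervals may exclude the full-sample point
            logger.warning(
                "%s: point %.4g outside interval [%.4g, %.4g]",
                self.method or "estimate",
                self.point,
                self.lower,
                self.upper,
            )

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def _marginal_ols(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form simple OLS of y on each column of Z, vectorized over columns."""
    n = y.size
    zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    szz = np.einsum("ij,ij->j", zc, zc)
    szy = zc.T @ yc
    slope = szy / szz
    syy = yc @ yc
    rss = syy - slope * szy
    se = np.sqrt(np.maximum(rss, 0.0) / ((n - 2) * szz))
    # exact fits give rss = 0; keep SEs strictly positive for downstream weights
    return slope, np.maximum(se, np.sqrt(np.finfo(float).tiny))


def per_instrument_associations(data) -> InstrumentSummary:
    """Marginal (one-instrument-at-a-time, with intercept) OLS of X and Y on each Z_j."""
    Z = np.asarray(data.Z, dtype=float)
    n = Z.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals")
    sd = Z.std(axis=0)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"constant dose column(s) {bad}: marginal slope undefined")
    bx, sx = _marginal_ols(Z, np.asarray(data.X, dtype=float))
    by, sy = _marginal_ols(Z, np.asarray(data.Y, dtype=float))
    return InstrumentSummary(beta_X=bx, se_X=sx, beta_Y=by, se_Y=sy)


def ratio_estimates(s: InstrumentSummary) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument IV ratio estimates and first-order inverse-variance weights.

    ratio_j = beta_Yj / beta_Xj; weight_j = beta_Xj² / se_Yj².
    """
    if (s.beta_X == 0).any():
        bad = np.flatnonzero(s.beta_X == 0).tolist()
        raise ValueError(f"zero exposure association for instrument(s) {bad}: ratio undefined")
    ratios = s.beta_Y / s.beta_X
    weights = s.beta_X**2 / s.se_Y**2
    return ratios, weights


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median.

    Sort the values; with cumulative weight S_j and total S_J, assign each
    sorted value the standardized mid-cumulative probability
    p_j = (S_{j-1} + w_j/2) / S_J and linearly interpolate the sorted values
    at p = 0.5.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if (weights <= 0).any():
        raise ValueError("weights must be positive")
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    p = (cw - w / 2.0) / cw[-1]
    return float(np.interp(0.5, p, v))


def _weighted_median_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise interpolated weighted median for a batch (B x J) of instances."""
    order = np.argsort(values, axis=1, kind="stable")
    v = np.take_along_axis(values, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    cw = np.cumsum(w, axis=1)
    p = (cw - w / 2.0) / cw[:, -1:]
    # linear interpolation of each row's step function at 0.5
    idx = np.sum(p < 0.5, axis=1)  # first index with p >= 0.5
    B, J = values.shape
    out = np.empty(B)
    at_left = idx == 0
    at_right = idx == J
    mid = ~(at_left | at_right)
    out[at_left] = v[at_left, 0]
    out[at_right] = v[at_right, -1]
    if mid.any():
        i = idx[mid]
        rows = np.flatnonzero(mid)
        p0, p1 = p[rows, i - 1], p[rows, i]
        v0, v1 = v[rows, i - 1], v[rows, i]
        frac = (0.5 - p0) / (p1 - p0)
        out[mid] = v0 + frac * (v1 - v0)
    return out


def _bootstrap_wme(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    max_redraw_rounds: int = 20,
) -> tuple[np.ndarray, int]:
    """Percentile-bootstrap WME replicates via sufficient-statistic matrix products.

    Individual-level resamples are encoded as multinomial count vectors; every
    per-column OLS sum is then a single matrix product of the count matrix with
    a per-row feature matrix.  Resamples in which some instrument has zero
    exposure association (or a constant dose column) are redrawn.
    """
    n, J = Z.shape
    # per-row features: Z, Z², Z·x, Z·y, then x, x², y, y², x·y is not needed
    M = np.empty((n, 4 * J + 4))
    M[:, :J] = Z
    M[:, J : 2 * J] = Z * Z
    M[:, 2 * J : 3 * J] = Z * X[:, None]
    M[:, 3 * J : 4 * J] = Z * Y[:, None]
    M[:, 4 * J] = X
    M[:, 4 * J + 1] = X * X
    M[:, 4 * J + 2] = Y
    M[:, 4 * J + 3] = Y * Y

    estimates = np.empty(n_boot)
    need = np.arange(n_boot)
    n_redrawn = 0
    p = np.full(n, 1.0 / n)
    for _ in range(max_redraw_rounds):
        B = need.size
        C = rng.multinomial(n, p, size=B).astype(float)
        S = C @ M
        sz = S[:, :J]
        szz = S[:, J : 2 * J] - sz * sz / n
        szx = S[:, 2 * J : 3 * J] - sz * S[:, [4 * J]] / n
        szy = S[:, 3 * J : 4 * J] - sz * S[:, [4 * J + 2]] / n
        syy = S[:, [4 * J + 3]] - S[:, [4 * J + 2]] ** 2 / n
        with np.errstate(divide="ignore", invalid="ignore"):
            bx = szx / szz
            by = szy / szz
            rss_y = syy - by * szy
            se_y2 = np.maximum(rss_y, 0.0) / ((n - 2) * szz)
            ratios = by / bx
            weights = bx**2 / se_y2
        ok = (
            (szz > 0).all(axis=1)
            & (bx != 0).all(axis=1)
            & np.isfinite(ratios).all(axis=1)
            & (weights > 0).all(axis=1)
        )
        if ok.any():
            estimates[need[ok]] = _weighted_median_rows(ratios[ok], weights[ok])
        need = need[~ok]
        if need.size == 0:
            break
        n_redrawn += need.size
    else:
        raise RuntimeError("bootstrap resampling kept producing degenerate instruments")
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap resample(s)", n_redrawn)
    return estimates, n_redrawn


def _summary_bootstrap_wme(
    s: InstrumentSummary, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Parametric bootstrap from summary statistics (independent normal errors)."""
    bx = rng.normal(s.beta_X, s.se_X, size=(n_boot, s.J))
    by = rng.normal(s.beta_Y, s.se_Y, size=(n_boot, s.J))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = by / bx
        weights = bx**2 / s.se_Y**2
    bad = ~np.isfinite(ratios).all(axis=1) | (weights <= 0).any(axis=1)
    if bad.any():
        keep = ~bad
        logger.info("dropping %d degenerate parametric resample(s)", int(bad.sum()))
        ratios, weights = ratios[keep], weights[keep]
    return _weighted_median_rows(ratios, weights)


def wme_with_ci(
    data,
    n_boot: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
    scheme: str = "individual",
) -> EstimateWithInterval:
    """WME point estimate with a bootstrapped confidence interval.

    ``scheme="individual"`` (default) resamples individuals nonparametrically
    and recomputes the marginal associations, ratio estimates and weighted
    median on each resample, taking percentile interval endpoints.
    ``scheme="summary"`` is the recipe of the standard WME implementations: a
    parametric bootstrap that redraws each per-instrument association from an
    independent normal around its estimate, with a normal-theory interval
    ``point ± z * SD(bootstrap)``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if scheme not in ("individual", "summary"):
        raise ValueError("scheme must be 'individual' or 'summary'")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    s = per_instrument_associations(data)
    ratios, weights = ratio_estimates(s)
    point = weighted_median(ratios, weights)
    if scheme == "individual":
        X = np.asarray(data.X, dtype=float)
        Y = np.asarray(data.Y, dtype=float)
        Z = np.asarray(data.Z, dtype=float)
        boots, _ = _bootstrap_wme(X, Y, Z, n_boot, rng)
        a = (1.0 - level) / 2.0
        lower, upper = np.quantile(boots, [a, 1.0 - a])
    else:
        boots = _summary_bootstrap_wme(s, n_boot, rng)
        z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
        sd = float(boots.std())
        lower, upper = point - z * sd, point + z * sd
    return EstimateWithInterval(
        point=point, lower=float(lower), upper=float(upper), level=level,
        method=f"WME[{scheme}]",
    )


def egger_regression(
    s: InstrumentSummary, level: float = 0.95
) -> tuple[EstimateWithInterval, EstimateWithInterval]:
    """Egger regression of outcome associations on exposure associations.

    Instruments with a negative exposure association are recoded (both
    associations jointly sign-flipped) first.  A weighted least-squares fit
    with weights 1/se_Y² returns the slope (causal-effect estimate) and
    intercept (average directional pleiotropy) with normal-theory intervals on
    J - 2 degrees of freedom.
    """
    J = s.J
    if J < 3:
        raise ValueError("Egger regression needs at least 3 instruments")
    sign = np.where(s.beta_X < 0, -1.0, 1.0)
    bx = s.beta_X * sign
    by = s.beta_Y * sign
    if np.ptp(bx) == 0:
        raise ValueError("exposure associations identical after recoding: singular design")
    w = 1.0 / s.se_Y**2
    sw = w.sum()
    xbar = (w * bx).sum() / sw
    ybar = (w * by).sum() / sw
    sxx = (w * (bx - xbar) ** 2).sum()
    slope = (w * (bx - xbar) * (by - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    resid = by - intercept - slope * bx
    sigma2 = (w * resid**2).sum() / (J - 2)
    se_slope = np.sqrt(sigma2 / sxx)
    se_intercept = np.sqrt(sigma2 * (1.0 / sw + xbar**2 / sxx))
    tq = stats.t.ppf(1.0 - (1.0 - level) / 2.0, df=J - 2)
    slope_est = EstimateWithInterval(
        point=float(slope),
        lower=float(slope - tq * se_slope),
        upper=float(slope + tq * se_slope),
        level=level,
        method="Egger slope",
    )
    intercept_est = EstimateWithInterval(
        point=float(intercept),
        lower=float(intercept - tq * se_intercept),
        upper=float(intercept + tq * se_intercept),
        level=level,
        method="Egger intercept",
    )
    return slope_est, intercept_est


def write_summary(s: InstrumentSummary, path) -> None:
    """Write per-instrument summary statistics as tab-separated text."""
    pd.DataFrame(
        {
            "variant_id": s.variant_ids,
            "beta_X": s.beta_X,
            "se_X": s.se_X,
            "beta_Y": s.beta_Y,
            "se_Y": s.se_Y,
        }
    ).to_csv(path, sep="\t", index=False)


def read_summary(path) -> InstrumentSummary:
    """Read per-instrument summary statistics (two-sample-style input)."""
    df = pd.read_csv(path, sep="\t")
    required = ["variant_id", "beta_X", "se_X", "beta_Y", "se_Y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"summary file missing column(s): {missing}")
    return InstrumentSummary(
        beta_X=df["beta_X"].to_numpy(),
        se_X=df["se_X"].to_numpy(),
        beta_Y=df["beta_Y"].to_numpy(),
        se_Y=df["se_Y"].to_numpy(),
        variant_ids=df["variant_id"].astype(str).tolist(),
    )
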