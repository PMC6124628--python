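"""Comparator causal-effect estimators for summary-data Mendelian randomization.

Implements the standard toolkit the model-averaging method is benchmarked
against: inverse-variance weighted (IVW) estimation under fixed-effect and
multiplicative random-effects models, MR-Egger regression, the simple and
weighted median estimators, and the kernel-smoothed mode-based estimate
(MBE).  All operate purely on summarized per-variant associations.

The multiplicative random-effects model inflates standard errors by the
residual standard error psi of the weighted regression of beta_y on beta_x,
floored at 1 so a random-effects interval is never narrower than the
fixed-effect one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize, stats

from .io import RatioEstimates, SummarizedData, ValidationError, ratio_estimates

__all__ = [
    "EstimatorResult",
    "ivw",
    "mr_egger",
    "median_estimate",
    "mbe",
    "weighted_median",
    "silverman_bandwidth",
    "ESTIMATOR_REGISTRY",
]

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class EstimatorResult:
    """Causal estimate with a symmetric normal 95% confidence interval."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    psi: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    n_variants: int = 0

    @property
    def excludes_null(self) -> bool:
        return self.ci_low > 0.0 or self.ci_high < 0.0


def _normal_result(method, estimate, se, n, psi=None, intercept=None,
                   intercept_se=None) -> EstimatorResult:
    return EstimatorResult(
        method=method,
        estimate=float(estimate),
        se=float(se),
        ci_low=float(estimate - Z95 * se),
        ci_high=float(estimate + Z95 * se),
        psi=psi,
        intercept=intercept,
        intercept_se=intercept_se,
        n_variants=int(n),
    )


def ivw(data: SummarizedData, model: str = "random") -> EstimatorResult:
    """Inverse-variance weighted estimate.

    The estimate is the precision-weighted mean of the variant-specific
    ratio estimates, equivalently the slope of the zero-intercept weighted
    regression of beta_y on beta_x with weights 1/se_y^2.  Under
    ``model="random"`` the fixed-effect standard error is multiplied by the
    residual standard error psi of that regression, floored at 1.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    r = ratio_estimates(data)
    w = r.se_theta ** -2
    sw = w.sum()
    if sw <= 0:
        raise ValidationError("degenerate data: no positive weights")
    estimate = float(np.sum(w * r.theta) / sw)
    se_fixed = sw ** -0.5
    J = data.J
    psi = 1.0
    if J >= 2:
        # residual standard error of beta_y = theta*beta_x with weights se_y^-2
        resid = data.beta_y - estimate * data.beta_x
        q = float(np.sum((resid / data.se_y) ** 2))
        psi = max(1.0, np.sqrt(q / (J - 1)))
    se = se_fixed * psi if model == "random" else se_fixed
    return _normal_result("ivw_" + model, estimate, se, J,
                          psi=psi if model == "random" else 1.0)


def mr_egger(data: SummarizedData) -> EstimatorResult:
    """MR-Egger regression with multiplicative random effects.

    Weighted linear regression of beta_y on beta_x *with* an intercept,
    weights 1/se_y^2; the slope is the causal estimate and the intercept
    captures average directional pleiotropy.  psi is floored at 1.  Not
    invariant to allele re-orientation of individual variants; variants are
    used as supplied.
    """
    J = data.J
    if J < 3:
        raise ValidationError(f"MR-Egger needs at least 3 variants, got {J}")
    w = data.se_y ** -2.0
    X = np.column_stack([np.ones(J), data.beta_x])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    xtwy = WX.T @ data.beta_y
    coef = np.linalg.solve(xtwx, xtwy)
    resid = data.beta_y - X @ coef
    q = float(np.sum(w * resid ** 2))
    psi = max(1.0, np.sqrt(q / (J - 2)))
    cov_unit = np.linalg.inv(xtwx)
    se_slope = psi * np.sqrt(cov_unit[1, 1])
    se_int = psi * np.sqrt(cov_unit[0, 0])
    return _normal_result("mr_egger", coef[1], se_slope, J, psi=psi,
                          intercept=float(coef[0]), intercept_se=float(se_int))


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median at the 50th cumulative-weight percentile.

    Sorts ``values``, forms standardized mid-point cumulative weights
    p_j = (cum_j - w_j/2) / sum(w), and linearly interpolates the value at
    p = 1/2.  With equal weights this reproduces the ordinary median.
    """
    order = np.argsort(values)
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    csum = np.cumsum(w)
    p = (csum - 0.5 * w) / csum[-1]
    return float(np.interp(0.5, p, v))


def median_estimate(
    data: SummarizedData,
    weighted: bool = False,
    n_boot: int = 1000,
    seed: int | None = None,
) -> EstimatorResult:
    """Simple or weighted median of the variant-specific ratio estimates.

    The simple median is robust when at least 50% of variants are valid;
    the weighted median when valid variants carry at least 50% of the
    inverse-variance weight.  The standard error comes from a parametric
    bootstrap: resample theta_j ~ N(theta_j, se_theta_j) and take the SD of
    the recomputed medians.
    """
    J = data.J
    if J < 3:
        raise ValidationError(f"median estimator needs >= 3 variants, got {J}")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; bootstrap SE will be noisy", n_boot)
    r = ratio_estimates(data)
    w = r.se_theta ** -2 if weighted else np.ones(J)
    estimate = weighted_median(r.theta, w) if weighted else float(np.median(r.theta))
    rng = np.random.default_rng(seed)
    draws = rng.normal(r.theta, r.se_theta, size=(n_boot, J))
    if weighted:
        boot = np.array([weighted_median(row, w) for row in draws])
    else:
        boot = np.median(draws, axis=1)
    se = float(np.std(boot, ddof=1))
    name = "median_weighted" if weighted else "median_simple"
    return _normal_result(name, estimate, se, J)


def silverman_bandwidth(theta: np.ndarray, phi: float = 1.0,
                        constant: float = 0.9) -> float:
    """Modified Silverman rule-of-thumb bandwidth on the ratio estimates.

    h = phi * constant * min(SD, 1.4826*MAD) * J^(-1/5).  Returns 0.0 when
    all estimates coincide.
    """
    theta = np.asarray(theta, dtype=float)
    J = theta.size
    s = float(np.std(theta, ddof=1))
    mad = 1.4826 * float(np.median(np.abs(theta - np.median(theta))))
    scale = min(x for x in (s, mad) if x > 0) if (s > 0 or mad > 0) else 0.0
    return phi * constant * scale * J ** (-0.2)


def _mixture_mode(theta: np.ndarray, weights: np.ndarray, h: float,
                  n_grid: int = 2048) -> float:
    """Mode of the weighted normal-kernel density, grid search + refinement."""
    lo = theta.min() - 3.0 * h
    hi = theta.max() + 3.0 * h
    grid = np.linspace(lo, hi, n_grid)
    dens = weights @ np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h) ** 2)
    i = int(np.argmax(dens))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]

    def neg(x: float) -> float:
        return -float(weights @ np.exp(-0.5 * ((x - theta) / h) ** 2))

    res = optimize.minimize_scalar(neg, bounds=(a, b), method="bounded")
    return float(res.x)


def mbe(
    data: SummarizedData,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    silverman_constant: float = 0.9,
) -> EstimatorResult:
    """Mode-based estimate: mode of a kernel-smoothed ratio-estimate density.

    Consistent when a plurality of variants share the true ratio estimate
    (zero modal pleiotropy).  Kernel weights are equal (simple) or
    proportional to 1/se_theta^2 (weighted); the bandwidth is ``phi`` times
    the modified Silverman rule.  No "no measurement error" assumption is
    made: se_theta comes from the first-order delta method throughout.  The
    standard error is the normal-scaled median absolute deviation of
    parametric-bootstrap modal estimates.
    """
    J = data.J
    if J < 3:
        raise ValidationError(f"MBE needs at least 3 variants, got {J}")
    if phi <= 0:
        raise ValueError("phi must be positive")
    r = ratio_estimates(data)
    w = r.se_theta ** -2 if weighted else np.ones(J)
    w = w / w.sum()
    h = silverman_bandwidth(r.theta, phi=phi, constant=silverman_constant)
    if h == 0.0:
        estimate = float(r.theta[0])  # all ratio estimates identical
    else:
        estimate = _mixture_mode(r.theta, w, h)
    rng = np.random.default_rng(seed)
    draws = rng.normal(r.theta, r.se_theta, size=(n_boot, J))
    boot = np.empty(n_boot)
    for b, row in enumerate(draws):
        hb = silverman_bandwidth(row, phi=phi, constant=silverman_constant)
        boot[b] = row[0] if hb == 0.0 else _mixture_mode(row, w, hb, n_grid=512)
    se = float(1.4826 * np.median(np.abs(boot - np.median(boot))))
    name = "mbe_weighted" if weighted else "mbe_simple"
    return _normal_result(name, estimate, se, J)


def _hpma_wrapper(data: SummarizedData, seed: int | None = None) -> EstimatorResult:
    # late import avoids a module cycle; exposes the model-averaging method
    # through the same registry interface as the comparators
    from .hpma import hpma_estimate

    result, _ = hpma_estimate(data)
    lo = result.confidence_set[0][0]
    hi = result.confidence_set[-1][1]
    se = result.normal_approx_se or float("nan")
    return EstimatorResult(
        method="hpma", estimate=result.estimate, se=se,
        ci_low=lo, ci_high=hi, n_variants=data.J,
    )


ESTIMATOR_REGISTRY: dict[str, Callable[..., EstimatorResult]] = {
    "ivw": lambda data, seed=None: ivw(data, model="random"),
    "ivw-fixed": lambda data, seed=None: ivw(data, model="fixed"),
    "egger": lambda data, seed=None: mr_egger(data),
    "median-simple": lambda data, seed=None: median_estimate(data, weighted=False, seed=seed),
    "median-weighted": lambda data, seed=None: median_estimate(data, weighted=True, seed=seed),
    "mbe-simple": lambda data, seed=None: mbe(data, weighted=False, seed=seed),
    "mbe-weighted": lambda data, seed=None: mbe(data, weighted=True, seed=seed),
    "hpma": _hpma_wrapper,
}
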