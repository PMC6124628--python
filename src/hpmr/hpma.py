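"""Heterogeneity-penalized model averaging over subsets of genetic variants.

The estimator considers every subset of at least two variants as a
candidate model (2^J - J - 1 models for J variants; single-variant subsets
are excluded because heterogeneity cannot be assessed on them).  Each
subset k contributes a normal distribution centred at its IVW estimate with
the multiplicative random-effects standard error, and receives an
unnormalized weight

    w_k = prod_{j in k} se(theta_j)^(-1) * exp[-(theta_j - theta_IVW,k)^2
                                               / (2 se(theta_j)^2)]

which grows with subset size through the se^(-1) terms but collapses
rapidly when the subset's ratio estimates are more heterogeneous than
sampling error allows.  The causal estimate is the mode of the resulting
weighted normal mixture; a generalized likelihood-ratio argument gives a
confidence set as all grid points whose twice-log-likelihood is within the
chi-squared(1) quantile (3.841 at 95%) of the maximum.  The set may be a
union of disjoint intervals when the mixture is multimodal, which is a
feature: it signals groups of variants supporting distinct causal effects.

All weight arithmetic is carried out in log space with log-sum-exp
normalization, since the raw product in w_k under- or overflows for
moderate J.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2

from .io import SummarizedData, ValidationError, ratio_estimates

__all__ = [
    "SubsetModel",
    "WeightedMixture",
    "CausalResult",
    "enumerate_subsets",
    "subset_ivw",
    "subset_log_weight",
    "build_mixture",
    "loglik",
    "mode_and_ci",
    "hpma_estimate",
    "MAX_VARIANTS",
]

logger = logging.getLogger(__name__)

#: enumeration cap: the model count 2^J - J - 1 doubles per added variant
MAX_VARIANTS = 20

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class SubsetModel:
    """One candidate model: a variant subset and its IVW summary."""

    mask: np.ndarray  # boolean, length J
    K: int  # number of included variants
    theta_ivw: float  # subset IVW estimate
    psi: float  # over-dispersion, >= 1
    se_re: float  # random-effects standard error
    log_weight: float  # unnormalized log weight (prior included)
    weight_norm: float  # normalized weight in [0, 1]


@dataclass(frozen=True)
class WeightedMixture:
    """The full collection of subset models defining the likelihood of theta."""

    J: int
    prior_p: float
    means: np.ndarray  # theta_ivw per subset
    sds: np.ndarray  # se_re per subset
    log_weights_norm: np.ndarray  # log normalized weights, logsumexp == 0
    masks: np.ndarray  # (n_subsets, J) boolean
    psis: np.ndarray

    @property
    def n_components(self) -> int:
        return self.means.size

    def components(self) -> list[SubsetModel]:
        return [
            SubsetModel(
                mask=self.masks[k],
                K=int(self.masks[k].sum()),
                theta_ivw=float(self.means[k]),
                psi=float(self.psis[k]),
                se_re=float(self.sds[k]),
                log_weight=float(self.log_weights_norm[k]),
                weight_norm=float(np.exp(self.log_weights_norm[k])),
            )
            for k in range(self.n_components)
        ]

    def weight_table(self) -> pd.DataFrame:
        """Per-subset summary, heaviest subsets first."""
        K = self.masks.sum(axis=1)
        df = pd.DataFrame(
            {
                "subset": ["".join("1" if m else "0" for m in row) for row in self.masks],
                "K": K.astype(int),
                "theta_ivw": self.means,
                "psi": self.psis,
                "se_re": self.sds,
                "weight": np.exp(self.log_weights_norm),
            }
        )
        return df.sort_values("weight", ascending=False, ignore_index=True)


@dataclass(frozen=True)
class CausalResult:
    """Modal estimate and composite likelihood-ratio confidence set."""

    estimate: float
    confidence_set: tuple  # ordered disjoint (lo, hi) pairs
    level: float
    grid: tuple  # (lo, hi, step)
    loglik_at_mode: float
    multimodal: bool
    method: str = "hpma"

    @property
    def normal_approx_se(self) -> float | None:
        """Half-width of a single-interval set divided by z_{0.975}.

        Diagnostic only; the method itself reports no standard error.
        Undefined (None) for composite sets.
        """
        if len(self.confidence_set) != 1:
            return None
        lo, hi = self.confidence_set[0]
        return (hi - lo) / 2.0 / 1.959963984540054

    def excludes(self, value: float) -> bool:
        return not any(lo <= value <= hi for lo, hi in self.confidence_set)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "confidence_set": [[lo, hi] for lo, hi in self.confidence_set],
            "level": self.level,
            "grid": {"lo": self.grid[0], "hi": self.grid[1], "step": self.grid[2]},
            "loglik_at_mode": self.loglik_at_mode,
            "multimodal": self.multimodal,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CausalResult":
        return cls(
            estimate=d["estimate"],
            confidence_set=tuple((lo, hi) for lo, hi in d["confidence_set"]),
            level=d["level"],
            grid=(d["grid"]["lo"], d["grid"]["hi"], d["grid"]["step"]),
            loglik_at_mode=d["loglik_at_mode"],
            multimodal=d["multimodal"],
            method=d.get("method", "hpma"),
        )


_mask_cache: dict[int, np.ndarray] = {}


def enumerate_subsets(J: int, max_variants: int = MAX_VARIANTS) -> np.ndarray:
    """All variant subsets of size >= 2 as a boolean (2^J - J - 1, J) array.

    Deterministic order: increasing subset size, lexicographic within size.
    Raises for J above the cap, where exhaustive enumeration becomes
    infeasible and pruning or stochastic search would be required.
    """
    if J < 2:
        raise ValidationError(f"need at least 2 variants, got {J}")
    if J > max_variants:
        raise ValidationError(
            f"J={J} exceeds the subset-enumeration cap ({max_variants}): "
            f"2^J - J - 1 models double with each added variant; prune "
            f"variants or raise max_variants explicitly"
        )
    if J in _mask_cache:
        return _mask_cache[J]
    masks = np.zeros((2 ** J - J - 1, J), dtype=bool)
    row = 0
    for size in range(2, J + 1):
        for combo in combinations(range(J), size):
            masks[row, list(combo)] = True
            row += 1
    _mask_cache[J] = masks
    return masks


def subset_ivw(
    data: SummarizedData, mask: np.ndarray, psi_scale: str = "sd"
) -> tuple[float, float, float]:
    """IVW estimate, over-dispersion and random-effects SE for one subset.

    Returns ``(theta_ivw, psi, se_re)`` where ``psi = max(1,
    sqrt(Q/(K-1)))`` with Q the weighted heterogeneity statistic of the
    subset (``psi_scale="var"`` drops the square root, treating the printed
    formula as a variance ratio), and ``se_re = psi / sqrt(sum of ratio
    precisions)``.
    """
    mask = np.asarray(mask, dtype=bool)
    K = int(mask.sum())
    if K < 2:
        raise ValidationError("subset must contain at least 2 variants")
    r = ratio_estimates(data)
    w = r.se_theta[mask] ** -2
    theta_k = float(np.sum(w * r.theta[mask]) / w.sum())
    resid = data.beta_y[mask] - theta_k * data.beta_x[mask]
    q = float(np.sum((resid / data.se_y[mask]) ** 2))
    ratio = q / (K - 1)
    psi = max(1.0, np.sqrt(ratio) if psi_scale == "sd" else ratio)
    se_re = psi / np.sqrt(w.sum())
    return theta_k, psi, float(se_re)


def subset_log_weight(
    data: SummarizedData, mask: np.ndarray, theta_ivw: float
) -> float:
    """Log of the unnormalized heterogeneity-penalized weight for a subset.

    log w_k = sum_{j in k} [ -log se(theta_j)
                             - (theta_j - theta_IVW,k)^2 / (2 se(theta_j)^2) ].
    """
    mask = np.asarray(mask, dtype=bool)
    r = ratio_estimates(data)
    se = r.se_theta[mask]
    dev = r.theta[mask] - theta_ivw
    return float(np.sum(-np.log(se) - dev ** 2 / (2.0 * se ** 2)))


def build_mixture(
    data: SummarizedData,
    prior_p: float = 0.5,
    psi_scale: str = "sd",
    max_variants: int = MAX_VARIANTS,
) -> WeightedMixture:
    """Assemble the weighted normal mixture over all variant subsets.

    ``prior_p`` is the prior probability that any one variant is a valid
    instrument; subset k receives the prior factor
    prior_p^K * (1 - prior_p)^(J - K) on its weight.  The default 0.5
    multiplies every subset by the same constant and so reproduces the
    equal-prior analysis exactly.  Weights are normalized with log-sum-exp.
    """
    if not 0.0 < prior_p < 1.0:
        raise ValueError("prior_p must lie strictly between 0 and 1")
    J = data.J
    masks = enumerate_subsets(J, max_variants=max_variants)
    M = masks.astype(float)
    r = ratio_estimates(data)
    w = r.se_theta ** -2  # ratio-estimate precisions

    # subset sums via a single mask matmul each; theta_IVW,k = S_wt / S_w
    s_w = M @ w
    s_wt = M @ (w * r.theta)
    s_wt2 = M @ (w * r.theta ** 2)
    means = s_wt / s_w

    # Q_k = sum_j w_j (theta_j - theta_k)^2 collapses to moment sums
    K = masks.sum(axis=1)
    q = s_wt2 - means ** 2 * s_w
    q = np.maximum(q, 0.0)  # guard tiny negative round-off
    ratio = q / (K - 1)
    psis = np.maximum(1.0, np.sqrt(ratio) if psi_scale == "sd" else ratio)
    sds = psis / np.sqrt(s_w)

    # log w_k = -sum log se_j - Q_k / 2, then the validity prior
    log_w = M @ (-np.log(r.se_theta)) - 0.5 * q
    log_w = log_w + K * np.log(prior_p) + (J - K) * np.log1p(-prior_p)
    log_norm = log_w - logsumexp(log_w)
    if not np.all(np.isfinite(log_norm)):
        # cannot occur for validated inputs; guards silent NaN propagation
        raise FloatingPointError("non-finite subset weights")
    return WeightedMixture(
        J=J, prior_p=prior_p, means=means, sds=sds,
        log_weights_norm=log_norm, masks=masks, psis=psis,
    )


def loglik(mixture: WeightedMixture, theta) -> np.ndarray | float:
    """Log-likelihood of the causal parameter under the weighted mixture.

    log sum_k w'_k N(theta; theta_IVW,k, se_re,k^2), evaluated by
    log-sum-exp; the 1/sqrt(2*pi) density constant is included (it cancels
    in every likelihood-ratio difference and in the argmax).  Accepts a
    scalar or an array of theta values.
    """
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    # one (n_components, n_theta) buffer, built in place: the grid search
    # evaluates ~2e6 component-point pairs per call at J = 10
    comp = np.subtract(theta_arr[None, :], mixture.means[:, None])
    comp /= mixture.sds[:, None]
    np.square(comp, out=comp)
    comp *= -0.5
    comp += (
        mixture.log_weights_norm - np.log(mixture.sds) - _HALF_LOG_2PI
    )[:, None]
    # streaming log-sum-exp over components, reusing the buffer
    m = comp.max(axis=0)
    comp -= m[None, :]
    np.exp(comp, out=comp)
    out = m + np.log(comp.sum(axis=0))
    return out if np.ndim(theta) else float(out[0])


def _intervals_from_mask(grid: np.ndarray, inside: np.ndarray) -> tuple:
    """Maximal runs of True grid points as (first, last) value pairs."""
    idx = np.flatnonzero(inside)
    if idx.size == 0:
        return ()
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return tuple((float(grid[a]), float(grid[b])) for a, b in zip(starts, ends))


def mode_and_ci(
    mixture: WeightedMixture,
    grid_lo: float = -1.0,
    grid_hi: float = 1.0,
    grid_step: float = 0.001,
    level: float = 0.95,
) -> CausalResult:
    """Grid-search modal estimate and likelihood-ratio confidence set.

    The likelihood is evaluated on the closed grid [grid_lo, grid_hi] with
    spacing grid_step; the estimate is the grid argmax (ties broken toward
    the smallest theta) and the confidence set collects the maximal runs of
    grid points satisfying 2*(logL_max - logL(theta)) <= chi2(1) quantile
    (3.841 at level 0.95).  Interval endpoints are the outermost qualifying
    grid points; no sub-grid refinement is applied.  A mode on the grid
    boundary triggers a warning: the grid is likely too narrow.
    """
    if not grid_lo < grid_hi:
        raise ValueError("grid_lo must be below grid_hi")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    n = int(round((grid_hi - grid_lo) / grid_step)) + 1
    grid = np.linspace(grid_lo, grid_hi, n)
    ll = loglik(mixture, grid)
    i_max = int(np.argmax(ll))  # argmax returns the first (smallest-theta) tie
    ll_max = float(ll[i_max])
    threshold = chi2.ppf(level, df=1)
    inside = 2.0 * (ll_max - ll) <= threshold
    intervals = _intervals_from_mask(grid, inside)
    if i_max in (0, n - 1):
        logger.warning(
            "mode at grid boundary (theta=%.4g); widen the grid", grid[i_max]
        )
    return CausalResult(
        estimate=float(grid[i_max]),
        confidence_set=intervals,
        level=level,
        grid=(grid_lo, grid_hi, grid_step),
        loglik_at_mode=ll_max,
        multimodal=len(intervals) > 1,
    )


def hpma_estimate(
    data: SummarizedData,
    grid_lo: float = -1.0,
    grid_hi: float = 1.0,
    grid_step: float = 0.001,
    level: float = 0.95,
    prior_p: float = 0.5,
    psi_scale: str = "sd",
    max_variants: int = MAX_VARIANTS,
) -> tuple[CausalResult, pd.DataFrame]:
    """End-to-end heterogeneity-penalized model-averaging analysis.

    Returns the causal result together with the per-subset weight table
    (mask, size, subset IVW estimate, over-dispersion, normalized weight),
    which supports reporting such as the weight carried by the all-variant
    subset.
    """
    mixture = build_mixture(
        data, prior_p=prior_p, psi_scale=psi_scale, max_variants=max_variants
    )
    logger.info(
        "model averaging over %d subset models (J=%d)", mixture.n_components, data.J
    )
    result = mode_and_ci(
        mixture, grid_lo=grid_lo, grid_hi=grid_hi, grid_step=grid_step, level=level
    )
    table = mixture.weight_table()
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug("top subsets by weight:\n%s", table.head(10).to_string())
    return result, table
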