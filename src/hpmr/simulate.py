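"""Two-sample Mendelian randomization simulation study.

Generates individual-level data under a linear structural model with an
unmeasured confounder U::

    U = sum_j zeta_j G_j + eps_U
    X = sum_j gamma_j G_j + U + eps_X
    Y = sum_j alpha_j G_j + theta X + U + eps_Y

with G_j ~ Binomial(2, maf) independent SNPs, standard-normal errors, and
per-dataset instrument strengths gamma_j ~ Uniform(0.03, 0.1).  Summary
associations are estimated by per-variant univariable linear regressions in
two non-overlapping cohorts (risk factor in cohort one, outcome in cohort
two), mimicking the standard two-sample design.

Four pleiotropy scenarios control the invalid variants' direct effects
alpha_j (on the outcome) and zeta_j (on the confounder):

1. none - all variants valid;
2. balanced pleiotropy - alpha ~ U(-0.1, 0.1), InSIDE holds;
3. directional pleiotropy - alpha ~ U(0, 0.1), InSIDE holds;
4. pleiotropy via the confounder - zeta ~ U(-0.1, 0.1), InSIDE violated.

The metrics harness applies any registered estimator to each simulated
dataset and aggregates mean, SD and mean SE of estimates plus empirical
power (% of 95% confidence intervals excluding zero; the Type 1 error rate
when theta = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import ESTIMATOR_REGISTRY
from .hpma import build_mixture, hpma_estimate, mode_and_ci
from .io import SummarizedData

__all__ = [
    "ScenarioConfig",
    "SimulationMetrics",
    "simulate_dataset",
    "instrument_strength",
    "run_study",
    "composite_ci_frequency",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of one simulation scenario.

    The defaults reproduce the base study conditions: J = 10 uncorrelated
    SNPs with minor allele frequency 0.3, two cohorts of 20 000 individuals
    and instrument effects gamma_j ~ U(0.03, 0.1) (about 1% of risk-factor
    variance explained, mean F around 20).  The first ``n_invalid``
    variants are the invalid ones; valid variants always have
    alpha_j = zeta_j = 0.
    """

    scenario: int = 1
    n_invalid: int = 0
    theta: float = 0.0
    J: int = 10
    n_per_sample: int = 20000
    maf: float = 0.3
    gamma_range: tuple = (0.03, 0.1)
    alpha_range: tuple | None = None  # derived from scenario when None
    zeta_range: tuple | None = None
    alpha_shared: float | None = None  # same pleiotropic effect for all invalid
    n_datasets: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3, 4):
            raise ValueError("scenario must be 1, 2, 3 or 4")
        if not 0 <= self.n_invalid <= self.J:
            raise ValueError("n_invalid must lie in [0, J]")
        if self.scenario == 1 and self.n_invalid:
            raise ValueError("scenario 1 has all variants valid")

    def _alpha_range(self) -> tuple | None:
        if self.alpha_range is not None:
            return self.alpha_range
        return {1: None, 2: (-0.1, 0.1), 3: (0.0, 0.1), 4: None}[self.scenario]

    def _zeta_range(self) -> tuple | None:
        if self.zeta_range is not None:
            return self.zeta_range
        return {1: None, 2: None, 3: None, 4: (-0.1, 0.1)}[self.scenario]

    def draw_effects(self, rng: np.random.Generator):
        """Per-dataset (gamma, alpha, zeta) draws, shared by both cohorts."""
        gamma = rng.uniform(*self.gamma_range, size=self.J)
        alpha = np.zeros(self.J)
        zeta = np.zeros(self.J)
        if self.n_invalid:
            sl = slice(0, self.n_invalid)
            if self.alpha_shared is not None:
                alpha[sl] = self.alpha_shared
            elif self._alpha_range() is not None:
                alpha[sl] = rng.uniform(*self._alpha_range(), size=self.n_invalid)
            if self._zeta_range() is not None:
                zeta[sl] = rng.uniform(*self._zeta_range(), size=self.n_invalid)
        return gamma, alpha, zeta


def _univariable_regressions(G: np.ndarray, y: np.ndarray):
    """Slope and SE of y ~ G_j, intercept included, vectorized over variants."""
    n = G.shape[0]
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sgg = np.einsum("ij,ij->j", Gc, Gc)
    sgy = Gc.T @ yc
    slope = sgy / sgg
    rss = yc @ yc - slope * sgy
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sgg)
    return slope, se


def _simulate_cohort(cfg: ScenarioConfig, gamma, alpha, zeta,
                     rng: np.random.Generator):
    n = cfg.n_per_sample
    G = rng.binomial(2, cfg.maf, size=(n, cfg.J)).astype(float)
    U = G @ zeta + rng.standard_normal(n)
    X = G @ gamma + U + rng.standard_normal(n)
    Y = G @ alpha + cfg.theta * X + U + rng.standard_normal(n)
    return G, X, Y


def simulate_dataset(cfg: ScenarioConfig, rng: np.random.Generator) -> SummarizedData:
    """One simulated two-sample summary dataset.

    Effect parameters are drawn once and shared by the two cohorts;
    variant-risk factor associations come from cohort one and
    variant-outcome associations from an independent cohort two.
    """
    gamma, alpha, zeta = cfg.draw_effects(rng)
    G1, X1, _ = _simulate_cohort(cfg, gamma, alpha, zeta, rng)
    bx, sx = _univariable_regressions(G1, X1)
    G2, _, Y2 = _simulate_cohort(cfg, gamma, alpha, zeta, rng)
    by, sy = _univariable_regressions(G2, Y2)
    return SummarizedData(
        variant_ids=tuple(f"g{j + 1}" for j in range(cfg.J)),
        beta_x=bx, beta_y=by, se_y=sy, se_x=sx,
    )


def _joint_fit(G: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """R^2 and F statistic of the joint regression of x on all variants."""
    n, J = G.shape
    Gc = G - G.mean(axis=0)
    xc = x - x.mean()
    coef = np.linalg.solve(Gc.T @ Gc, Gc.T @ xc)
    tss = float(xc @ xc)
    rss = tss - float(coef @ (Gc.T @ xc))
    r2 = 1.0 - rss / tss
    f = (r2 / J) / ((1.0 - r2) / (n - J - 1))
    return r2, f


def instrument_strength(
    cfg: ScenarioConfig, n_datasets: int | None = None, seed: int | None = None
) -> tuple[float, float]:
    """Mean R^2 and mean F of the instruments across simulated datasets.

    Per dataset, the risk factor in cohort one is regressed jointly on all
    J variants; the returned pair is (mean R^2, mean F) over datasets.
    """
    n_datasets = n_datasets or cfg.n_datasets
    seed = cfg.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(n_datasets)
    r2s = np.empty(n_datasets)
    fs = np.empty(n_datasets)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        gamma, alpha, zeta = cfg.draw_effects(rng)
        G, X, _ = _simulate_cohort(cfg, gamma, alpha, zeta, rng)
        r2s[i], fs[i] = _joint_fit(G, X)
    return float(r2s.mean()), float(fs.mean())


@dataclass
class SimulationMetrics:
    """Streaming aggregator of per-method estimates and CI decisions."""

    method: str
    n: int = 0
    sum_est: float = 0.0
    sum_est2: float = 0.0
    sum_se: float = 0.0
    n_se: int = 0
    n_reject: int = 0
    n_failed: int = 0

    def update(self, estimate: float, se: float | None, excludes_null: bool) -> None:
        self.n += 1
        self.sum_est += estimate
        self.sum_est2 += estimate * estimate
        if se is not None and np.isfinite(se):
            self.sum_se += se
            self.n_se += 1
        self.n_reject += bool(excludes_null)

    def summary(self) -> dict:
        mean = self.sum_est / self.n if self.n else np.nan
        var = (
            (self.sum_est2 - self.n * mean * mean) / (self.n - 1)
            if self.n > 1 else np.nan
        )
        return {
            "method": self.method,
            "n_datasets": self.n,
            "mean": mean,
            "sd": float(np.sqrt(max(var, 0.0))) if self.n > 1 else np.nan,
            "mean_se": self.sum_se / self.n_se if self.n_se else np.nan,
            "power": 100.0 * self.n_reject / self.n if self.n else np.nan,
            "n_failed": self.n_failed,
        }


# grid used for the model-averaging method inside simulations
_SIM_GRID = {"grid_lo": -1.0, "grid_hi": 1.0, "grid_step": 0.001}


def _apply_method(method: str, data: SummarizedData, seed: int):
    """(estimate, se or None, excludes_null) for one dataset and method."""
    if method == "hpma":
        # skip the per-subset weight table in the Monte Carlo hot loop
        result = mode_and_ci(build_mixture(data), **_SIM_GRID)
        return result.estimate, None, result.excludes(0.0)
    est = ESTIMATOR_REGISTRY[method](data, seed=seed)
    return est.estimate, est.se, est.excludes_null


def run_study(
    cfg: ScenarioConfig,
    methods: Sequence[str],
    n_datasets: int | None = None,
    seed: int | None = None,
    n_datasets_per_method: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Monte Carlo comparison of estimators under one scenario.

    Each simulated dataset is analysed by every requested method (method
    names from the estimator registry plus ``"hpma"``).  ``power`` is the
    percentage of 95% confidence intervals excluding zero - for the
    model-averaging method, zero must fall outside every interval of the
    composite set.  ``n_datasets_per_method`` lets expensive methods run on
    a prefix of the dataset stream without disturbing it for the others.
    Method failures on individual datasets are logged, counted in
    ``n_failed`` and excluded from the aggregates.
    """
    unknown = [m for m in methods if m != "hpma" and m not in ESTIMATOR_REGISTRY]
    if unknown:
        raise ValueError(
            f"unknown methods {unknown}; available: "
            f"{sorted(ESTIMATOR_REGISTRY)}"
        )
    n_datasets = n_datasets or cfg.n_datasets
    seed = cfg.seed if seed is None else seed
    per_method = {m: n_datasets for m in methods}
    if n_datasets_per_method:
        per_method.update({m: min(n, n_datasets) for m, n in n_datasets_per_method.items()})
    aggs = {m: SimulationMetrics(method=m) for m in methods}
    streams = np.random.SeedSequence(seed).spawn(n_datasets)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        data = simulate_dataset(cfg, rng)
        method_seed = int(ss.generate_state(1, np.uint32)[0])
        for m in methods:
            if i >= per_method[m]:
                continue
            try:
                est, se, rej = _apply_method(m, data, method_seed)
            except Exception:  # noqa: BLE001 - isolate per-dataset failures
                logger.exception("method %s failed on dataset %d", m, i)
                aggs[m].n_failed += 1
                continue
            aggs[m].update(est, se, rej)
    return pd.DataFrame([aggs[m].summary() for m in methods])


def composite_ci_frequency(
    cfg: ScenarioConfig, n_datasets: int | None = None, seed: int | None = None
) -> float:
    """Fraction of datasets whose confidence set has two or more intervals.

    Intended for equal-pleiotropy configurations (``alpha_shared`` set, so
    all invalid variants push toward one alternative effect), where the
    mixture likelihood can become bimodal and the likelihood-ratio
    confidence set splits into disjoint ranges.
    """
    n_datasets = n_datasets or cfg.n_datasets
    seed = cfg.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(n_datasets)
    n_composite = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        data = simulate_dataset(cfg, rng)
        result, _ = hpma_estimate(data, **_SIM_GRID)
        n_composite += result.multimodal
    return n_composite / n_datasets
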