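# Methods

## Problem setting

Mendelian randomization (MR) uses genetic variants as instrumental
variables to estimate the causal effect of a risk factor *X* on an outcome
*Y* from observational data. In the two-sample summary-data design, the
inputs are, for each of *J* uncorrelated variants, the estimated
per-allele association with the risk factor (β̂_Xj), the estimated
association with the outcome (β̂_Yj) and the standard error se(β̂_Yj),
taken from univariable regressions in two non-overlapping cohorts. A valid
instrument must be associated with the risk factor, independent of
confounders, and affect the outcome only through the risk factor; variants
violating the latter two conditions (pleiotropy) bias the standard
estimators.

The per-variant ratio (Wald) estimate is θ̂_j = β̂_Yj/β̂_Xj with
first-order delta-method standard error se(θ̂_j) = se(β̂_Yj)/|β̂_Xj|. The
absolute value in the denominator keeps the standard error positive for
variants reported on the risk-factor-decreasing allele; ratio estimates
and their standard errors are invariant to jointly flipping the sign of
(β̂_Xj, β̂_Yj), i.e. to allele re-orientation. Uncertainty in β̂_Xj is
ignored throughout, as is standard for this design.

## The heterogeneity-penalized model-averaging estimator

Every subset σ_k of at least two variants defines a candidate model
(2^J − J − 1 models; single-variant subsets are excluded because
heterogeneity cannot be assessed within them). Subset *k* contributes a
normal distribution centred at its inverse-variance weighted (IVW)
estimate

    θ̂_IVW,k = Σ_{j∈σ_k} θ̂_j se(θ̂_j)^{-2} / Σ_{j∈σ_k} se(θ̂_j)^{-2}

with multiplicative random-effects standard error
se(θ̂_IVWr,k) = ψ̂_k / √(Σ_{j∈σ_k} se(θ̂_j)^{-2}), where

    ψ̂_k = max(1, √(Q_k/(K−1))),
    Q_k  = Σ_{j∈σ_k} se(β̂_Yj)^{-2} (β̂_Yj − θ̂_IVW,k β̂_Xj)²,

*K* the subset size. ψ̂ is interpreted on the standard-deviation scale
(the square root of the mean heterogeneity statistic) because it plays the
role of a residual standard error multiplying the fixed-effect SE; the
floor at 1 forbids under-dispersion, so a random-effects interval is never
narrower than the fixed-effect one. A `psi_scale="var"` switch implements
the alternative variance-scale reading for sensitivity analysis.

The unnormalized subset weight is

    w_k = Π_{j∈σ_k} se(θ̂_j)^{-1} exp[−(θ̂_j − θ̂_IVW,k)²/(2 se(θ̂_j)²)],

which grows with subset size through the se^{-1} factors but collapses
exponentially when a subset is more heterogeneous than sampling error
allows. An optional validity prior multiplies w_k by
p^K (1−p)^{J−K}, where `prior_p = p` is the prior probability that any one
variant is a valid instrument; the default p = 0.5 multiplies every subset
by the same constant and reproduces the equal-prior analysis exactly.
Weights are normalized to sum to one.

The causal estimate is the mode of the resulting weighted normal mixture
likelihood

    L(θ) = Σ_k w'_k se(θ̂_IVWr,k)^{-1} exp[−(θ − θ̂_IVW,k)²/(2 se(θ̂_IVWr,k)²)].

It is consistent when a *weighted plurality* of variants are valid: as
standard errors shrink, the mixture degenerates to spikes at the subset
IVW estimates, and the tallest spike sits at the estimate shared by the
subset with the largest product of inverse standard errors.

### Numerical choices

- **Log-space weights.** The product defining w_k spans hundreds of orders
  of magnitude for J ≈ 10–17 (each factor carries a dimensional se^{-1}
  term), so all weight arithmetic is done on log w_k with log-sum-exp
  normalization; the mixture log-likelihood is also evaluated by
  log-sum-exp and stays finite at any finite θ. The subset sums are
  computed as three moment matmuls against the (2^J−J−1, J) subset mask
  matrix, which makes a J = 10 analysis take milliseconds.
- **Density constant.** The 1/√(2π) factor is included in the
  log-likelihood; it cancels in the argmax and in every likelihood-ratio
  difference.
- **Grid search.** The likelihood is evaluated on a closed grid, default
  (−1, 1, 0.001), so estimates and interval endpoints resolve to 0.001 on
  that default. The grid is never widened automatically: a mode on the
  boundary logs a warning so behaviour stays predictable; bounds and step
  are exposed as options. Ties at the argmax break toward the smallest θ.
- **Confidence set.** A generalized likelihood-ratio inversion: the level-
  (1−α) set collects all grid points with 2(log L_max − log L(θ)) ≤
  χ²_{1,1−α} (3.841 at 95%). It is reported as the maximal runs of
  qualifying grid points, so it may be a union of disjoint intervals when
  the likelihood is multimodal — a real feature indicating variant groups
  supporting distinct causal effects, not an artifact. Endpoints are the
  outermost qualifying grid points; no sub-grid refinement is applied.
- **No standard error.** The method reports no SE. For a single-interval
  set, `CausalResult.normal_approx_se` exposes half the interval width
  divided by 1.96 as a diagnostic only.
- **Subset cap.** Enumeration is refused above J = 20 (the model count
  doubles per variant); scalable subset search is out of scope. No subset
  pruning is applied by default, preserving exactness of the weights.

## Comparator estimators

- **IVW** (fixed / multiplicative random effects): precision-weighted mean
  of ratio estimates; random-effects SE multiplies the fixed SE by the
  weighted zero-intercept regression's residual standard error, floored at 1.
- **MR-Egger**: weighted regression of β̂_Y on β̂_X *with* intercept
  (weights se(β̂_Y)^{-2}), random-effects ψ floored at 1; the slope is the
  causal estimate, the intercept measures directional pleiotropy.
  Consistent under the InSIDE assumption (instrument strength independent
  of direct effects). Deliberately not re-orienting variants; orientation
  is the caller's responsibility and the non-invariance is documented.
- **Simple / weighted median**: the median, or the interpolated
  inverse-variance-weighted 50th percentile, of the ratio estimates;
  consistent when (weighted) ≥50% of instruments are valid. SEs by
  parametric bootstrap (θ̂_j resampled from N(θ̂_j, se(θ̂_j)), default
  1000 replicates, seeded). The bootstrap scheme and replicate count are
  this package's documented choice.
- **Mode-based estimate (MBE)**: mode of a normal-kernel density over the
  ratio estimates, equal or inverse-variance kernel weights, bandwidth
  ϕ × 0.9·min(SD, 1.4826·MAD)·J^{−1/5} (modified Silverman rule; the 0.9
  constant is an exposed argument). No "no measurement error" (NOME)
  assumption: se(θ̂_j) is always the delta-method value. SE is the
  normal-scaled MAD of parametric-bootstrap modes. Degenerate case: if all
  ratio estimates coincide the bandwidth is zero and that common value is
  returned, with the SE still bootstrapped.

95% intervals for all comparators are estimate ± 1.96·se, which is also
how empirical power is scored for them in the simulation harness.

## Simulation study

Individual-level data are generated under a linear structural model with
an unmeasured confounder *U* entering both *X* and *Y* with unit
coefficient:

    U = Σ ζ_j G_j + ε_U,   X = Σ γ_j G_j + U + ε_X,
    Y = Σ α_j G_j + θX + U + ε_Y,

G_j ~ Binomial(2, 0.3) (independent SNPs, MAF 30%), ε ~ N(0,1)
independently, γ_j ~ U(0.03, 0.1) redrawn per dataset. Defaults: J = 10
variants, two independent cohorts of 20 000 individuals (risk-factor
associations from cohort one, outcome associations from cohort two),
causal effect θ ∈ {0, 0.2}. Under these conditions the instruments
jointly explain ≈1.0% of risk-factor variance, mean F ≈ 20 — genuinely
weak-ish instruments, as intended. Four scenarios govern the invalid
variants (always the first `n_invalid`; valid variants have α = ζ = 0):
(1) none; (2) balanced pleiotropy α ~ U(−0.1, 0.1); (3) directional
pleiotropy α ~ U(0, 0.1); (4) pleiotropy via the confounder
ζ ~ U(−0.1, 0.1), which violates InSIDE. Effect draws are shared by the
two cohorts within a dataset (the same genetic architecture measured
twice); regressions are intercept-only univariable fits, computed by
closed-form simple-regression algebra vectorized across variants and
verified against `numpy.linalg.lstsq`.

Seeding: a master `SeedSequence` spawns one substream per dataset, so an
expensive method can be run on a prefix of the dataset stream without
perturbing the draws seen by other methods.

Metrics per method: mean and SD of estimates, mean SE (where the method
reports one) and empirical power, the percentage of 95% confidence
intervals excluding zero (the Type 1 error rate when θ = 0). For the
model-averaging method, zero must fall outside *every* interval of the
composite set.

`composite_ci_frequency` measures how often the confidence set splits into
multiple intervals under an equal-pleiotropy configuration
(`alpha_shared`); the shared pleiotropic-effect magnitude is a free
parameter and no particular frequency is asserted for it.

### What the generator does and does not emulate

The generator produces uncorrelated biallelic SNPs with homogeneous linear
effects, Gaussian noise and an additive confounder. It does not emulate
linkage disequilibrium, allele-frequency spectra, non-linearity, effect
heterogeneity across individuals, binary outcomes/logistic summary
statistics, sample overlap between the cohorts, or winner's-curse variant
selection. Passing tests therefore demonstrate correctness of the
estimators and their operating characteristics *under the stated model*,
not robustness to those real-data complications.

### Problem sizes used in the test suite and acceptance script

Monte Carlo checks run at 1000 replicates for the model-averaging method's
operating characteristics (4000 for IVW-only quantities, 500 per
configuration for the six minority-invalid robustness checks), with
tolerances computed from the binomial/normal Monte Carlo error at those
counts. These sizes give standard errors a few times smaller than the
effects being checked while keeping a full run in minutes on one core.

## Known limitations

- Exhaustive subset enumeration caps the method at J ≤ 20 in this
  implementation (and is practically slow well before that); stochastic
  subset exploration is future work.
- The grid bounds the reportable estimate; effects outside (−1, 1) on the
  chosen scale require re-gridding (a boundary warning flags this).
- Weighted-plurality consistency is an asymptotic guarantee; with weak
  instruments and finite samples the estimate shows the usual two-sample
  attenuation toward the null.
- MR-Egger results depend on variant orientation, which the package does
  not normalize.
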