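# hpmr — heterogeneity-penalized model averaging for Mendelian randomization

`hpmr` estimates the causal effect of a risk factor on an outcome from
two-sample summary genetic-association data when some of the candidate
genetic instruments may be invalid (pleiotropic). Its core is a
model-averaging estimator that is consistent whenever a **weighted
plurality** of the variants are valid instruments — a weaker requirement
than the majority-validity condition of median-based methods.

It is aimed at epidemiologists and statistical geneticists running
summary-data MR analyses: the input is a table with one row per
uncorrelated variant — β̂_Xj (association with the risk factor), β̂_Yj
(association with the outcome) and se(β̂_Yj).

## The method

Every subset σ_k of ≥ 2 variants yields an IVW estimate
θ̂_IVW,k = Σ_{j∈σ_k} θ̂_j se(θ̂_j)⁻² / Σ_{j∈σ_k} se(θ̂_j)⁻², where
θ̂_j = β̂_Yj/β̂_Xj are the per-variant ratio estimates, and a
random-effects standard error se(θ̂_IVWr,k) = ψ̂_k (Σ se(θ̂_j)⁻²)^(−1/2)
with over-dispersion ψ̂_k floored at 1. Each subset is weighted by

  w_k = Π_{j∈σ_k} se(θ̂_j)⁻¹ · exp[ −(θ̂_j − θ̂_IVW,k)² / (2 se(θ̂_j)²) ],

so larger subsets gain weight while heterogeneous ones are penalized
exponentially. The causal estimate is the mode of the normalized weighted
mixture of normal densities N(θ̂_IVW,k, se(θ̂_IVWr,k)²), found by grid
search (default grid −1 to 1, step 0.001). The 95% confidence set is the
likelihood-ratio inversion: all grid points whose twice-log-likelihood is
within 3.841 (the 95th percentile of χ²₁) of the maximum. It needs no
bootstrap, can be asymmetric, and can consist of several disjoint
intervals — which flags groups of variants supporting distinct causal
mechanisms. An optional prior p^K(1−p)^{J−K} up-weights subsets according
to a prior probability p that each variant is valid (p = 0.5 ≡ equal
prior weights).

The package also implements the standard comparators (fixed/random-effects
IVW, MR-Egger, simple/weighted median, simple/weighted mode-based
estimate) and a Monte Carlo harness that simulates two-sample datasets
from an individual-level structural model with configurable pleiotropy
scenarios.

## Worked example

Create a synthetic 10-variant dataset with a true effect of 0.2 in which
three variants carry a pleiotropic outcome offset of 0.25, then analyse it:

```sh
hpmr fixtures --j 10 --theta 0.2 --n-invalid 3 --offset 0.25 --seed 11 --out example.tsv
hpmr estimate --method hpma --input example.tsv --weights-out weights.tsv
hpmr estimate --method ivw  --input example.tsv
```

The model-averaging result:

```json
{
  "method": "hpma",
  "estimate": 0.222,
  "confidence_set": [[0.122, 0.323]],
  "level": 0.95,
  "multimodal": false
}
```

and the top of `weights.tsv`:

```
subset      K  theta_ivw  psi  se_re   weight
0001111111  7  0.2226     1.0  0.0479  0.3132
0001110111  6  0.2147     1.0  0.0491  0.0902
0000111111  6  0.2250     1.0  0.0489  0.0762
```

The heaviest subset (31% of all weight) is exactly the seven valid
variants (the mask excludes snp1–snp3, the pleiotropic ones), and the
estimate 0.222 with CI [0.122, 0.323] covers the true 0.2. Standard IVW on
the same data returns 0.419 (CI 0.193–0.645) — pulled far from the truth
by the three invalid variants, with over-dispersion ψ̂ = 2.83 signalling
the heterogeneity the model-averaging weights exploited.

The same analysis is available programmatically:

```python
from hpmr import read_summarized, hpma_estimate
data = read_summarized("example.tsv")
result, weights = hpma_estimate(data)
print(result.estimate, result.confidence_set)
```

A Monte Carlo comparison under a chosen pleiotropy scenario:

```sh
hpmr simulate --scenario 3 --n-invalid 5 --theta 0 --n-datasets 1000 \
              --methods ivw,hpma --seed 1 --out metrics.tsv
```

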