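# Methods

## Overview

`tphpmf` imputes non-biological zeros in sample × taxon microbiome count
matrices. The procedure has three stages: (1) identify which zeros are
technical rather than biological; (2) organize taxa into a nested
phylogenetic hierarchy; (3) impute the flagged entries with a
hierarchical Bayesian probabilistic matrix factorization whose priors
follow that hierarchy. This note records the model assumptions, the
defaults and why they were chosen, the numerical choices, and what the
synthetic benchmarks do and do not establish.

## Pre-processing

Counts are scaled so each sample totals `library_size` (default 10⁶,
the conventional "counts per million × 1" scale for metagenomic relative
abundance) and transformed entrywise as `log10(x + offset)` with
`offset = 1.01`. An offset strictly greater than 1 guarantees every
transformed value is strictly positive, so the zero placeholder
`log10(1.01) ≈ 0.0043` is distinguishable from any genuine abundance and
back-transformation can never produce negative counts. Samples with zero
total count are rejected rather than dropped: an empty library is a data
error the user must see.

## Zero identification

A taxon essentially absent everywhere carries no information to impute
from. The prevalence screen keeps a taxon only when the one-sided Wilson
95% lower confidence bound on the proportion of samples with non-zero
abundance is strictly positive. Wilson (not Wald) because the Wald lower
bound degenerates at small counts; with the Wilson bound the screen
reduces to "present in at least one sample", which is exactly the
intended role of dropping all-zero columns while remaining a principled,
threshold-adjustable test (`abundance_threshold` configurable).

Each kept taxon's column is fitted with the two-component mixture
`p·Γ(α, β) + (1 − p)·N(x'γ, σ²)` by EM:

- **Initialization**: split at the 25th percentile; the low part seeds
  the gamma (method of moments), the high part the normal regression.
  The gamma component is meant to absorb the near-zero dropout mass, so
  seeding it from the low tail is the natural starting point.
- **M-step**: mixing weight = mean responsibility; regression
  coefficients and σ by responsibility-weighted least squares; gamma
  shape by safeguarded Newton on the weighted profile equation
  `log α − ψ(α) = log ȳ_w − (log y)̄_w`, rate `β = α/ȳ_w`. Solving the
  shape equation to convergence makes the M-step an exact maximizer,
  which is what keeps the observed-data log-likelihood monotone (a
  single Newton step measurably does not).
- **Boundary fallback**: the normal-only model is the `p → 0` boundary
  of the mixture family. When EM converges to an interior local mode
  whose likelihood falls below the null regression's (a real phenomenon
  on columns with no dropout signal), the boundary solution is the MLE
  and the fit is reported as the null with `p = 0`. This also keeps the
  likelihood-ratio statistic non-negative by construction.
- **Convergence**: tolerance 1e-6 on the log-likelihood, max 100
  iterations; non-convergence is a warning, not an error. Near-constant
  columns are rejected as degenerate.

Taxa pass to flagging when the likelihood-ratio statistic
`2(ℓ_mix − ℓ_null)` exceeds the χ² threshold with **df = 3** (the
mixture adds p, α, β). The null sits on the boundary of the parameter
space, so the χ²₃ reference is approximate and conservative; empirically
the screen rejects well under 10% of pure-normal columns at α = 0.05
(asserted in the test suite as an upper bound). Zero-valued entries of
passing taxa are flagged when the posterior gamma membership

    e_ij = p f_Γ(y_ij) / [p f_Γ(y_ij) + (1 − p) f_N(y_ij)]

computed in log space, is at least 0.5. Only entries equal to the zero
placeholder are ever eligible: observed non-zero abundances are data,
never imputation targets, and zeros of taxa failing either screen are
left untouched as biological zeros.

## Phylogenetic hierarchy

Patristic distances (from a newick tree, or supplied directly as a
matrix) are clustered by complete linkage and the dendrogram is cut at
three strictly increasing heights, producing nested partitions "S", "G",
"F" (finest to coarsest). Complete linkage guarantees every cluster at
cut height h has diameter ≤ h, so the levels behave like taxonomic ranks
with controlled within-group divergence. Default cut heights are the
(0.25, 0.5, 0.75) quantiles of the off-diagonal distance distribution —
a scale-free default that adapts to the dataset's distance spread; both
quantiles and explicit heights are configurable (they are genuine
hyperparameters, tunable by cross-validation). Cluster ids are
renumbered by smallest member index so runs are deterministic.

Aggregated matrices at the coarser levels sum the member taxa's
normalized counts before the log transform (abundance is additive at
higher ranks — summing counts is what collapsing a taxonomy level does),
and an aggregated entry is missing only when *every* member entry is
missing. Averaging log-abundances was the rejected alternative: it has
no counting interpretation and makes the aggregate sensitive to the
number of members rather than their total abundance.

## The factorization engine

The engine runs over H = 4 layers ordered coarsest → finest: F, G, S,
then the individual taxa (the matrix actually imputed). Every layer h
carries data `Y^h` with observation mask δ; at the finest layer δ = 0
exactly on flagged entries, at coarser layers δ = 0 under the
all-members-missing rule.

Model per layer: `y_nm ~ N(⟨s_n^h, t_m^h⟩, σ²)` on observed entries;
priors `t_m^h ~ N(t_{p(m)}^{h−1}, σ_t² I)` (parent cluster's latent
vector; the root conditions on `T⁰ = 0`) and the sample chain
`s_n^h ~ N(s_n^{h−1}, σ_s² I)` with `S⁰ = 0`. The corresponding MAP
objective per layer is the regularized squared loss `E^h` with ridge
weights `λ_t = σ²/σ_t²`, `λ_s = σ²/σ_s²` (see the engine module
docstring for the exact expression).

**Full conditionals.** Each latent vector's Gibbs update is the exact
Gaussian implied by the posterior:

    t_m^h | · ~ N(Λ⁻¹ b, Λ⁻¹)
    Λ = (1/σ²) Σ_n δ_nm s_n s_n' + (1/σ_t²)(1 + |c(m)|·1[h<H]) I
    b = (1/σ²) Σ_n δ_nm y_nm s_n + (1/σ_t²)(t_{p(m)}^{h−1} + Σ_{m'∈c(m)} t_{m'}^{h+1})

and symmetrically for `s_n^h` with a single chain-child. These were
derived by hand and are verified two independent ways in the test suite:
the conditional mean is checked to be a stationary point of the
finite-difference gradient of `E^h` (tolerance 1e-5), and on a 3×3,
rank-1 instance the chain's posterior mean of a missing entry matches
dense numerical integration (latents marginalized analytically on the
sample side, gridded on the taxon side) within 3 Monte-Carlo standard
errors.

**Sweep order.** One Gibbs sweep visits layers coarsest → finest and
then finest → coarsest, updating all taxon vectors then all sample
vectors per layer, in ascending index order, in place (each draw
conditions on the newest values). The within-layer order is a free
choice; ascending index keeps runs reproducible.

**Sampler defaults**: latent dimension D = 10, σ² = σ_s² = σ_t² = 1
(λ_s = λ_t = 1), 200 sweeps, burn-in 50, thinning 2 — all tunable, and
the tuning module exists precisely because the right values are
dataset-dependent. Flagged entries are imputed by the posterior mean of
`⟨s_n, t_m⟩` at the taxon layer over retained draws (posterior sd is
reported alongside), clamped below at `log10(offset)`. Only the finest
layer is used for imputation; the coarser layers act purely as priors.

**Numerical hygiene**: precision-matrix Cholesky solves with a 1e-10
jitter retry; draws use the upper-triangular back-solve so mean and
noise share one factorization. Whether σ², σ_s², σ_t² should be
resampled within the chain was an open design question; they are fixed
hyperparameters here (tunable by CV), since nothing in the objective
requires resampling and fixing them keeps the sampler simple and
deterministic.

## Hyperparameter tuning

Observed entries (not samples) are partitioned uniformly at random into
`n_folds` folds (default 10, optionally repeated); each fold is hidden
in turn, the engine imputes it, and the configuration is scored by RMSE
on the hidden entries. Entry-wise masking matches the estimand — entry
reconstruction. Hidden entries are treated as missing in the aggregated
layers too (their counts are excluded from cluster sums), so no
information leaks through the hierarchy. Grid search only: the grids
are small and determinism matters more than search efficiency. Ties are
broken toward smaller latent dimension, then fewer sweeps.

## Synthetic benchmarks

Three generators produce zero-free "complete" matrices on the log scale:

1. **pmf** — `Y = 3.0 + S T'/√D + ε`, D = 3, noise sd 0.3. Location 3.0
   puts typical abundances near 10³ per million, the middle of the range
   a normalized gut-metagenome log-abundance actually occupies; rank 3
   with noise sd 0.3 gives signal-to-noise comparable to a strongly
   structured community.
2. **linear** — each entry is regenerated from a positive seed matrix as
   a sparse (5-neighbour, Dirichlet-weighted) combination of other taxa
   in its sample and other samples of its taxon, with the self-weights
   structurally zero.
3. **semi** — zeros of a partially observed template are replaced by
   per-taxon normal draws fitted to the observed non-zero values
   (global fallback for taxa with fewer than two).

Zero inflation drops each entry with probability `logistic(a − b·y)`,
slope b = 1 by default so low-abundance entries drop more often (b = 0
recovers abundance-independent binomial dropout); the intercept is
calibrated by bisection to hit the target zero fraction (default 0.7,
the middle of the 60–80% range typical of real data) within 0.01. The
exact functional form of real dropout is unknown; the logistic choice is
a stand-in isolated behind `inflate_zeros`.

Because fully synthetic data has no phylogeny, benchmark runs build the
hierarchy from the correlation-profile distance `√(2(1 − r))` computed
on the *observed* zero-inflated matrix. This emulates the empirical fact
the hierarchy exploits — phylogenetically close taxa have correlated
abundance profiles — without touching the ground truth.

Robustness utilities: multinomial resampling to fixed sequencing depths
(1000–10000 reads/sample) and injection of pathological samples in which
the lowest-abundance quartile of taxa takes the matrix maximum and all
other taxa are zeroed.

Metrics: MSE restricted to dropped entries; mean per-taxon Pearson
correlation between imputed and complete columns (constant columns
excluded with a warning); Wasserstein-1 distance between the per-taxon
mean/sd-ratio distributions (the raw (mean, sd) pairs are exported so
the pair reading can be plotted as well).

**What a green benchmark establishes — and does not.** The generators
reproduce low-rank structure, neighbour-regression structure,
abundance-dependent dropout and realistic zero fractions. They do not
reproduce compositionality constraints, taxon-specific overdispersion,
batch effects, or a real phylogeny's deep/shallow branch imbalance. A
passing benchmark shows the machinery recovers the structure it models;
it is not evidence about any particular real dataset.

## Known limitations

- The χ²₃ LRT reference is approximate (boundary non-regularity);
  the screen is conservative rather than exact.
- Imputation uses the finest layer only; averaging predictions across
  layers is possible but unimplemented.
- No per-entry sequencing-depth offsets inside the mixture, and no
  zero-inflated negative-binomial alternative.
- Observation-noise and prior variances are fixed per run (CV-tunable),
  not resampled within the Gibbs chain.
- Rarefaction-based normalization and CLR/ILR transforms are out of
  scope; BIOM input is unsupported (TSV/CSV only).
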