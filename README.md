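# tphpmf

Phylogeny-aware hierarchical Bayesian probabilistic matrix factorization
for imputing non-biological zeros in microbiome taxon count matrices.

## The problem

Taxon count matrices from 16S or shotgun metagenomic sequencing are
extremely sparse — often 60–80% zeros. Some zeros are biological (the
taxon is genuinely absent); many are technical, caused by limited
sequencing depth, DNA extraction inefficiency or PCR bias. Treating
technical zeros as real absences distorts downstream analyses such as
differential-abundance testing. `tphpmf` (i) decides which zeros are
non-biological, and (ii) imputes them, borrowing strength across samples,
across taxa, and — the distinctive part — across the phylogeny.

## The model

Counts are normalized to a common library size (10⁶) and transformed to
`Y_ij = log10(O^N_ij + 1.01)`, so a zero count maps to `log10(1.01) > 0`.

**Zero identification.** Each taxon column is modelled as the mixture

    Y_ij ~ p_j · Γ(α_j, β_j) + (1 − p_j) · N(X_i'γ_j, σ_j²)

where the gamma component captures the dropout mass near zero and the
normal regression the true signal (with optional sample covariates X).
Parameters are fitted by EM; taxa passing a likelihood-ratio screen
(χ²₃, p ≤ 0.05) have each zero entry scored by its posterior gamma
membership `e_ij`; entries with `e_ij ≥ 0.5` are flagged for imputation.
A one-sided Wilson binomial filter first removes taxa absent essentially
everywhere.

**Hierarchy.** Taxa are clustered by complete linkage on phylogenetic
(patristic) distances and the dendrogram is cut at three increasing
heights, giving nested partitions "S" ⊂ "G" ⊂ "F" (species/genus/family
-like). The engine runs over four layers: the taxon matrix itself plus
the three aggregated cluster matrices.

**Imputation.** At every layer h the observed entries follow a low-rank
model `y^h_nm ~ N(⟨s_n^h, t_m^h⟩, σ²)`. The taxon latent vector's prior
mean is its parent cluster's latent vector at the coarser layer
(`t_m^h ~ N(t_{p(m)}^{h−1}, σ_t² I)`, root prior mean 0); sample latent
vectors form the analogous chain across layers. MAP inference minimizes,
per layer, the regularized loss

    E^h = Σ δ_nm (y_nm − ⟨s_n, t_m⟩)² + λ_t Σ_m [‖t_m − t_{p(m)}‖² + Σ_{m'∈c(m)} ‖t_m − t_{m'}‖²]
        + λ_s Σ_n [‖s_n − s_n^{h−1}‖² + ‖s_n − s_n^{h+1}‖²]

with `λ_t = σ²/σ_t²`, `λ_s = σ²/σ_s²`. A Gibbs sampler sweeps the layers
top-down then bottom-up, drawing each latent vector from its exact
Gaussian full conditional; flagged entries are filled with the posterior
mean of `⟨s_n, t_m⟩` at the taxon layer over the retained draws.

## Worked example

```python
import numpy as np
from tphpmf.engine import EngineConfig
from tphpmf.simulate import SimulationSpec, simulate_complete, benchmark_imputation

spec = SimulationSpec(design="pmf", n_samples=50, n_taxa=100, seed=1)
complete = simulate_complete(spec)                  # zero-free ground truth
res = benchmark_imputation(
    complete, target_zero_fraction=0.7, seed=1,
    engine_config=EngineConfig(n_samples=100, burn_in=40, thin=2, seed=1),
)
r, b = res["report"], res["baseline"]
print(f"zero fraction {r.zero_fraction_achieved:.3f}")
print(f"MSE  imputed {r.mse:.3f}   zero-fill {b.mse:.3f}")
print(f"Pearson imputed {r.mean_pearson:.3f}   zero-fill {b.mean_pearson:.3f}")
```

Output:

```
zero fraction 0.701
MSE  imputed 0.503   zero-fill 27.831
Pearson imputed 0.729   zero-fill 0.394
```

The dropout model removed 70% of entries; imputing them with the
hierarchical factorization reduces the mean squared error on those
entries from 27.8 (leaving the zeros in place) to 0.50, and raises the
mean per-taxon correlation with the ground truth from 0.39 to 0.73.

On real data, run the pipeline from the shell:

```bash
tphpmf impute --counts otu_table.tsv --tree taxa.nwk --out results/ --seed 7
```

which writes the imputed matrix, the flag mask, per-taxon mixture fits,
the hierarchy assignment, objective traces and a reproducibility
manifest. `tphpmf simulate`, `tphpmf benchmark` and `tphpmf tune` expose
the synthetic-data generators, the evaluation metrics and cross-validated
hyperparameter search.

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline — simulation of the
three synthetic designs at ~70% zeros, zero flagging, hierarchy
construction, Gibbs-sampled imputation and scoring — from scratch:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/tphpmf/preprocessing.py` — normalization, log transform, masks
- `src/tphpmf/zero_identification.py` — binomial filter, gamma-normal EM, LRT, flagging
- `src/tphpmf/hierarchy.py` — patristic distances, complete-linkage S/G/F hierarchy, aggregation
- `src/tphpmf/engine.py` — hierarchical Gibbs sampler and imputation
- `src/tphpmf/tuning.py` — entry-wise cross-validated grid search
- `src/tphpmf/simulate.py` — synthetic designs, zero inflation, robustness perturbations, metrics
- `src/tphpmf/io.py`, `pipeline.py`, `cli.py` — file formats, orchestration, CLI

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
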