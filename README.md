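# purkinet

Analysis pipeline for developmental time-course RNA-seq of a purified
neuronal population, built around a question from neurogenetics: do the
autism-risk genes expressed in a developing cell type form temporal
co-expression clusters, and does the composition of those clusters differ
between brain regions with respect to intellectual-disability (ID)
co-morbidity?

The package implements the full chain from a count matrix to that answer:

- **Normalization & QC** — median-of-ratios size factors, RPKM, a monotone
  log2 variance stabilizer, PCA with a time-point separation verdict, and
  marker-panel verification of capture purity.
- **Time-course differential expression** — a negative-binomial GLM
  likelihood-ratio test of a time-factor model against an intercept-only
  model (chi-square with T−1 df, BH q-values), with significant genes split
  into positively and negatively time-correlated clusters.
- **Signed weighted co-expression networks** — soft-thresholded signed
  adjacency ((1+r)/2)^β, topological overlap, average-linkage module
  detection (minimum size 30), module eigengenes, eigengene merging at
  dendrogram height 0.5, and module membership (kME, core members at
  kME > 0.8).
- **Gene-set over-representation** — Fisher's exact upper tail with a
  goseq-style gene-length bias correction: an isotonic probability
  weighting function reduced to the odds parameter of a Wallenius
  noncentral hypergeometric law.
- **The ratio-of-odds-ratios (ROR) permutation test** — the headline
  statistic. Two disease-gene strata (ID-co-morbid vs ID-free) are crossed
  with two tissue clusters, giving four 2×2 tables. Per tissue,
  ROR = OR(ID)/OR(ID-free); the statistic is Δ = |log₁₀ ROR_A − log₁₀
  ROR_B|. Significance comes from redrawing each table from its
  margin-fixed conditional law (Patefield-style sequential hypergeometric
  sampling), applying Haldane's +0.5 correction to any drawn table with a
  zero, and the add-one empirical p-value (#{Δ* ≥ Δ}+1)/(B+1), BH-adjusted
  across strata.
- **A synthetic-data generator** — negative-binomial counts over 5 time
  points × 3 replicates with planted monotone temporal modules, module-level
  latent factors, log-normal gene lengths and depth factors, and disease
  lists with a planted cross-tissue ID-composition bias; every analysis
  stage is validated against this answer key.

The fit/transform-shaped stages are exposed as scikit-learn-style
estimators (`CoexpressionModules`, `TimeCourseDE`, `SizeFactorNormalizer`)
that compose with sklearn tooling; module-level functions wrap them.

## Worked example

Run the whole pipeline on a synthetic study (writes counts, design,
annotation, gene lists, and all stage outputs under `demo/`):

```sh
purkinet run --config run.yaml
```

with `run.yaml`:

```yaml
seed: 5
out_dir: demo
n_genes: 1000
power: 3
permutations: 100000
```

The network stage detects three modules (`M1`: 56 genes, `M2`: 54, `M3`:
43) recovering the three planted 50-gene modules, and `demo/ror.json`
contains, for the syndromic stratum:

```json
{
 "stratum": "syndromic_only",
 "delta": 2.0952,
 "pvalue": 8.9999e-05,
 "odds_ratios": {"A/ID": 0.2653, "A/ID_free": 6.6226,
                 "B/ID": 8.8095, "B/ID_free": 1.7660},
 "ror": {"A": 0.0401, "B": 4.9883}
}
```

Read: in the development-correlated cluster (tissue A analogue) the
ID-free genes are enriched and the ID-associated genes depleted
(ROR ≈ 0.04), while the pattern inverts in the time-flat cluster
(ROR ≈ 4.99); the absolute log₁₀ difference Δ ≈ 2.10 is exceeded by only
8 of 100 000 margin-fixed permutations (p ≈ 9×10⁻⁵) — the planted
composition bias (odds 8 vs 0.1) is recovered.

Individual stages are also callable (`purkinet simulate`, `purkinet de`,
`purkinet network`, `purkinet ror`) or usable as a library:

```python
from purkinet import ror
t = ror.haldane_correct(ror.ContingencyTable([[8, 22], [0, 11]]))
ror.odds_ratio(t)        # 8.6889
```

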