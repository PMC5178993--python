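# metapheno

Construction of *metaphenotypes* — synthetic phenotypic variables derived
from a panel of correlated quantitative traits — and family-based genetic
analysis of them with a variance-components mixed model.

The package implements a two-stage methodology:

1. **Metaphenotype construction.** Traits are quality-controlled, freed of
   missing values by Bayesian-PCA imputation, standardized, and decomposed
   with fastICA (negentropy fixed point with symmetric decorrelation); PCA
   is available as the reference method. The number of components can be
   chosen by element-wise (Wold-style) cross-validation. Sign and order
   indeterminacy are resolved canonically so component labels C1..Ck are
   reproducible.
2. **Genetic analysis in extended pedigrees.** The kinship matrix is
   computed recursively from the pedigree (with a Monte-Carlo gene-dropping
   oracle for verification). Each metaphenotype's heritability is estimated
   by maximum likelihood under `y ~ N(Xb, s2_g * 2Phi + s2_e * I)` with a
   boundary-corrected likelihood-ratio test, and every (SNP, metaphenotype)
   pair is tested by a fixed-effect LRT with global Bonferroni correction.

Supporting modules provide text-PLINK/TSV I/O, genotype QC (call rate, IBS
duplicates, heterozygosity outliers, MAF), ICA-vs-PCA component matching,
composite LD r², GraphML trait-graph export, and a synthetic-data generator
producing extended families, Mendelian genotypes, and trait matrices mixed
from polygenic / SNP-driven / non-Gaussian latent sources.

## Usage

Full pipeline from a YAML config:

```sh
metapheno run --config config.yaml
```

```yaml
# config.yaml
paths:
  ped: data/genotypes.ped
  map: data/genotypes.map
  phenotypes: data/phenotypes.tsv
  output_dir: results/
traits: [T01, T02, T03, T04, T05, T06, T07, T08]
covariates: [age, sex]
decompose: {methods: [ica, pca], k: auto}   # k: auto uses cross-validation
alpha: 0.05
seed: 1
```

Outputs: QC report, imputed phenotypes, kinship matrix, loadings/scores per
method, heritability tables, association TSVs, ICA-vs-PCA comparison table,
GraphML graphs, and a `manifest.json` with a content hash per artifact
(two runs with the same config and seed produce identical hashes).

Stage-wise subcommands: `simulate`, `qc`, `impute`, `decompose`,
`heritability`, `gwas`, `compare`, `graph` (see `metapheno --help`).

Generate a synthetic family study to try the pipeline:

```sh
metapheno simulate --config sim.yaml --out data/
```

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the heavy end-to-end checks: kinship
recursion vs. 100k-replicate gene dropping, ICA source recovery (Amari
index), heritability recovery on 21 simulated families, LRT calibration
over 1000 null replicates, cross-validated model-selection recovery,
end-to-end pleiotropic-SNP detection, imputation-vs-baseline RMSE, and
bit-level pipeline reproducibility.

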