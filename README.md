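# eqtlcausal

eQTL-anchored causal inference for gene regulatory networks.

Given a gene-expression matrix, a genotype matrix, and a pairing of each
candidate regulator gene *A* to its best eQTL *E*, the package scores every
ordered gene pair *A* → *B* with posterior probabilities built from six
nested likelihood-ratio tests on the triple (*E*, *A*, *B*):

| test | name | verifies |
|---|---|---|
| 0 | correlation | *A* and *B* are correlated |
| 1 | primary linkage | *E* regulates *A* |
| 2 | secondary linkage | *E* regulates *B* |
| 3 | conditional independence | *E* ⟂ *B* given *A* (the chain *E*→*A*→*B*) |
| 4 | relevance | *B* is not independent of (*E*, *A*) jointly |
| 5 | controlled | the *A*–*B* correlation is not pure pleiotropy of *E* |

Expression rows are *supernormalized* (rank-based inverse-normal transform,
re-standardized to exactly zero mean and unit 1/n variance), which gives each
test a closed-form statistic and an analytical null law: `LLR/n ~ D(k1, k2)`,
the distribution of `-0.5*ln(1-Y)` with `Y ~ Beta(k1/2, k2/2)`. Observed
statistics are converted to posterior probabilities by empirical-Bayes local
FDR estimation against the analytical null, then combined into:

* the **traditional** causal score `PT = P2 * P3`, and
* the **novel** composite score `P = (P2 * P5 + P4) / 2`, which stays
  powered under hidden confounders and measurement error.

The package also ships a measurement-error simulation (latent
*E* → A_true → *B* with noisy observed *A*) with a grid scan showing where
the conditional-independence test produces false negatives, a desk-scale
synthetic eQTL-network generator with groundtruth and confounded-pair
labels, and evaluation utilities (midrank AUROC, Davis–Goadrich AUPR,
subsampling, local precision of top predictions split by confounding).

## CLI

```sh
# score a dataset (TSV in, TSV out; per-score matrices + long table)
eqtlcausal infer --expression expr.tsv --genotypes geno.tsv \
    --pairs pairs.tsv --out-prefix results/run --score all

# analytical null parameters / quantiles for a test
eqtlcausal nulldist --test 3 --n 300 --nv 3

# measurement-error grid scan (p-value heatmaps for tests 2-5)
eqtlcausal simulate grid --n 300 --maf 0.1 --grid-points 25 --out grid.tsv

# synthetic benchmark network with groundtruth
eqtlcausal simulate network --n-genes 1000 --n-samples 300 \
    --out-prefix fixtures/net

# AUROC / Davis-Goadrich AUPR of a score table against groundtruth
eqtlcausal evaluate --scores results/run.long.tsv \
    --groundtruth fixtures/net.edges.tsv --out metrics.tsv
```

Input formats: tab-separated, UTF-8, header row. Expression/genotype
matrices carry the row ID in the first column and one sample per remaining
column; the pairs file has two columns (eQTL ID, gene ID). A YAML config
file can supply any flag (`--config cfg.yaml`; explicit flags win).

## Layout

```
src/eqtlcausal/
  preprocess.py   supernormalization, genotype encoding/validation
  lrt.py          sufficient statistics + the six closed-form LLRs (batched)
  nulls.py        the D(k1, k2) family and per-test null laws
  posterior.py    pi0 estimation and LLR -> posterior maps (local FDR)
  scores.py       composite scores and the dataset-level driver
  simulate.py     measurement-error model, grid scan, network generator
  evaluation.py   AUROC, Davis-Goadrich AUPR, subsampling, local precision
  tsv.py          TSV readers/writers
  cli.py          command-line interface
```
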