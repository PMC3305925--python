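# mbopls

Multi-block OPLS (orthogonal projections to latent structures) regression
for multi-platform sample × feature abundance data, with nested
cross-validated model validation, permutation significance, and a
bootstrap/kernel-density feature-relevance score.

The method works in two steps: every block (one analytical platform's
matrix) is fitted against the trait by single-response OPLS and stripped
of its trait-orthogonal structured variance; the filtered blocks are
concatenated along the feature axis and a top-level OPLS is fitted on the
result. One orthogonal-component count per block plus one for the top
model are chosen by seven-fold internal cross-validation. Model quality
is reported as rCV² — the squared Pearson correlation between the trait
and fully nested out-of-fold predictions (median over repeated runs) —
with an empirical permutation P-value (n₀+1)/(n_perm+1). Feature
relevance combines the bootstrap sampling density of each correlation
loading with its permutation-null density into a posterior-style log-odds
score (log B > 0 flags association), complemented by a Spearman screen
with Benjamini–Hochberg FDR control.

## Layout

| module | contents |
|---|---|
| `mbopls.preprocessing` | log2 transform, unit-variance scaling, missing-value filter/imputation, redundant-peak summarization (first PC), Q-matrix population-structure correction, missing-tolerant NIPALS PCA |
| `mbopls.opls` | single-response OPLS fit/predict, correlation loadings, JSON serialization |
| `mbopls.multiblock` | two-step multi-block model, top-regressor construction, internal-CV component selection |
| `mbopls.validation` | rCV², repeated nested external CV, permutation test |
| `mbopls.feature_selection` | bootstrap/null loading distributions, log B score, Spearman screen, BH FDR |
| `mbopls.association` | Euclidean distances, Mantel test (permutation or exhaustive), one-vs-rest differential abundance, Spearman correlation networks |
| `mbopls.simulate` | seeded synthetic multi-block generator with planted shared/orthogonal latents, population structure and missingness |
| `mbopls.io`, `mbopls.pipeline`, `mbopls.cli` | CSV/TSV readers and writers, end-to-end pipeline with JSON run report, `mbopls` command line |

## Command line

```bash
# synthetic dataset (blocks as CSV, trait table, Q-matrix, truth JSON)
mbopls simulate --seed 1 --out data/

# component selection + model fit
mbopls fit --blocks data/block1.csv --blocks data/block2.csv \
    --blocks data/block3.csv --blocks data/block4.csv \
    --trait data/traits.csv:trait --q data/qmatrix.csv \
    --max-orth 3 --folds 7 --seed 1 --out model.json

# nested external cross-validation and permutation significance
mbopls crossval --blocks data/block1.csv ... --trait data/traits.csv:trait \
    --repeats 50 --seed 1 --out cv.json
mbopls permtest --blocks data/block1.csv ... --trait data/traits.csv:trait \
    --n-perm 1000 --seed 1 --out permtest.json

# feature scoring (log B + Spearman/FDR) and correlation network
mbopls select --blocks data/block1.csv ... --trait data/traits.csv:trait \
    --n-boot 200 --n-null 200 --seed 1 --out scores.tsv
mbopls network --matrix data/block1.csv --p-max 0.001 --out net

# Mantel test between metabolite-space and a precomputed distance matrix
mbopls mantel --matrix data/block1.csv --distances genetic_dist.csv

# everything at once, from a YAML config
mbopls run --config run.yaml
```

Input matrices are CSV/TSV with sample IDs in the first column and
feature IDs in the header; empty cells, `NA` or `NaN` mark missing
values. Traits are a sample × trait table; the Q-matrix has one column
per subpopulation with rows summing to one.

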