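# besc — Batch Effect Signature Correction

Blind, single-sample batch-effect correction for gene expression
matrices.

Most batch-correction methods (ComBat, SVA, RUV, HCP) estimate their
correction parameters on the very dataset being corrected, so every time
samples are added the whole correction has to be recomputed — and, worse,
methods that hunt for hidden covariates can remove genuine but unknown
biology. `besc` takes a different route: it learns a fixed set of
orthonormal **batch effect signature** (BES) vectors once, from a large
reference compendium of replicated samples (e.g. named cell lines
measured across many independent collections), and thereafter corrects
any new sample by projecting out those directions. No parameter is ever
refit on the data being corrected, which makes the correction *blind*
and *single-sample*: adding samples never changes earlier corrections.

## The model

Expression of gene *i* in sample *j* is modelled additively:

```
x_ij = μ_i + f_i(y_j) + Σ_l γ_il g_lj + e_ij
```

where *y_j* is a biological covariate that fully fixes the sample's
identity (a cell-line name), the γ/g term is a rank-*L* batch
perturbation shared across collections, and *e* is noise. Because *y* is
categorical, fitting reduces to per-(gene, type) means; the residual
matrix **R** = **X** − fitted means carries only batch effect plus
noise. The signatures are the leading principal components of **Rᵀ** —
unit vectors λ_k in gene space, centered to zero sum and kept mutually
orthonormal.

A new sample **x** is corrected by least squares:

```
a_k = λ_kᵀ x        x_corr = x − Σ_k a_k λ_k
```

Batch effect is quantified by the **Distance Ratio Score** (DRS): the
mean over samples of `log2(d_dt / d_dbst)`, where `d_dt` is the
Euclidean distance to the closest sample of a *different type* and
`d_dbst` the distance to the closest sample of the *same type from a
different batch*. High DRS means replicates cluster by biology, not by
batch. Significance is assessed against a gene-wise permutation null:
signatures fit to a reference whose genes were independently shuffled
across samples should not improve the DRS.

## Worked example

```python
from besc import (SyntheticConfig, generate_dataset, fit_bes_pipeline,
                  correct_matrix, drs)

cfg = SyntheticConfig(m=1000, n_types=8, n_collections=24,
                      samples_per_collection=6, L=5, noise_sd=0.5, seed=7)
expr, ann, truth = generate_dataset(cfg)

# hold out 6 collections as a "new data" validation set
colls = sorted(ann["collection"].unique())
ref_rows = ann["collection"].isin(colls[:18])
ref_ann = ann[ref_rows].reset_index(drop=True)
val_ann = ann[~ref_rows].reset_index(drop=True)
ref = expr.subset_samples(ref_ann["sample_id"])
val = expr.subset_samples(val_ann["sample_id"])

model = fit_bes_pipeline(ref, ref_ann, k_max=10)
print("eigenvalues:", model.eigenvalues.round(1))

corrected = correct_matrix(val, model, k=5).corrected
print("DRS uncorrected:", round(drs(val, val_ann).mean_score, 3))
print("DRS corrected  :", round(drs(corrected, val_ann).mean_score, 3))
```

prints

```
eigenvalues: [1431.9 1115.2  635.9  516.4  216.3    4.     3.9    3.8    3.6    3.6]
DRS uncorrected: 0.493
DRS corrected  : 1.946
```

The eigenvalue spectrum drops sharply after five components — the five
planted batch directions — and correcting the held-out collections with
those five signatures raises their DRS from 0.49 to 1.95: after
correction, a sample's nearest same-type neighbour from another batch is
about four times closer, relative to different-type samples, than
before.

## Command line

```
besc simulate --out data/ --seed 1            # synthetic compendium
besc fit --in ref.tsv --ann ann.tsv --out model/ --k 50
besc correct --model model/ --in new.tsv --out corrected.tsv --k 15
besc drs --in corrected.tsv --ann ann.tsv
besc cv --in ref.tsv --ann ann.tsv --k-grid 0,5,10,...,30 --seed 1
besc permtest --ref ref.tsv --ann ann.tsv --val val.tsv --val-ann va.tsv \
              --k-grid 0,5,10 --n-perm 100 --seed 1
```

Expression files are tab-delimited, genes in rows (first column
`probe_id`), samples in columns; annotations need `sample_id`,
`sample_type` and `collection` columns (an optional `batch` column
defaults to the collection). Models persist as a diffable directory of
text files (signatures, reference means, JSON metadata).

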