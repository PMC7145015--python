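# Methods

## Model and estimation

The package treats the expression of gene *i* in sample *j* as

x_ij = μ_i + f_i(y_j) + Σ_{l=1..L} γ_il g_lj + e_ij,

with a categorical covariate *y* (the sample type: a cell-line name, or
any label that fully fixes the sample's biological identity), a rank-L
batch perturbation whose gene-space directions γ_l are shared across
collections, and i.i.d. noise. Because *y* is categorical, the fit of
μ + f is the one-way group-means fit: no regression machinery, just
per-(gene, type) arithmetic means, with singleton types reproducing
their single sample exactly. The residual matrix R (genes × samples)
then satisfies, per gene and type, a zero within-type sum by
construction.

Signatures are estimated as the principal components of Rᵀ: genes are
centered across samples (numerically a near-no-op, since group-mean
residuals already average to ~0 per gene) and the left singular vectors
of the centered R are taken in order of decreasing singular value, with
eigenvalues s²/(n−1) of the gene–gene covariance stored alongside. The
decomposition is a deterministic full (thin) SVD rather than a
randomized solver; at the intended reference scale (a few thousand
samples) the cost is seconds, and bit-reproducibility across runs is
worth more than the speed of a sketching method. Components with
eigenvalue below 1e−10 × the largest are treated as numerically null;
requesting more truncates with a warning.

Two conventions make models portable. First, each signature's
largest-magnitude entry is made positive, so models agree across linear
algebra backends that differ in eigenvector sign. Second,
`enforce_zero_sum` (default on) mean-centers each signature over genes
and re-orthonormalizes the set by modified Gram–Schmidt in eigenvalue
order. Plain eigenvectors of a residual covariance are not generally
zero-sum; centering them buys a useful exact property — the correction
becomes invariant to adding a constant to every gene of a sample, i.e.
insensitive to per-sample intensity offsets — at the price of a
perturbation that is tiny whenever the residuals are themselves close to
zero-mean per sample. The flag is persisted in the model metadata so a
loaded model behaves identically.

## Correction

For a new sample x on the model's probe set, weights are the scalar
products a_k = λ_kᵀx and the corrected vector is x − Σ a_k λ_k — an
orthogonal projection, hence idempotent, norm-nonincreasing in k, and
exactly reconstructable (corrected + Σ a_k λ_k = x). The projection is
applied to the raw vector, not to the vector minus reference means: for
any component of x inside the signature span the two are equivalent, and
the raw form keeps the single-sample contract literal. An optional
`center_by_reference_means` flag subtracts the training means first and
restores them after, for users who prefer weights measured about the
reference origin.

When a matrix to correct carries only a subset of the model's probes
(coverage threshold: 0.8 by default), the subset rows of the signature
matrix are no longer orthonormal, so weights come from a general
least-squares solve on the intersection, and only shared probes are
returned. Each column is corrected independently; correcting a submatrix
equals the submatrix of the full correction.

## Distance Ratio Score

DRS is the mean over evaluable samples of log2(d_dt / d_dbst), where
d_dt is the Euclidean distance (over all shared probes, on log2 values,
unfiltered and unscaled) to the nearest different-type sample and d_dbst
to the nearest same-type different-batch sample. Samples missing either
neighbour kind are excluded and counted; a nearest distance of exactly 0
(duplicate profiles) excludes the sample rather than clamping, avoiding
unbounded log ratios. Nearest-neighbour ties resolve to the smallest
sample index, making the score deterministic. The score is invariant
under renaming of type/batch labels and under global rotations of
expression space.

## Permutation null

To test whether a correction is meaningful, each gene of the reference
is permuted independently across samples (preserving per-gene marginals,
destroying inter-gene batch coherence), the full fit is re-run, and the
validation set is corrected with each null model. Replicate seeds are
spawned from a single master seed, so null ensembles are exactly
reproducible. At each signature count the observed DRS is compared to
the null DRS distribution two ways — a one-sample Student's t-test and a
z-score with one-sided normal p — because both summaries are in common
use and they diverge when the null is small or non-normal; a
zero-variance null is reported as degenerate with a warning rather than
silently producing 0/0.

## Grouped cross-validation

Collections (deposited datasets; the default batch unit) are assigned
whole to folds — largest collection first onto the currently lightest
fold, ties broken by a seeded shuffle — so no collection's batch
perturbation leaks between training and test. With many collections of
skewed sizes this greedy balance keeps every fold within a few percent
of the nominal test fraction. Per fold, signatures are fit on training
collections only, the test collections are corrected over a grid of
signature counts, and the per-sample DRS values are averaged; a test
fold lacking two types or two batches is skipped with a warning.

## Differential-expression probe

`de_count` is a deliberately generic conservativeness probe, not a
recommended DE pipeline: per-gene ordinary least squares with the group
and an optional categorical covariate (batch) as factors, two-sided t
p-values for the group effect, Benjamini–Hochberg adjustment, and a
count of genes under the FDR threshold (default 0.05). A design in which
the group is constant within every batch is rejected as confounded. The
quantity of interest is never the count itself but its stability under
correction.

## Synthetic data generator

The generator draws baseline gene means N(8, 2²) (log2 scale), per-type
effects N(0, 2²), a shared loading matrix Γ (entries N(0, 1)), one score
vector per collection (entries N(0, 1)), and noise N(0, 0.5²). All
samples of a collection share a score vector (collection = batch), and
types are assigned round-robin with a per-collection offset so each type
meets many batches. The per-gene batch perturbation scale is
(loading sd)·(score sd)·√L; `SyntheticConfig.with_batch_to_noise(r)`
sets the noise sd to achieve a given batch-to-noise ratio r, the knob
the simulation studies vary (r ∈ {2, 3, 5} across the test suite).
Default sizes (2 000 genes, 20 collections × 10 samples, 10 types, L=5)
are chosen so every pipeline stage runs in seconds while the planted
subspace remains identifiable; the generator accepts array-scale m
(~54 000) when needed.

Two optional features extend the additive core:

- `shared_direction_mode=False` draws fresh loadings per collection — a
  negative control under which blind correction is expected to fail,
  since nothing learned from the reference transfers.
- `bio_within_scale > 0` adds within-type biological scatter along an
  orthonormal basis of the type-effect span, emulating the fact that
  real within-type variation (culture drift, treatment response)
  perturbs the same pathways that separate types. This is off by
  default. It matters for one specific phenomenon: the shape of the
  cross-validated DRS curve beyond the true batch rank. In the purely
  additive model, signatures beyond L capture isotropic training noise,
  and projecting test samples off random directions is statistically
  neutral, so the cv curve plateaus rather than declines. With
  biological scatter on, the post-batch eigenvectors align with
  biological directions, over-correction strips real type signal, and
  the cv DRS curve rises to the planted rank and falls after it — the
  over-correction regime the cv harness exists to detect. The cv peak
  studies therefore enable it (scale 2.5, i.e. biological scatter
  somewhat above the noise floor in eigenvalue terms).

`plant_biological_contrast` adds a balanced two-group ±effect/2 contrast
on chosen genes, optionally projected orthogonal to the planted batch
span; group assignment is random across collections, so the contrast is
never confounded with batch.

What passing tests on this generator do *not* show: robustness to
probe-level artifacts, intensity-dependent bias, non-Gaussian noise,
heteroscedastic genes, or real collection-size distributions — none of
which the generator emulates.

## Problem sizes in the shipped studies

The packaged simulation studies use 400–2 000 genes and 100–280 samples:
subspace recovery at the generator defaults (m=2 000, 20 collections,
L=5, batch-to-noise 5, 10 replicate seeds); blind correction of 8
held-out collections against batch-free ground truth (m=1 000, ratio 2);
the cv peak study at m=400 with L=10 and biological scatter; the
permutation study with 20 null replicates. These sizes give stable
statistics in seconds per study while exercising every code path at
realistic aspect ratios.

## Known limitations

- Signatures are only as clean as the reference: any biological
  variation not captured by the type label (e.g. a contrast present in
  the reference residuals) will be absorbed into the signature span and
  subsequently removed from corrected data.
- Correction assumes the new data's batch perturbations lie in the span
  learned from the reference; idiosyncratic, collection-specific
  directions are untouched (and untouchable by any blind method).
- The number of signatures k is user-chosen. Grouped cross-validation
  gives a data-driven curve, but on data without a biological component
  in the residual space the curve can plateau, leaving k weakly
  identified above the true rank.
- DRS requires every evaluable sample to have a same-type replicate in
  another batch; sets without cross-batch replication cannot be scored.
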