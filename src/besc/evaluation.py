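"""Quantifying batch effect and validating signature models.

The central metric is the Distance Ratio Score (DRS). For each sample it
compares two nearest-neighbor distances in expression space:

    score_i = log2( d(x_i, nearest different-type sample)
                    / d(x_i, nearest same-type, different-batch sample) )

and the DRS is the mean score over evaluable samples. When replicates of
a sample type cluster together regardless of batch, the denominator is
small relative to the numerator and the DRS is high; when samples cluster
by batch instead, the DRS is low. Distances are Euclidean over all shared
probes of the log2 matrix. Because the score is per-sample, DRS values
from different test sets can be averaged — which is what makes grouped
cross-validation of signature models possible.

Statistical significance of a correction is assessed against a gene-wise
permutation null: permuting each gene independently across samples of the
reference set destroys any coherent batch direction while preserving
every gene's marginal distribution, so signatures fit to permuted data
should not improve the DRS of a validation set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from statsmodels.stats.multitest import multipletests

from besc.data_model import ExpressionMatrix, validate_annotation
from besc.estimation import BESModel, fit_bes_pipeline
from besc.correction import correct_matrix

logger = logging.getLogger(__name__)


@dataclass
class DRSResult:
    """Per-sample log2 distance ratios and their mean."""

    per_sample_score: pd.Series      # indexed by sample_id, evaluable only
    mean_score: float
    n_evaluable: int
    n_excluded: int
    exclusion_reasons: dict          # sample_id -> reason


@dataclass
class PermutationTestResult:
    """True vs permutation-null DRS along a grid of signature counts."""

    k_grid: np.ndarray
    true_drs: np.ndarray             # per k
    null_drs: np.ndarray             # n_perm x len(k_grid)
    z_score: np.ndarray
    p_normal: np.ndarray             # one-sided, from z
    p_ttest: np.ndarray              # one-sample Student's t against null
    n_perm: int
    seed: int


def drs(expr: ExpressionMatrix, ann: pd.DataFrame) -> DRSResult:
    """Distance Ratio Score of a sample set.

    Needs at least two sample types and two batches. Samples lacking
    either neighbor kind, or whose required nearest distance is exactly
    zero, are excluded and counted with a reason.
    """
    ann = validate_annotation(ann)
    if list(ann["sample_id"]) != list(expr.sample_ids):
        raise ValueError("annotation is not aligned to the expression matrix")
    types = ann["sample_type"].to_numpy()
    batches = ann["batch"].to_numpy()
    if len(set(types)) < 2:
        raise ValueError("DRS needs at least 2 sample types")
    if len(set(batches)) < 2:
        raise ValueError("DRS needs at least 2 batches")
    n = expr.n_samples
    dist = squareform(pdist(expr.values.T, metric="euclidean"))
    scores: dict[str, float] = {}
    excluded: dict[str, str] = {}
    for i in range(n):
        diff_type = np.flatnonzero(types != types[i])
        same_type_diff_batch = np.flatnonzero(
            (types == types[i]) & (batches != batches[i])
        )
        if diff_type.size == 0:
            excluded[expr.sample_ids[i]] = "no different-type sample"
            continue
        if same_type_diff_batch.size == 0:
            excluded[expr.sample_ids[i]] = "no same-type different-batch sample"
            continue
        # np.argmin returns the first minimum: ties resolve to the
        # smallest sample index, deterministically
        d_dt = dist[i, diff_type[np.argmin(dist[i, diff_type])]]
        d_db = dist[i, same_type_diff_batch[np.argmin(dist[i, same_type_diff_batch])]]
        if d_dt == 0.0 or d_db == 0.0:
            logger.warning("sample %s has a zero nearest distance; excluded",
                           expr.sample_ids[i])
            excluded[expr.sample_ids[i]] = "zero distance"
            continue
        scores[expr.sample_ids[i]] = float(np.log2(d_dt / d_db))
    if not scores:
        raise ValueError("no evaluable samples for DRS")
    per_sample = pd.Series(scores, name="drs")
    return DRSResult(
        per_sample_score=per_sample,
        mean_score=float(per_sample.mean()),
        n_evaluable=len(per_sample),
        n_excluded=len(excluded),
        exclusion_reasons=excluded,
    )


def permuted_null_bes(
    expr: ExpressionMatrix,
    ann: pd.DataFrame,
    k_max: int,
    n_perm: int = 100,
    seed: int = 0,
    enforce_zero_sum: bool = True,
) -> list[BESModel]:
    """Fit signature models to gene-wise permuted copies of a reference set.

    Each replicate permutes every gene's values independently across
    samples (destroying batch structure, preserving per-gene marginals),
    then runs the full type-means -> residuals -> signatures fit.
    Replicate seeds are spawned deterministically from ``seed``.
    """
    if n_perm < 2:
        raise ValueError("need at least 2 permutation replicates")
    ann = validate_annotation(ann)
    child_seeds = np.random.SeedSequence(seed).spawn(n_perm)
    models = []
    for rep, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        permuted = ExpressionMatrix(
            expr.probe_ids.copy(),
            expr.sample_ids.copy(),
            rng.permuted(expr.values, axis=1),
        )
        models.append(fit_bes_pipeline(
            permuted, ann, k_max, enforce_zero_sum=enforce_zero_sum,
            metadata={"permutation_replicate": rep, "seed": seed},
        ))
    return models


def _one_sided_from_null(
    true_val: float, null_vals: np.ndarray
) -> tuple[float, float, float]:
    """(z, normal p, t-test p) for H1: true DRS exceeds the null DRS."""
    mu = float(np.mean(null_vals))
    sd = float(np.std(null_vals, ddof=1))
    if sd == 0.0:
        if np.isclose(true_val, mu):
            return 0.0, 0.5, 0.5
        warnings.warn("zero variance in permutation null; p is degenerate",
                      RuntimeWarning, stacklevel=2)
        p = 0.0 if true_val > mu else 1.0
        return np.inf if true_val > mu else -np.inf, p, p
    z = (true_val - mu) / sd
    p_norm = float(stats.norm.sf(z))
    # one-sample t of the null sample against the observed DRS; small when
    # the null mean sits far below the observed value
    p_t = float(stats.ttest_1samp(null_vals, popmean=true_val,
                                  alternative="less").pvalue)
    return float(z), p_norm, p_t


def drs_pvalue(
    expr: ExpressionMatrix,
    ann: pd.DataFrame,
    true_model: BESModel,
    null_models: list[BESModel],
    k_grid: list[int],
) -> PermutationTestResult:
    """Permutation p-value of the corrected DRS at each signature count.

    At each k the validation set is corrected with the true model and with
    every null model; both a one-sample Student's t p-value and a z-score
    with one-sided normal p-value are reported.
    """
    if len(null_models) < 2:
        raise ValueError("need at least 2 null models")
    ann = validate_annotation(ann)
    k_grid = np.asarray(sorted(k_grid), dtype=int)
    n_perm = len(null_models)
    true_scores = np.empty(len(k_grid))
    null_scores = np.empty((n_perm, len(k_grid)))
    for a, k in enumerate(k_grid):
        res = correct_matrix(expr, true_model, int(k))
        true_scores[a] = drs(res.corrected, ann).mean_score
        for b, nm in enumerate(null_models):
            resn = correct_matrix(expr, nm, int(min(k, nm.n_signatures)))
            null_scores[b, a] = drs(resn.corrected, ann).mean_score
    z = np.empty(len(k_grid))
    p_norm = np.empty(len(k_grid))
    p_t = np.empty(len(k_grid))
    for a in range(len(k_grid)):
        z[a], p_norm[a], p_t[a] = _one_sided_from_null(
            true_scores[a], null_scores[:, a])
    seed = next((m.metadata.get("seed") for m in null_models
                 if "seed" in m.metadata), -1)
    return PermutationTestResult(
        k_grid=k_grid, true_drs=true_scores, null_drs=null_scores,
        z_score=z, p_normal=p_norm, p_ttest=p_t, n_perm=n_perm,
        seed=int(seed) if seed is not None else -1,
    )


def grouped_cv_split(
    ann: pd.DataFrame, n_folds: int = 5, seed: int = 0
) -> np.ndarray:
    """Assign whole collections to folds, balancing sample counts greedily.

    Every sample of a collection lands in the same fold (no leakage of a
    collection's batch perturbation between training and test). Returns
    the fold index per annotation row.
    """
    ann = validate_annotation(ann)
    sizes = ann["collection"].value_counts()
    if len(sizes) < n_folds:
        raise ValueError(
            f"{len(sizes)} collections cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = sizes.index.to_numpy().copy()
    rng.shuffle(order)
    # largest-first greedy onto the currently lightest fold; the seeded
    # shuffle breaks ties among equal-size collections
    order = sorted(order, key=lambda c: -sizes[c])
    fold_of_collection: dict[str, int] = {}
    load = np.zeros(n_folds, dtype=int)
    for c in order:
        f = int(np.argmin(load))
        fold_of_collection[c] = f
        load[f] += sizes[c]
    return ann["collection"].map(fold_of_collection).to_numpy(dtype=int)


def cross_validate_drs(
    expr: ExpressionMatrix,
    ann: pd.DataFrame,
    k_grid: list[int],
    n_folds: int = 5,
    seed: int = 0,
    enforce_zero_sum: bool = True,
) -> pd.Series:
    """Collection-grouped cross-validated DRS per signature count.

    Per fold: signatures are fit on the training collections only, the
    test collections are corrected at each k and their DRS computed from
    their own annotations; fold values are averaged per k. A fold whose
    test set lacks two sample types or two batches is skipped with a
    warning. k = 0 rows equal the uncorrected test DRS.
    """
    ann = validate_annotation(ann)
    if list(ann["sample_id"]) != list(expr.sample_ids):
        raise ValueError("annotation is not aligned to the expression matrix")
    k_grid = sorted(set(int(k) for k in k_grid))
    folds = grouped_cv_split(ann, n_folds=n_folds, seed=seed)
    k_fit = max(k_grid)
    rows = []
    for f in range(n_folds):
        test_mask = folds == f
        test_ann = ann.loc[test_mask].reset_index(drop=True)
        train_ann = ann.loc[~test_mask].reset_index(drop=True)
        if test_ann["sample_type"].nunique() < 2 or test_ann["batch"].nunique() < 2:
            warnings.warn(f"fold {f}: test set lacks 2 types or 2 batches; "
                          "skipped", RuntimeWarning, stacklevel=2)
            continue
        test_expr = expr.subset_samples(test_ann["sample_id"])
        train_expr = expr.subset_samples(train_ann["sample_id"])
        model = None
        if k_fit > 0:
            model = fit_bes_pipeline(train_expr, train_ann, k_fit,
                                     enforce_zero_sum=enforce_zero_sum)
        row = {}
        for k in k_grid:
            if k == 0 or model is None:
                corrected = test_expr
            else:
                corrected = correct_matrix(
                    test_expr, model, min(k, model.n_signatures)).corrected
            row[k] = drs(corrected, test_ann).mean_score
        rows.append(row)
    if not rows:
        raise ValueError("no usable cross-validation folds")
    table = pd.DataFrame(rows)
    out = table.mean(axis=0)
    out.index.name = "k"
    out.name = "mean_test_drs"
    return out


def correction_correlation(
    model_a: BESModel,
    model_b: BESModel,
    k_grid: list[int],
    n_vectors: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Agreement between the corrections of two signature models.

    Random standard-normal vectors are corrected with both models; at each
    k the Pearson correlation of the two *estimated batch components*
    (sum_k a_k lambda_k) is averaged over vectors. Models trained on
    different reference sets that captured the same underlying directions
    agree strongly at small k.
    """
    if list(model_a.probe_ids) != list(model_b.probe_ids):
        raise ValueError("models must share an identical probe set and order")
    rng = np.random.default_rng(seed)
    m = model_a.signatures.shape[0]
    k_grid = sorted(set(int(k) for k in k_grid))
    X = rng.standard_normal((m, n_vectors))
    out = {}
    for k in k_grid:
        if k == 0:
            out[k] = np.nan
            continue
        ka = min(k, model_a.n_signatures)
        kb = min(k, model_b.n_signatures)
        Da, Db = model_a.signatures[:, :ka], model_b.signatures[:, :kb]
        Ba = Da @ (Da.T @ X)
        Bb = Db @ (Db.T @ X)
        rs = []
        for j in range(n_vectors):
            sa, sb = Ba[:, j].std(), Bb[:, j].std()
            if sa == 0 or sb == 0:
                continue
            rs.append(np.corrcoef(Ba[:, j], Bb[:, j])[0, 1])
        out[k] = float(np.mean(rs)) if rs else np.nan
    ser = pd.Series(out, name="mean_correction_correlation")
    ser.index.name = "k"
    return ser


def de_count(
    expr: ExpressionMatrix,
    group_labels,
    covariate_labels=None,
    fdr: float = 0.05,
) -> int:
    """Number of genes differing between two groups at a given FDR.

    Fits one ordinary-least-squares model per gene with the group and an
    optional categorical covariate (e.g. batch) as factors, takes the
    two-sided t p-value of the group effect, adjusts by Benjamini-Hochberg
    and counts adjusted p < ``fdr``. This is a generic conservativeness
    probe — a well-behaved correction should leave a group contrast that
    is orthogonal to the batch space essentially untouched.
    """
    groups = np.asarray(group_labels)
    n = expr.n_samples
    if groups.shape[0] != n:
        raise ValueError("group labels do not match the number of samples")
    levels = sorted(set(groups.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if min((groups == g).sum() for g in levels) < 2:
        raise ValueError("each group needs at least 2 samples")
    g = (groups == levels[1]).astype(float)
    X_cols = [np.ones(n), g]
    if covariate_labels is not None:
        cov = np.asarray(covariate_labels)
        if all(len(set(groups[cov == c])) == 1 for c in set(cov.tolist())):
            raise ValueError(
                "design is confounded: the group is constant within every "
                "covariate level")
        dummies = pd.get_dummies(pd.Series(cov), drop_first=True)
        X_cols.extend(dummies[c].to_numpy(dtype=float) for c in dummies)
    X = np.column_stack(X_cols)
    rank = np.linalg.matrix_rank(X)
    dof = n - rank
    if dof < 1:
        raise ValueError("no residual degrees of freedom")
    pinv = np.linalg.pinv(X)
    Y = expr.values.T                       # n x m
    B = pinv @ Y                            # p x m
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / dof
    var_g = np.linalg.pinv(X.T @ X)[1, 1]
    se = np.sqrt(np.maximum(sigma2 * var_g, 1e-300))
    t = B[1, :] / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    rejected, _, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return int(rejected.sum())
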