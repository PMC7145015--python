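"""Blind, single-sample removal of batch effect via signature projection.

For a new expression vector x and the first k signatures (columns of D),
the batch-effect estimate is the least-squares fit sum_k a_k * lambda_k
and the corrected expression is the residual

    x_corr = x - sum_k a_k * lambda_k .

When x covers the model's full probe set the signatures are orthonormal,
so a_k = lambda_k^T x (a plain scalar product) and the correction is an
orthogonal projection: idempotent, norm-nonincreasing in k, and — because
signatures are zero-sum — invariant to adding a constant to every gene of
a sample. No other sample enters the computation, so samples can be
corrected one at a time and corrections never change when data are added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from besc.data_model import ExpressionMatrix
from besc.estimation import BESModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 0.8


@dataclass
class CorrectionResult:
    """Corrected expression plus the fitted signature weights per sample."""

    corrected: ExpressionMatrix
    weights: np.ndarray          # k_used x n
    k_used: int
    probe_coverage: float


def correct_sample(
    x: np.ndarray,
    model: BESModel,
    k: int,
    center_by_reference_means: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Correct a single expression vector given on the model's probe order.

    Returns ``(corrected, weights)`` where ``weights[j] = lambda_{j+1}^T x``.
    ``k = 0`` is the identity correction. The optional
    ``center_by_reference_means`` flag subtracts the per-gene reference
    means before projection and adds them back afterwards; the default
    projects the raw vector, which is equivalent for any component lying
    in the signature span and is the plain reading of the correction
    formula.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != model.signatures.shape[0]:
        raise ValueError(
            f"expression vector has length {x.shape[0] if x.ndim == 1 else x.shape},"
            f" expected {model.signatures.shape[0]}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("expression vector contains non-finite values")
    if k < 0 or k > model.n_signatures:
        raise ValueError(f"k = {k} outside [0, {model.n_signatures}]")
    if k == 0:
        return x.copy(), np.empty(0)
    D = model.signatures[:, :k]
    work = x - model.reference_means if center_by_reference_means else x
    a = D.T @ work
    corrected = x - D @ a
    return corrected, a


def correct_matrix(
    expr: ExpressionMatrix,
    model: BESModel,
    k: int,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    center_by_reference_means: bool = False,
) -> CorrectionResult:
    """Correct every sample of a matrix independently.

    Probes are matched to the model by id. With full coverage each sample
    is corrected by scalar-product weights; when the matrix carries only a
    strict subset of the model's probes, the subset rows of D are no
    longer orthonormal, so weights come from a general least-squares solve
    on the intersection and only the shared probes are corrected. Coverage
    below ``min_coverage`` is an error.
    """
    if k < 0 or k > model.n_signatures:
        raise ValueError(f"k = {k} outside [0, {model.n_signatures}]")
    have = set(expr.probe_ids)
    shared = [p for p in model.probe_ids if p in have]
    coverage = len(shared) / len(model.probe_ids)
    if coverage < min_coverage:
        raise ValueError(
            f"probe coverage {coverage:.3f} below required {min_coverage:.3f}"
        )
    orthonormal = len(shared) == len(model.probe_ids)
    sub = expr if orthonormal and expr.n_probes == len(shared) else expr.subset_probes(shared)
    if k == 0:
        return CorrectionResult(
            corrected=ExpressionMatrix(
                sub.probe_ids.copy(), sub.sample_ids.copy(), sub.values.copy()
            ),
            weights=np.empty((0, sub.n_samples)),
            k_used=0,
            probe_coverage=coverage,
        )
    row_of = {p: i for i, p in enumerate(model.probe_ids)}
    rows = [row_of[p] for p in sub.probe_ids]
    D = model.signatures[rows, :k]
    X = sub.values
    if center_by_reference_means:
        mu = model.reference_means[rows][:, None]
        work = X - mu
    else:
        work = X
    if orthonormal:
        A = D.T @ work                       # orthonormal: scalar products
    else:
        A, *_ = np.linalg.lstsq(D, work, rcond=None)
    corrected = X - D @ A
    return CorrectionResult(
        corrected=ExpressionMatrix(
            sub.probe_ids.copy(), sub.sample_ids.copy(), corrected
        ),
        weights=A,
        k_used=k,
        probe_coverage=coverage,
    )
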