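"""Estimation of batch effect signatures (BES) from a reference compendium.

The reference model for the expression of gene i in sample j is

    x_ij = mu_i + f_i(y_j) + sum_l gamma_il * g_lj + e_ij

where y_j is a fully identifying biological covariate (cell line name),
the gamma/g term is a low-rank shared batch perturbation and e is noise.
Because y_j is categorical, f_i reduces to per-(gene, type) means: fitting
the model is a one-way group-means fit. The residual matrix R (expression
minus fitted type means) then carries only batch effect plus noise, and
the signatures are the leading principal components of R^T — equivalently
the top eigenvectors of the gene-gene covariance, equivalently (up to sign)
the left singular vectors of the per-gene-centered R.

Each signature is a unit vector over genes; with ``enforce_zero_sum`` each
is additionally mean-centered over genes and the set re-orthonormalized,
which makes the downstream correction invariant to per-sample constant
shifts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from besc.data_model import ExpressionMatrix, validate_annotation

logger = logging.getLogger(__name__)

RANK_TOL = 1e-10  # eigenvalue cutoff relative to the largest


@dataclass
class TypeMeanModel:
    """Per-(gene, sample type) fitted means plus per-gene global means."""

    probe_ids: np.ndarray
    global_means: np.ndarray            # length m
    type_means: pd.DataFrame            # m x n_types, columns = type labels
    type_counts: pd.Series              # samples per type in training

    @property
    def types(self) -> list[str]:
        return list(self.type_means.columns)


@dataclass
class ResidualMatrix:
    """Expression after removing fitted sample-type means; m x n."""

    probe_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray


@dataclass
class BESModel:
    """Ordered orthonormal batch effect signatures over a fixed probe set.

    ``signatures`` is the m x K matrix D whose columns are unit vectors in
    gene space ordered by decreasing eigenvalue of the residual covariance.
    ``reference_means`` are the per-gene global means of the training set,
    used only by the optional mean-centering correction path.
    """

    probe_ids: np.ndarray
    signatures: np.ndarray              # m x K
    eigenvalues: np.ndarray             # length K, nonincreasing
    reference_means: np.ndarray         # length m
    zero_sum_enforced: bool
    metadata: dict = field(default_factory=dict)

    @property
    def n_signatures(self) -> int:
        return self.signatures.shape[1]

    def validate(self) -> None:
        D = self.signatures
        gram = D.T @ D
        if not np.allclose(gram, np.eye(D.shape[1]), atol=1e-8):
            raise ValueError("signature columns are not orthonormal")
        ev = self.eigenvalues
        if np.any(ev < -1e-12) or np.any(np.diff(ev) > 1e-12):
            raise ValueError("eigenvalues must be nonnegative and nonincreasing")
        if self.zero_sum_enforced:
            sums = D.sum(axis=0)
            if np.any(np.abs(sums) > 1e-8 * np.sqrt(D.shape[0])):
                raise ValueError("zero-sum flag set but columns do not sum to 0")

    # ---- persistence: a diffable directory of text files ----

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        sig = pd.DataFrame(
            self.signatures,
            index=pd.Index(self.probe_ids, name="probe_id"),
            columns=[f"BES{k + 1}" for k in range(self.n_signatures)],
        )
        sig.to_csv(directory / "signatures.tsv", sep="\t", float_format="%.10g")
        means = pd.DataFrame(
            {"reference_mean": self.reference_means},
            index=pd.Index(self.probe_ids, name="probe_id"),
        )
        means.to_csv(directory / "reference_means.tsv", sep="\t",
                     float_format="%.10g")
        sidecar = {
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "K": int(self.n_signatures),
            "zero_sum_enforced": bool(self.zero_sum_enforced),
            **self.metadata,
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "BESModel":
        directory = Path(directory)
        sig = pd.read_csv(directory / "signatures.tsv", sep="\t", index_col=0)
        means = pd.read_csv(directory / "reference_means.tsv", sep="\t",
                            index_col=0)
        sidecar = json.loads((directory / "model.json").read_text())
        meta = {k: v for k, v in sidecar.items()
                if k not in ("eigenvalues", "K", "zero_sum_enforced")}
        return cls(
            probe_ids=sig.index.to_numpy(dtype=object),
            signatures=sig.to_numpy(dtype=float),
            eigenvalues=np.asarray(sidecar["eigenvalues"], dtype=float),
            reference_means=means["reference_mean"].to_numpy(dtype=float),
            zero_sum_enforced=bool(sidecar["zero_sum_enforced"]),
            metadata=meta,
        )


def fit_type_means(expr: ExpressionMatrix, ann: pd.DataFrame) -> TypeMeanModel:
    """Fit per-(gene, sample type) means — the categorical group-means model.

    ``ann`` must be aligned to ``expr`` (same samples, same order); types
    with a single sample get that sample as their mean.
    """
    ann = validate_annotation(ann)
    if list(ann["sample_id"]) != list(expr.sample_ids):
        raise ValueError("annotation is not aligned to the expression matrix")
    types = ann["sample_type"].to_numpy()
    df = pd.DataFrame(expr.values, columns=types,
                      index=pd.Index(expr.probe_ids, name="probe_id"))
    type_means = df.T.groupby(level=0).mean().T  # m x n_types
    type_counts = pd.Series(types).value_counts()
    type_means = type_means[sorted(type_means.columns)]
    type_counts = type_counts.reindex(type_means.columns)
    return TypeMeanModel(
        probe_ids=expr.probe_ids.copy(),
        global_means=expr.values.mean(axis=1),
        type_means=type_means,
        type_counts=type_counts,
    )


def compute_residuals(
    expr: ExpressionMatrix, model: TypeMeanModel, ann: pd.DataFrame
) -> ResidualMatrix:
    """Subtract each sample's fitted type mean: r_ij = x_ij - mean_i(type_j)."""
    ann = validate_annotation(ann)
    if list(ann["sample_id"]) != list(expr.sample_ids):
        raise ValueError("annotation is not aligned to the expression matrix")
    unseen = sorted(set(ann["sample_type"]) - set(model.types))
    if unseen:
        raise ValueError(f"sample types not present in the fitted model: {unseen}")
    fitted = model.type_means[ann["sample_type"].to_numpy()].to_numpy()
    return ResidualMatrix(
        probe_ids=expr.probe_ids.copy(),
        sample_ids=expr.sample_ids.copy(),
        values=expr.values - fitted,
    )


def _modified_gram_schmidt(V: np.ndarray, drop_tol: float = 1e-10) -> np.ndarray:
    """Orthonormalize columns in order, dropping numerically null columns."""
    V = V.copy()
    cols = []
    for k in range(V.shape[1]):
        v = V[:, k]
        for q in cols:
            v = v - (q @ v) * q
        nrm = np.linalg.norm(v)
        if nrm > drop_tol:
            cols.append(v / nrm)
    return np.column_stack(cols) if cols else np.empty((V.shape[0], 0))


def _fix_signs(D: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive."""
    if D.size == 0:
        return D
    idx = np.argmax(np.abs(D), axis=0)
    signs = np.sign(D[idx, np.arange(D.shape[1])])
    signs[signs == 0] = 1.0
    return D * signs


def estimate_bes(
    resid: ResidualMatrix,
    k_max: int,
    enforce_zero_sum: bool = True,
    reference_means: np.ndarray | None = None,
    metadata: dict | None = None,
) -> BESModel:
    """Extract batch effect signatures from a residual matrix.

    Computes the top ``k_max`` principal components of R^T: genes are
    centered across samples (a near-no-op since group-mean residuals
    already average to ~0 per gene), then the left singular vectors of the
    centered R are taken in order of decreasing singular value. Eigenvalues
    stored are those of the gene-gene sample covariance, s^2 / (n - 1).

    With ``enforce_zero_sum`` each signature is mean-centered over genes
    and the set re-orthonormalized by modified Gram-Schmidt in eigenvalue
    order, making them zero-sum unit vectors. Requesting more components
    than the numerical rank truncates with a warning.
    """
    R = np.asarray(resid.values, dtype=float)
    m, n = R.shape
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    limit = min(m, n - 1) if n > 1 else 1
    if k_max > limit:
        raise ValueError(f"k_max = {k_max} exceeds min(m, n - 1) = {limit}")
    Rc = R - R.mean(axis=1, keepdims=True)
    # deterministic full (thin) SVD; reference scale keeps this tractable
    U, s, _ = np.linalg.svd(Rc, full_matrices=False)
    eig = s**2 / max(n - 1, 1)
    rank = int(np.sum(eig > RANK_TOL * eig[0])) if eig.size and eig[0] > 0 else 0
    if rank == 0:
        raise ValueError("residual matrix is numerically zero; no signatures")
    k = k_max
    if k > rank:
        warnings.warn(
            f"requested {k_max} signatures but numerical rank is {rank}; "
            "truncating", RuntimeWarning, stacklevel=2,
        )
        k = rank
    D = U[:, :k]
    eig = eig[:k]
    if enforce_zero_sum:
        D = D - D.mean(axis=0, keepdims=True)
        D = _modified_gram_schmidt(D)
        if D.shape[1] < k:
            warnings.warn(
                "zero-sum centering reduced the signature count to "
                f"{D.shape[1]}", RuntimeWarning, stacklevel=2,
            )
            eig = eig[: D.shape[1]]
    D = _fix_signs(D)
    if reference_means is None:
        reference_means = np.zeros(m)
    model = BESModel(
        probe_ids=resid.probe_ids.copy(),
        signatures=D,
        eigenvalues=eig,
        reference_means=np.asarray(reference_means, dtype=float),
        zero_sum_enforced=enforce_zero_sum,
        metadata={"n_train": int(n), **(metadata or {})},
    )
    model.validate()
    return model


def fit_bes_pipeline(
    expr: ExpressionMatrix,
    ann: pd.DataFrame,
    k_max: int,
    enforce_zero_sum: bool = True,
    metadata: dict | None = None,
) -> BESModel:
    """Full reference fit: type means -> residuals -> signatures."""
    ann = validate_annotation(ann)
    tm = fit_type_means(expr, ann)
    resid = compute_residuals(expr, tm, ann)
    meta = {
        "n_types": int(ann["sample_type"].nunique()),
        "n_collections": int(ann["collection"].nunique()),
        **(metadata or {}),
    }
    return estimate_bes(
        resid, k_max, enforce_zero_sum=enforce_zero_sum,
        reference_means=tm.global_means, metadata=meta,
    )
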