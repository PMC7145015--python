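"""Synthetic expression compendia with planted low-rank batch structure.

Generates data under the additive model

    x_ij = mu_i + f_i(type_j) + sum_l gamma_il * g_l(collection_j) + e_ij

i.e. per-type gene means, a rank-L batch perturbation, and i.i.d. Gaussian
noise. The central premise being emulated is that batch perturbation
*directions* (the columns of Gamma) are shared across collections while
each collection draws its own scores g — so a model trained on one set of
collections can correct samples from entirely new collections. A
``shared_direction_mode=False`` switch draws fresh loadings per collection
instead, as a negative control under which blind correction should fail.

Collections double as batches, mirroring compendia assembled from public
repositories where each deposited series is processed as one batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from besc.data_model import ExpressionMatrix, validate_annotation


@dataclass
class SyntheticConfig:
    """Generator settings.

    The per-gene standard deviation of the total batch perturbation is
    ``batch_loadings_scale * batch_score_scale * sqrt(L)``; the
    batch-to-noise ratio reported by :meth:`batch_noise_ratio` is that
    quantity over ``noise_sd``. Defaults give a compendium of 20
    collections x 10 samples spanning 10 sample types with 5 shared batch
    directions — small enough to iterate on, large enough for the
    signature subspace to be identifiable.

    Scales are in log2-expression units. ``type_effect_scale = 2`` spreads
    type means by ~2 log2 units (biological differences between cell lines
    dwarf noise); ``noise_sd = 0.5`` is typical replicate scatter for
    processed arrays.

    ``bio_within_scale`` adds within-type biological scatter concentrated
    along the directions that separate the type means (culture drift,
    treatment response and the like vary the same pathways that differ
    between types). It is off by default; switching it on creates the
    over-correction regime in which removing more signatures than the
    planted batch rank starts stripping biology.
    """

    m: int = 2000
    n_types: int = 10
    n_collections: int = 20
    samples_per_collection: int = 10
    L: int = 5
    batch_loadings_scale: float = 1.0
    batch_score_scale: float = 1.0
    type_effect_scale: float = 2.0
    noise_sd: float = 0.5
    bio_within_scale: float = 0.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    shared_direction_mode: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 0:
            raise ValueError("L must be >= 0")
        if self.m < max(self.L, 2):
            raise ValueError(f"m = {self.m} must be >= max(L, 2)")
        if self.n_collections < 2:
            raise ValueError("need at least 2 collections")
        for name in ("batch_loadings_scale", "batch_score_scale",
                     "type_effect_scale", "noise_sd", "bio_within_scale",
                     "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_collections * self.samples_per_collection

    def batch_noise_ratio(self) -> float:
        """Per-gene batch-perturbation sd over noise sd."""
        batch_sd = (self.batch_loadings_scale * self.batch_score_scale
                    * np.sqrt(max(self.L, 1)))
        return float("inf") if self.noise_sd == 0 else batch_sd / self.noise_sd

    @classmethod
    def with_batch_to_noise(cls, ratio: float, **kwargs) -> "SyntheticConfig":
        """Config whose noise_sd is set to hit a given batch/noise ratio."""
        cfg = cls(**kwargs)
        batch_sd = (cfg.batch_loadings_scale * cfg.batch_score_scale
                    * np.sqrt(max(cfg.L, 1)))
        return cls(**{**asdict(cfg), "noise_sd": batch_sd / ratio})


@dataclass
class SyntheticTruth:
    """Planted ground truth: type means, loadings Gamma and scores g."""

    type_means: pd.DataFrame        # m x n_types
    gamma: np.ndarray               # m x L (shared mode) or m x (L*C)
    scores: np.ndarray              # L x n per-sample scores on gamma
    sample_types: np.ndarray
    collections: np.ndarray


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw one compendium: expression, annotation and planted truth.

    All samples of a collection share one score vector g (collection =
    batch); sample types are assigned round-robin within each collection
    so types are balanced across collections up to rounding. The same
    seed reproduces the dataset bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    m, n = cfg.m, cfg.n_samples
    probe_ids = np.array([f"probe_{i:05d}" for i in range(m)], dtype=object)
    sample_ids = np.array([f"S{j:05d}" for j in range(n)], dtype=object)
    type_labels = [f"type_{t:02d}" for t in range(cfg.n_types)]
    coll_labels = [f"GSE{c:04d}" for c in range(cfg.n_collections)]

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=m)
    type_effects = rng.normal(0.0, cfg.type_effect_scale, size=(m, cfg.n_types))
    type_means = pd.DataFrame(
        baseline[:, None] + type_effects,
        index=pd.Index(probe_ids, name="probe_id"), columns=type_labels,
    )

    collections = np.repeat(coll_labels, cfg.samples_per_collection)
    # round-robin with a per-collection offset so each type meets many batches
    sample_types = np.array([
        type_labels[(c * 3 + s) % cfg.n_types]
        for c in range(cfg.n_collections)
        for s in range(cfg.samples_per_collection)
    ], dtype=object)

    gamma_shared = rng.normal(0.0, cfg.batch_loadings_scale, size=(m, cfg.L))
    coll_scores = rng.normal(0.0, cfg.batch_score_scale,
                             size=(cfg.L, cfg.n_collections))
    if cfg.shared_direction_mode:
        gamma = gamma_shared
        batch = gamma @ coll_scores  # m x C, one perturbation per collection
    else:
        gamma = rng.normal(0.0, cfg.batch_loadings_scale,
                           size=(m, cfg.L * cfg.n_collections))
        batch = np.column_stack([
            gamma[:, c * cfg.L:(c + 1) * cfg.L] @ coll_scores[:, c]
            for c in range(cfg.n_collections)
        ])

    coll_index = {c: i for i, c in enumerate(coll_labels)}
    col_of_sample = np.array([coll_index[c] for c in collections])
    noise = rng.normal(0.0, cfg.noise_sd, size=(m, n))
    type_idx = {t: i for i, t in enumerate(type_labels)}
    t_of_sample = np.array([type_idx[t] for t in sample_types])
    values = (type_means.to_numpy()[:, t_of_sample]
              + batch[:, col_of_sample] + noise)
    if cfg.bio_within_scale > 0 and cfg.n_types > 1:
        # within-type biological scatter along the type-separating
        # directions: an orthonormal basis of the type-effect span
        bio_dirs, _ = np.linalg.qr(type_effects)
        xi = rng.normal(0.0, cfg.bio_within_scale,
                        size=(bio_dirs.shape[1], n))
        values = values + bio_dirs @ xi

    expr = ExpressionMatrix(probe_ids, sample_ids, values)
    ann = validate_annotation(pd.DataFrame({
        "sample_id": sample_ids,
        "sample_type": sample_types,
        "collection": collections,
    }))
    truth = SyntheticTruth(
        type_means=type_means,
        gamma=gamma,
        scores=coll_scores[:, col_of_sample],
        sample_types=sample_types,
        collections=np.asarray(collections, dtype=object),
    )
    return expr, ann, truth


def plant_biological_contrast(
    expr: ExpressionMatrix,
    truth: SyntheticTruth,
    n_de_genes: int,
    effect_size: float,
    orthogonal_to_batch: bool = True,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[str], np.ndarray]:
    """Add a two-group differential-expression contrast to a dataset.

    Samples are split into two balanced groups at random (independent of
    collection, so the contrast is not confounded with batch) and a
    contrast vector with ``effect_size`` on ``n_de_genes`` random genes is
    added with opposite halves (+v/2, -v/2) to the two groups. With
    ``orthogonal_to_batch`` the vector is first projected orthogonal to
    the planted batch loading span, so signature correction has no
    legitimate reason to touch it.

    Returns the modified matrix, the DE gene list and per-sample group
    labels ("g0"/"g1").
    """
    rng = np.random.default_rng(seed)
    m, n = expr.values.shape
    if n_de_genes > m:
        raise ValueError("n_de_genes exceeds the number of genes")
    de_idx = rng.choice(m, size=n_de_genes, replace=False)
    v = np.zeros(m)
    v[de_idx] = effect_size * rng.choice([-1.0, 1.0], size=n_de_genes)
    if orthogonal_to_batch and truth.gamma.shape[1] > 0 and effect_size != 0:
        Q, _ = np.linalg.qr(truth.gamma)
        v = v - Q @ (Q.T @ v)
        if np.linalg.norm(v) < 1e-6:
            raise ValueError(
                "orthogonalization against the batch span annihilated the "
                "contrast"
            )
    groups = np.array(["g0"] * n, dtype=object)
    flip = rng.permutation(n)[: n // 2]
    groups[flip] = "g1"
    values = expr.values.copy()
    sign = np.where(groups == "g1", 1.0, -1.0)
    values += np.outer(v / 2.0, sign)
    out = ExpressionMatrix(expr.probe_ids.copy(), expr.sample_ids.copy(), values)
    de_genes = [str(expr.probe_ids[i]) for i in sorted(de_idx)]
    return out, de_genes, groups
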