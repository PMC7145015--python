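import numpy as np
import pandas as pd
import pytest
from scipy import stats

from besc.data_model import ExpressionMatrix, validate_annotation
from besc.estimation import fit_bes_pipeline
from besc.correction import correct_matrix
from besc.evaluation import (
    _one_sided_from_null,
    correction_correlation,
    cross_validate_drs,
    de_count,
    drs,
    drs_pvalue,
    grouped_cv_split,
    permuted_null_bes,
)
from besc.synthetic import SyntheticConfig, generate_dataset


def _ann(types, batches):
    n = len(types)
    return validate_annotation(pd.DataFrame({
        "sample_id": [f"s{j}" for j in range(n)],
        "sample_type": types,
        "collection": batches,
    }))


def _points(coords):
    """Samples as 2-D points; Euclidean distances are the planar ones."""
    X = np.asarray(coords, dtype=float).T
    return ExpressionMatrix(["p0", "p1"],
                            [f"s{j}" for j in range(X.shape[1])], X)


def _brute_force_drs(values, types, batches):
    """Exhaustive all-pairs nearest-neighbor oracle for the score."""
    n = values.shape[1]
    scores = []
    for i in range(n):
        d = [np.sqrt(((values[:, i] - values[:, j]) ** 2).sum())
             for j in range(n)]
        dt = [d[j] for j in range(n) if types[j] != types[i]]
        db = [d[j] for j in range(n)
              if types[j] == types[i] and batches[j] != batches[i]]
        if not dt or not db:
            continue
        if min(dt) == 0 or min(db) == 0:
            continue
        scores.append(np.log2(min(dt) / min(db)))
    return float(np.mean(scores)), len(scores)


class TestDRS:
    def test_hand_computed_ratio(self):
        # s0: nearest different type at distance 4, nearest same-type
        # different-batch at distance 1 -> log2(4/1) = 2
        expr = _points([(0, 0), (4, 0), (1, 0), (4, 1)])
        ann = _ann(["A", "B", "A", "B"], ["b1", "b2", "b2", "b1"])
        res = drs(expr, ann)
        assert res.per_sample_score["s0"] == pytest.approx(2.0)

    def test_equal_distances_score_zero(self):
        expr = _points([(0, 0), (2, 0), (0, 2), (5, 5)])
        ann = _ann(["A", "B", "A", "B"], ["b1", "b1", "b2", "b2"])
        res = drs(expr, ann)
        assert res.per_sample_score["s0"] == pytest.approx(0.0)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(101)
        for _ in range(5):
            n = 40
            X = rng.normal(size=(6, n))
            types = rng.choice(["A", "B", "C"], size=n).tolist()
            batches = rng.choice(["b1", "b2", "b3", "b4"], size=n).tolist()
            expr = ExpressionMatrix([f"p{i}" for i in range(6)],
                                    [f"s{j}" for j in range(n)], X)
            res = drs(expr, _ann(types, batches))
            oracle_mean, oracle_n = _brute_force_drs(X, types, batches)
            assert res.n_evaluable == oracle_n
            assert res.mean_score == pytest.approx(oracle_mean, abs=1e-10)

    def test_zero_distance_sample_excluded(self):
        expr = _points([(0, 0), (0, 0), (3, 0), (0, 1)])
        ann = _ann(["A", "A", "B", "A"], ["b1", "b2", "b1", "b2"])
        res = drs(expr, ann)
        assert res.exclusion_reasons["s0"] == "zero distance"
        assert "s0" not in res.per_sample_score.index

    def test_sample_without_cross_batch_replicate_excluded(self):
        expr = _points([(0, 0), (1, 0), (2, 0), (3, 0)])
        ann = _ann(["A", "B", "B", "A"], ["b1", "b1", "b1", "b2"])
        res = drs(expr, ann)
        assert (res.exclusion_reasons["s1"]
                == "no same-type different-batch sample")

    def test_requires_two_types(self):
        expr = _points([(0, 0), (1, 0)])
        with pytest.raises(ValueError, match="2 sample types"):
            drs(expr, _ann(["A", "A"], ["b1", "b2"]))

    def test_invariant_to_label_renaming_and_rotation(self):
        rng = np.random.default_rng(102)
        X = rng.normal(size=(5, 24))
        types = rng.choice(["A", "B"], size=24).tolist()
        batches = rng.choice(["b1", "b2", "b3"], size=24).tolist()
        expr = ExpressionMatrix([f"p{i}" for i in range(5)],
                                [f"s{j}" for j in range(24)], X)
        base = drs(expr, _ann(types, batches)).mean_score
        renamed = drs(expr, _ann([t + "_x" for t in types],
                                 [b + "_y" for b in batches])).mean_score
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        rotated = ExpressionMatrix(expr.probe_ids, expr.sample_ids, Q @ X)
        rot = drs(rotated, _ann(types, batches)).mean_score
        assert renamed == pytest.approx(base)
        assert rot == pytest.approx(base, abs=1e-9)


class TestPermutedNull:
    def test_preserves_per_gene_multisets(self, small_synthetic):
        expr, ann, _ = small_synthetic
        # re-derive one permuted replicate the way the null fit does
        rng = np.random.default_rng(np.random.SeedSequence(5).spawn(1)[0])
        permuted = rng.permuted(expr.values, axis=1)
        for i in range(0, expr.n_probes, 97):
            assert sorted(permuted[i]) == pytest.approx(
                sorted(expr.values[i]))

    def test_same_seed_is_bit_identical(self, small_synthetic):
        expr, ann, _ = small_synthetic
        a = permuted_null_bes(expr, ann, k_max=3, n_perm=2, seed=9)
        b = permuted_null_bes(expr, ann, k_max=3, n_perm=2, seed=9)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.signatures, mb.signatures)

    def test_null_eigenvalues_far_below_true_with_planted_batch(
            self, small_synthetic):
        expr, ann, _ = small_synthetic
        true_model = fit_bes_pipeline(expr, ann, k_max=3)
        nulls = permuted_null_bes(expr, ann, k_max=3, n_perm=3, seed=1)
        for nm in nulls:
            assert nm.eigenvalues[0] < 0.5 * true_model.eigenvalues[0]


class TestOneSidedFromNull:
    def test_true_at_null_mean(self):
        z, p_norm, p_t = _one_sided_from_null(0.0, np.array([-1.0, 0.0, 1.0]))
        assert z == pytest.approx(0.0)
        assert p_norm == pytest.approx(0.5)
        assert p_t == pytest.approx(0.5)

    def test_three_sd_above_null(self):
        null = np.array([-1.0, 0.0, 1.0])  # mean 0, sd (ddof=1) = 1
        z, p_norm, _ = _one_sided_from_null(3.0, null)
        assert z == pytest.approx(3.0)
        assert p_norm == pytest.approx(stats.norm.sf(3.0), rel=1e-12)
        assert p_norm == pytest.approx(1.35e-3, rel=0.01)

    def test_degenerate_null_warns(self):
        with pytest.warns(RuntimeWarning, match="zero variance"):
            z, p_norm, p_t = _one_sided_from_null(1.0, np.zeros(5))
        assert p_norm == 0.0 and p_t == 0.0


class TestGroupedCVSplit:
    def test_five_equal_collections_exact_split(self):
        ann = _ann(["A"] * 10, [f"c{j % 5}" for j in range(10)])
        folds = grouped_cv_split(ann, n_folds=5, seed=0)
        assert sorted(np.bincount(folds)) == [2, 2, 2, 2, 2]

    def test_no_collection_straddles_folds(self):
        rng = np.random.default_rng(33)
        colls = rng.choice([f"c{j}" for j in range(20)], size=200).tolist()
        ann = _ann(rng.choice(["A", "B"], size=200).tolist(), colls)
        folds = grouped_cv_split(ann, n_folds=5, seed=1)
        table = pd.DataFrame({"c": ann["collection"], "f": folds})
        assert (table.groupby("c")["f"].nunique() == 1).all()

    def test_skewed_collection_sizes_stay_balanced(self):
        rng = np.random.default_rng(34)
        sizes = np.maximum(1, rng.lognormal(1.5, 1.0, size=348).astype(int))
        colls = [f"c{j}" for j, s in enumerate(sizes) for _ in range(s)]
        n = len(colls)
        ann = _ann(["A"] * n, colls)
        folds = grouped_cv_split(ann, n_folds=5, seed=2)
        fracs = np.bincount(folds, minlength=5) / n
        assert np.all(np.abs(fracs - 0.2) < 0.1)

    def test_fewer_collections_than_folds_is_an_error(self):
        ann = _ann(["A", "B"], ["c1", "c2"])
        with pytest.raises(ValueError, match="cannot fill"):
            grouped_cv_split(ann, n_folds=3)


@pytest.fixture(scope="module")
def cv_data():
    cfg = SyntheticConfig(m=300, n_types=5, n_collections=10,
                          samples_per_collection=6, L=3, noise_sd=0.4,
                          seed=5)
    return generate_dataset(cfg)


class TestCrossValidateDRS:
    def test_k_zero_equals_uncorrected_test_drs(self, cv_data):
        expr, ann, _ = cv_data
        curve = cross_validate_drs(expr, ann, [0, 3], n_folds=3, seed=4)
        folds = grouped_cv_split(ann, n_folds=3, seed=4)
        per_fold = []
        for f in range(3):
            mask = folds == f
            sub_ann = ann.loc[mask].reset_index(drop=True)
            sub = expr.subset_samples(sub_ann["sample_id"])
            per_fold.append(drs(sub, sub_ann).mean_score)
        assert curve[0] == pytest.approx(np.mean(per_fold))
        assert curve[3] > curve[0]  # correction helps on planted batch

    def test_relabeling_collections_preserves_results(self, cv_data):
        expr, ann, _ = cv_data
        curve = cross_validate_drs(expr, ann, [0, 3], n_folds=3, seed=4)
        renamed = ann.copy()
        renamed["collection"] = "x_" + renamed["collection"]
        renamed["batch"] = "x_" + renamed["batch"]
        curve2 = cross_validate_drs(expr, renamed, [0, 3], n_folds=3, seed=4)
        pd.testing.assert_series_equal(curve, curve2)


@pytest.fixture(scope="module")
def fitted_model(small_synthetic):
    expr, ann, _ = small_synthetic
    return fit_bes_pipeline(expr, ann, k_max=6)


class TestCorrectionCorrelation:
    def test_identical_models_correlate_perfectly(self, fitted_model):
        out = correction_correlation(fitted_model, fitted_model, [1, 3, 6],
                                     n_vectors=20, seed=0)
        assert np.allclose(out.to_numpy(), 1.0, atol=1e-10)

    def test_orthogonal_models_correlate_near_zero(self, fitted_model):
        model = fitted_model
        m = model.signatures.shape[0]
        rng = np.random.default_rng(55)
        D = model.signatures[:, :3]
        V = rng.normal(size=(m, 3))
        V -= D @ (D.T @ V)
        Q, _ = np.linalg.qr(V)
        other = type(model)(
            probe_ids=model.probe_ids.copy(), signatures=Q,
            eigenvalues=np.array([3.0, 2.0, 1.0]),
            reference_means=model.reference_means.copy(),
            zero_sum_enforced=False,
        )
        out = correction_correlation(model, other, [3], n_vectors=30, seed=1)
        assert abs(out[3]) < 3 / np.sqrt(m)

    def test_disjoint_reference_halves_agree_at_planted_rank(self):
        cfg = dict(m=400, n_types=6, n_collections=16,
                   samples_per_collection=6, L=3, noise_sd=0.4)
        expr, ann, _ = generate_dataset(SyntheticConfig(**cfg, seed=71))
        half = ann["collection"].isin(
            sorted(ann["collection"].unique())[:8])
        ann_a = ann.loc[half].reset_index(drop=True)
        ann_b = ann.loc[~half].reset_index(drop=True)
        model_a = fit_bes_pipeline(
            expr.subset_samples(ann_a["sample_id"]), ann_a, k_max=9)
        model_b = fit_bes_pipeline(
            expr.subset_samples(ann_b["sample_id"]), ann_b, k_max=9)
        out = correction_correlation(model_a, model_b, [3, 9],
                                     n_vectors=40, seed=2)
        assert out[3] > out[9]
        assert out[3] > 0.5


class TestDECount:
    def _noise_expr(self, rng, m=1000, n=40):
        return ExpressionMatrix([f"p{i}" for i in range(m)],
                                [f"s{j}" for j in range(n)],
                                rng.normal(8.0, 1.0, size=(m, n)))

    def test_pure_noise_yields_zero_counts(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            expr = self._noise_expr(rng)
            groups = ["g0"] * 20 + ["g1"] * 20
            if de_count(expr, groups) == 0:
                hits += 1
        assert hits >= 9  # a false positive slipping through once is fine

    def test_planted_effects_are_detected(self):
        rng = np.random.default_rng(77)
        expr = self._noise_expr(rng)
        groups = np.array(["g0"] * 20 + ["g1"] * 20)
        expr.values[:100, groups == "g1"] += 5.0  # 5 sigma on 100 genes
        assert de_count(expr, groups) >= 95

    def test_permuted_labels_behave_like_null(self):
        rng = np.random.default_rng(78)
        expr = self._noise_expr(rng)
        groups = np.array(["g0"] * 20 + ["g1"] * 20)
        expr.values[:100, groups == "g1"] += 5.0
        permuted = rng.permutation(groups)
        # label structure destroyed: the planted contrast should vanish
        assert de_count(expr, permuted) <= 5

    def test_confounded_design_is_an_error(self):
        rng = np.random.default_rng(79)
        expr = self._noise_expr(rng, m=50, n=8)
        groups = ["g0"] * 4 + ["g1"] * 4
        batches = ["b0"] * 4 + ["b1"] * 4
        with pytest.raises(ValueError, match="confounded"):
            de_count(expr, groups, covariate_labels=batches)


class TestDRSPvalue:
    def test_true_model_beats_null_on_planted_batch(self, small_synthetic):
        expr, ann, truth = small_synthetic
        # validation = a fresh draw sharing the planted directions is
        # exercised in the acceptance tests; here the reference itself
        # doubles as the evaluation set to keep the unit test fast
        true_model = fit_bes_pipeline(expr, ann, k_max=4)
        nulls = permuted_null_bes(expr, ann, k_max=4, n_perm=4, seed=3)
        res = drs_pvalue(expr, ann, true_model, nulls, [0, 4])
        assert res.true_drs[1] > res.true_drs[0]
        assert res.p_normal[1] < 0.05
        assert res.null_drs.shape == (4, 2)
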