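import math

import numpy as np
import pandas as pd
import pytest

from radsig import (
    DoseLabels,
    ExpressionMatrix,
    HyperParams,
    adjacent_error_fraction,
    confusion_matrix,
    goodness_of_fit,
    kfold_validate_signature,
    misclassification,
    multiclass_log_loss,
    quantile_normalize,
    stratified_kfold,
    traditional_validate,
)
from radsig.validation import internal_cv_score, null_predict, uniform_proba

from conftest import make_labels, make_matrix, mixed_direction_dataset, separable_dataset


class TestPointMetrics:
    def test_misclassification_arithmetic(self):
        true = make_labels([0, 0, 0, 0, 200, 200, 200, 200])
        pred = make_labels([0, 0, 0, 200, 200, 200, 200, 0])
        assert misclassification(true, pred) == 0.25
        assert misclassification(true, true) == 0.0
        flipped = make_labels([200, 200, 200, 200, 0, 0, 0, 0])
        assert misclassification(true, flipped) == 1.0

    def test_gof_arithmetic_and_symmetry(self):
        true = make_labels([0, 1000], samples=["a", "b"])
        pred = make_labels([50, 1000], samples=["a", "b"])
        assert goodness_of_fit(true, pred) == 25.0
        assert goodness_of_fit(pred, true) == 25.0
        assert goodness_of_fit(true, true) == 0.0

    def test_sample_set_mismatch_raises(self):
        with pytest.raises(ValueError):
            misclassification(make_labels([0, 200], samples=["a", "b"]),
                              make_labels([0, 200], samples=["a", "c"]))

    def test_gof_zero_iff_misclassification_zero(self, rng):
        # holds whenever the class dose values are distinct
        classes = np.array([0.0, 50.0, 200.0, 1000.0])
        true = make_labels(rng.choice(classes, 30))
        pred = make_labels(rng.choice(classes, 30))
        assert (goodness_of_fit(true, pred) == 0) == (
            misclassification(true, pred) == 0
        )
        assert goodness_of_fit(true, true) == 0 and misclassification(true, true) == 0


class TestLogLoss:
    def test_perfect_predictor_zero(self):
        true = make_labels([0, 200], samples=["a", "b"])
        proba = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"],
                             columns=[0.0, 200.0])
        assert multiclass_log_loss(true, proba) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_uniform_predictor_equals_ln_m(self, m):
        classes = [float(c) for c in range(m)]
        true = make_labels(classes, samples=[f"s{i}" for i in range(m)])
        proba = uniform_proba([f"s{i}" for i in range(m)], classes)
        assert multiclass_log_loss(true, proba) == math.log(m)

    def test_two_sample_worked_example(self):
        true = make_labels([0, 200], samples=["a", "b"])
        proba = pd.DataFrame([[0.8, 0.2], [0.5, 0.5]], index=["a", "b"],
                             columns=[0.0, 200.0])
        expected = -(math.log(0.8) + math.log(0.5)) / 2
        assert multiclass_log_loss(true, proba) == pytest.approx(expected, abs=1e-12)

    def test_unnormalized_rows_rejected(self):
        true = make_labels([0], samples=["a"])
        proba = pd.DataFrame([[0.7, 0.7]], index=["a"], columns=[0.0, 200.0])
        with pytest.raises(ValueError, match="sum to 1"):
            multiclass_log_loss(true, proba)


class TestStratifiedKfold:
    def test_round_robin_balanced(self):
        labels = make_labels([0] * 4 + [50] * 4 + [200] * 4)
        folds = stratified_kfold(labels, k=3, seed=0)
        sizes = [len(folds.fold_samples(f)) for f in (1, 2, 3)]
        assert sizes == [6, 3, 3] or sorted(sizes) == [3, 3, 6]
        for f in (1, 2, 3):
            fold_labels = labels.for_samples(folds.fold_samples(f))
            assert len(np.unique(fold_labels)) == 3  # every class present

    @pytest.mark.parametrize("n,k,seed", [(12, 3, 0), (20, 4, 1), (25, 5, 7),
                                          (40, 5, 42), (18, 2, 3)])
    def test_disjoint_covering_balanced(self, n, k, seed):
        rng = np.random.default_rng(seed)
        doses = np.repeat([0.0, 200.0], n // 2)
        labels = make_labels(rng.permutation(doses))
        folds = stratified_kfold(labels, k=k, seed=seed)
        all_samples = sorted(
            s for f in range(1, k + 1) for s in folds.fold_samples(f)
        )
        assert all_samples == sorted(labels.sample_ids)
        for cls in labels.classes:
            counts = []
            for f in range(1, k + 1):
                fl = labels.for_samples(folds.fold_samples(f))
                counts.append(int((fl == cls).sum()))
            assert max(counts) - min(counts) <= 1

    def test_class_smaller_than_k_raises(self):
        labels = make_labels([0, 0, 0, 200, 200])
        with pytest.raises(ValueError, match="smaller k"):
            stratified_kfold(labels, k=3, seed=0)

    def test_train_and_test_folds_disjoint(self):
        labels = make_labels([0] * 6 + [200] * 6)
        folds = stratified_kfold(labels, k=3, seed=9)
        for f in (1, 2, 3):
            assert not set(folds.fold_samples(f)) & set(folds.train_samples(f))


class TestInternalScore:
    def test_perfect_gene_zero_misclassification(self):
        mat, labels = separable_dataset(n_per_class=10, n_genes=1, gap=8.0)
        score = internal_cv_score(mat, labels, mat.row_ids,
                                  HyperParams(C=100, sigma=1),
                                  "misclassification", k=5, seed=0)
        assert score == 0.0

    def test_pure_noise_approaches_chance(self):
        # 2 balanced classes: misclassification ~ 0.5, log loss ~ ln 2
        mcs, lls = [], []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            mat = make_matrix(rng.standard_normal((3, 40)))
            labels = make_labels(np.repeat([0.0, 200.0], 20))
            params = HyperParams(C=10, sigma=1)
            mcs.append(internal_cv_score(mat, labels, mat.row_ids, params,
                                         "misclassification", 5, seed))
            lls.append(internal_cv_score(mat, labels, mat.row_ids, params,
                                         "log_loss", 5, seed))
        assert abs(np.mean(mcs) - 0.5) < 0.15
        assert abs(np.mean(lls) - math.log(2)) < 0.1

    def test_class_smaller_than_folds_raises(self):
        mat, labels = separable_dataset(n_per_class=3)
        with pytest.raises(ValueError, match="smaller k"):
            internal_cv_score(mat, labels, mat.row_ids,
                              HyperParams(C=1, sigma=1), "log_loss", 5, 0)


class TestKfoldValidation:
    def test_informative_signature_perfect(self):
        mat, labels = separable_dataset(n_per_class=10, gap=8.0)
        rep = kfold_validate_signature(mat, labels, mat.row_ids, k=5,
                                       params=HyperParams(C=100, sigma=1),
                                       repeats=3, seed=0)
        assert rep.misclassification == 0.0
        assert rep.misclassification_se == 0.0
        assert rep.goodness_of_fit == 0.0
        assert int(rep.confusion.to_numpy().sum()) == 20 * 3  # pooled repeats

    def test_pure_noise_signature_near_chance(self):
        # a single finite dataset can carry accidental structure, so the
        # uninformative limit is checked on the mean over dataset draws
        mcs, lls = [], []
        for ds_seed in (1, 2, 3):
            rng = np.random.default_rng(ds_seed)
            mat = make_matrix(rng.standard_normal((3, 60)))
            labels = make_labels(np.repeat([0.0, 200.0], 30))
            rep = kfold_validate_signature(mat, labels, mat.row_ids, k=5,
                                           params=HyperParams(C=10, sigma=1),
                                           repeats=7, seed=ds_seed)
            mcs.append(rep.misclassification)
            lls.append(rep.log_loss)
        assert abs(np.mean(mcs) - 0.5) < 0.15
        assert abs(np.mean(lls) - math.log(2)) < 0.1

    def test_repeats_floor(self):
        mat, labels = separable_dataset()
        with pytest.raises(ValueError, match="repeats"):
            kfold_validate_signature(mat, labels, mat.row_ids, repeats=1)

    def test_ineligible_signature_rejected(self):
        mat, labels = separable_dataset()
        with pytest.raises(KeyError, match="ghost"):
            kfold_validate_signature(mat, labels, mat.row_ids + ["ghost"],
                                     repeats=2)


class TestQuantileNormalize:
    def test_two_sample_worked_example(self):
        train = make_matrix(np.array([[1.0], [2.0], [3.0]]),
                            rows=["a", "b", "c"], cols=["s1"])
        test = make_matrix(np.array([[2.0], [4.0], [6.0]]),
                           rows=["a", "b", "c"], cols=["t1"])
        tr, te = quantile_normalize(train, test, ["a", "b", "c"])
        assert np.allclose(tr.values[:, 0], [1.5, 3.0, 4.5])
        assert np.allclose(te.values[:, 0], [1.5, 3.0, 4.5])

    def test_sorted_vectors_identical_across_samples(self, rng):
        train = make_matrix(rng.standard_normal((10, 6)))
        test = make_matrix(rng.standard_normal((10, 4)) * 3 + 1,
                           cols=[f"t{j}" for j in range(4)])
        tr, te = quantile_normalize(train, test, train.row_ids)
        pooled = np.concatenate([tr.values, te.values], axis=1)
        ref = np.sort(pooled[:, 0])
        for j in range(pooled.shape[1]):
            assert np.array_equal(np.sort(pooled[:, j]), ref)

    def test_idempotent(self, rng):
        train = make_matrix(rng.standard_normal((8, 5)))
        test = make_matrix(rng.standard_normal((8, 3)),
                           cols=[f"t{j}" for j in range(3)])
        tr1, te1 = quantile_normalize(train, test, train.row_ids)
        tr2, te2 = quantile_normalize(tr1, te1, train.row_ids)
        # idempotent up to one ulp (the reference is a mean of identical
        # sorted vectors, which floating summation reproduces to ~1e-16)
        assert np.allclose(tr1.values, tr2.values, atol=1e-12, rtol=0)
        assert np.allclose(te1.values, te2.values, atol=1e-12, rtol=0)

    def test_identical_sorted_values_fixed_point(self):
        vals = np.array([[1.0, 3.0], [2.0, 1.0], [3.0, 2.0]])
        train = make_matrix(vals[:, :1], rows=list("abc"), cols=["s1"])
        test = make_matrix(vals[:, 1:], rows=list("abc"), cols=["t1"])
        tr, te = quantile_normalize(train, test, list("abc"))
        assert np.array_equal(tr.values, vals[:, :1])
        assert np.array_equal(te.values, vals[:, 1:])

    def test_missing_gene_rejected(self, rng):
        train = make_matrix(rng.standard_normal((3, 2)), rows=list("abc"))
        test = make_matrix(rng.standard_normal((2, 2)), rows=list("ab"),
                           cols=["t0", "t1"])
        with pytest.raises(KeyError, match="test"):
            quantile_normalize(train, test, list("abc"))


class TestTraditionalValidation:
    def test_consistency_on_identical_distribution(self):
        # signature genes respond in both directions, so the class signal
        # survives per-sample quantile normalization
        train, labels = mixed_direction_dataset(n_per_class=10, seed=0)
        test, test_labels = mixed_direction_dataset(n_per_class=8, seed=99,
                                                    prefix="T")
        rep = traditional_validate(train, labels, test, test_labels,
                                   train.row_ids,
                                   params=HyperParams(C=100, sigma=1),
                                   repeats=2, seed=0)
        assert rep.misclassification == 0.0

    def test_disjoint_class_sets_rejected(self):
        train, tl = separable_dataset(classes=(0.0, 200.0))
        test, sl = separable_dataset(classes=(0.0, 1000.0), seed=5)
        test = ExpressionMatrix(test.data.rename(columns=lambda c: "T" + c))
        sl = DoseLabels(sl.series.rename(index=lambda c: "T" + c))
        with pytest.raises(ValueError, match="class sets"):
            traditional_validate(train, tl, test, sl, train.row_ids, repeats=2)


class TestConfusion:
    def test_perfect_diagonal_and_conservation(self):
        true = make_labels([0, 0, 50, 200, 1000, 1000])
        cm = confusion_matrix(true, true)
        assert np.array_equal(np.diag(cm.to_numpy()), [2, 1, 1, 2])
        assert cm.to_numpy().sum() == 6

    def test_row_sums_are_class_counts(self, rng):
        classes = np.array([0.0, 50.0, 200.0, 1000.0])
        true = make_labels(rng.choice(classes, 40))
        pred = make_labels(rng.choice(classes, 40))
        cm = confusion_matrix(true, pred, classes)
        for c in classes:
            assert cm.loc[c].sum() == (true.series == c).sum()

    def test_adjacency_statistic(self):
        # constructed: 4 errors, 3 adjacent (one step) and 1 two steps away
        counts = np.array(
            [[5, 1, 1, 0],
             [1, 5, 0, 0],
             [0, 0, 5, 1],
             [0, 0, 0, 5]]
        )
        cm = pd.DataFrame(counts, index=[0.0, 50.0, 200.0, 1000.0],
                          columns=[0.0, 50.0, 200.0, 1000.0])
        assert adjacent_error_fraction(cm) == 0.75

    def test_adjacency_undefined_without_errors(self):
        cm = pd.DataFrame(np.eye(3) * 4, index=[0., 50., 200.],
                          columns=[0., 50., 200.])
        assert math.isnan(adjacent_error_fraction(cm))


def test_null_predictor_contract():
    pred = null_predict(["a", "b"], [0.0, 50.0, 200.0])
    assert (pred.series == 0.0).all()
    proba = uniform_proba(["a", "b"], [0.0, 50.0, 200.0])
    assert np.allclose(proba.to_numpy(), 1 / 3)


def test_report_json_roundtrip(tmp_path):
    mat, labels = separable_dataset(n_per_class=10, gap=8.0)
    rep = kfold_validate_signature(mat, labels, mat.row_ids, k=2,
                                   params=HyperParams(C=10, sigma=1),
                                   repeats=2, seed=0, dataset_id="toy")
    out = tmp_path / "report.json"
    rep.to_json(out)
    import json

    loaded = json.loads(out.read_text())
    assert loaded["protocol"] == "kfold"
    assert loaded["dataset_id"] == "toy"
    assert loaded["misclassification"]["mean"] == rep.misclassification
    row = rep.tsv_row()
    assert row["n_repeats"] == 2 and row["protocol"] == "kfold"
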