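"""Fold plans, classifiers and the 5-fold x 25-resample protocol."""

import numpy as np
import pandas as pd
import pytest

from mammotex.classify import (
    audit_leakage,
    make_fold_plan,
    run_protocol,
    task_labels,
    train_fcnn,
    train_linear_svm,
)
from mammotex.evaluate import auc


def _cohort(n_patients, tumors_per_patient=1):
    rows = []
    t = 0
    for p in range(n_patients):
        for _ in range(tumors_per_patient):
            rows.append({"tumor_id": f"T{t}", "patient_id": f"P{p}"})
            t += 1
    return pd.DataFrame(rows)


class TestFoldPlan:
    def test_ten_patients_two_per_fold(self):
        plan = make_fold_plan(_cohort(10), seed=1)
        counts = pd.Series(plan.patient_fold).value_counts()
        assert (counts == 2).all()

    def test_patients_with_two_tumors_share_fold(self):
        cohort = _cohort(10, tumors_per_patient=2)
        plan = make_fold_plan(cohort, seed=2)
        fold_of_tumor = cohort["patient_id"].map(plan.patient_fold)
        grp = cohort.assign(f=fold_of_tumor).groupby("patient_id")["f"].nunique()
        assert (grp == 1).all()

    def test_hundred_patients_75_25_split(self):
        plan = make_fold_plan(_cohort(100), seed=3)
        train, val = plan.splits[0][0]
        assert len(train) + len(val) == 80  # 20 patients held out in fold 0
        assert abs(len(val) - 0.25 * 80) <= 1
        assert not (train & val)

    def test_deterministic_given_seed(self):
        a = make_fold_plan(_cohort(30), seed=9)
        b = make_fold_plan(_cohort(30), seed=9)
        assert a.patient_fold == b.patient_fold
        assert a.splits[2][13] == b.splits[2][13]

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            make_fold_plan(_cohort(4))


class TestLinearSvm:
    def test_separable_clouds_reach_auc_one(self, rng):
        X = pd.DataFrame(
            np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))]),
            columns=["a", "b"],
        )
        y = np.repeat([0, 1], 20)
        model = train_linear_svm(X, y)
        assert auc(model.scores(X), y) == 1.0

    def test_xor_is_linearly_inseparable(self, rng):
        base = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        X = pd.DataFrame(
            np.repeat(base, 20, axis=0) + rng.normal(0, 0.05, (80, 2)),
            columns=["a", "b"],
        )
        y = np.repeat([0, 1, 1, 0], 20)
        model = train_linear_svm(X, y)
        assert abs(auc(model.scores(X), y) - 0.5) < 0.2

    def test_1d_max_margin_solution(self):
        # support vectors at -1 and +1 -> w = 1, b = 0 in the hard-margin limit
        X = pd.DataFrame({"x": [-2.0, -1.0, 1.0, 2.0]})
        y = np.array([0, 0, 1, 1])
        model = train_linear_svm(X, y)
        w = float(model.estimator.coef_[0][0])
        b = float(model.estimator.intercept_[0])
        assert w == pytest.approx(1.0, rel=1e-3)
        assert b == pytest.approx(0.0, abs=1e-3)


class TestFcnn:
    def test_separable_toy_learns(self, rng):
        X = pd.DataFrame(
            np.vstack([rng.normal(-2, 0.4, (30, 3)), rng.normal(2, 0.4, (30, 3))]),
            columns=list("abc"),
        )
        y = np.repeat([0, 1], 30)
        model = train_fcnn(X, y, seed=0)
        assert auc(model.scores(X), y) > 0.95

    def test_architecture_is_five_hidden_layers(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        X.columns = [str(c) for c in X.columns]
        y = (rng.random(40) < 0.5).astype(int)
        model = train_fcnn(X, y, seed=1)
        assert model.estimator.hidden_layer_sizes == (50, 40, 30, 20, 10)

    def test_shuffled_labels_score_near_chance(self, rng):
        """Mean held-out AUC over 10 seeds stays within 0.5 +/- 0.1."""
        X = pd.DataFrame(rng.normal(size=(80, 5)))
        X.columns = [str(c) for c in X.columns]
        aucs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = r.permutation(np.repeat([0, 1], 40))
            model = train_fcnn(X.iloc[:60], y[:60], seed=seed)
            aucs.append(auc(model.scores(X.iloc[60:]), y[60:]))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_deterministic_given_seed(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        X.columns = [str(c) for c in X.columns]
        y = (rng.random(30) < 0.5).astype(int)
        a = train_fcnn(X, y, seed=11)
        b = train_fcnn(X, y, seed=11)
        assert np.array_equal(a.scores(X), b.scores(X))


class TestProtocol:
    def test_full_protocol_on_base_cohort(self, base_cohort):
        import warnings

        from mammotex.classify import make_fold_plan

        kept, feats = base_cohort["kept"], base_cohort["features"]
        plan = make_fold_plan(kept, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_protocol(
                feats, kept, "er", ("dce",), "relieff", "svm", plan, seed=5
            )
        assert len(res.folds) == 5
        for fold in res.folds:
            assert len(fold.val_aucs) == 25          # 25 candidates per fold
            assert len(fold.selected_features) == 32  # ReliefF keeps 32
            if fold.test_auc is not None:
                assert 0.0 <= fold.test_auc <= 1.0
        assert res.n_models_trained <= 125

    def test_best_model_is_validation_argmax(self, base_cohort):
        import warnings

        from mammotex.classify import make_fold_plan

        kept, feats = base_cohort["kept"], base_cohort["features"]
        plan = make_fold_plan(kept, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_protocol(
                feats, kept, "pr", ("dce",), "relieff", "svm", plan, seed=6
            )
        for fold in res.folds:
            arr = np.asarray(fold.val_aucs)
            if fold.best_split >= 0:
                assert fold.val_aucs[fold.best_split] == np.nanmax(arr)

    def test_leakage_audit_clean(self, base_cohort):
        import warnings

        from mammotex.classify import make_fold_plan

        kept, feats = base_cohort["kept"], base_cohort["features"]
        plan = make_fold_plan(kept, seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_protocol(
                feats, kept, "er", ("dce", "t2"), "relieff", "svm", plan, seed=7
            )
        assert audit_leakage(res, kept) == 0

    def test_missing_labels_dropped_per_task(self, base_cohort):
        kept = base_cohort["kept"]
        y = task_labels(kept, "er")
        n_missing = (kept["er"].astype(str) == "").sum()
        assert len(y) == len(kept) - n_missing
        assert set(y.unique()) <= {0, 1}
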