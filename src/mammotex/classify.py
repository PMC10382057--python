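"""Classifiers and the full cross-validation protocol.

The experimental design is patient-wise throughout: patients (not tumors)
are split into five folds; for each choice of test fold the remaining
patients are resampled 25 times into 75 % train / 25 % validation, one model
is trained per resample, the model with the best validation AUC is retained
(ties broken by the lowest split index), evaluated once on the held-out test
fold, and the test AUCs are averaged over the five fold choices.  Z-score
normalization and feature selection are refitted per test fold on the
train+validation rows only and frozen for the test rows.

Two model families are supported: a linear SVM with an effectively
unregularized margin (slack penalty C = 1e6) and a fully connected network
with hidden layers 50-40-30-20-10 (ReLU, sigmoid output, binary
cross-entropy, Adam with default parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .evaluate import auc
from .features.normalize import zscore_apply, zscore_fit
from .reduction import fit_reduction
from .synth import TASKS


class LeakageError(AssertionError):
    """A patient appeared on both sides of a train/test boundary."""


@dataclass
class FoldPlan:
    """Patient-level fold assignment plus the 25 train/val resamples per
    test fold."""

    patient_fold: Dict[str, int]
    # test fold index -> list of (train_patients, val_patients)
    splits: Dict[int, List[Tuple[frozenset, frozenset]]]
    n_folds: int
    n_splits: int
    seed: int

    def patients_in_fold(self, f: int) -> frozenset:
        return frozenset(p for p, ff in self.patient_fold.items() if ff == f)


def make_fold_plan(
    cohort: pd.DataFrame, n_folds: int = 5, n_splits: int = 25, seed: int = 0
) -> FoldPlan:
    """Randomly assign patients to folds and draw the 75/25 resamples.

    All tumors of a patient always share a fold.  Deterministic given seed.
    """
    patients = sorted(cohort["patient_id"].unique())
    if len(patients) < n_folds:
        raise ValueError(f"need at least {n_folds} patients, got {len(patients)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 91]))
    order = rng.permutation(len(patients))
    fold_of = {}
    chunks = np.array_split(order, n_folds)
    for f, chunk in enumerate(chunks):
        for j in chunk:
            fold_of[patients[j]] = f
    splits: Dict[int, List[Tuple[frozenset, frozenset]]] = {}
    for f in range(n_folds):
        rest = sorted(p for p in patients if fold_of[p] != f)
        per_fold = []
        for s in range(n_splits):
            r = np.random.default_rng(np.random.SeedSequence([seed, 7, f, s]))
            perm = r.permutation(len(rest))
            n_val = int(round(0.25 * len(rest)))
            n_val = min(max(n_val, 1), len(rest) - 1)
            val = frozenset(rest[j] for j in perm[:n_val])
            train = frozenset(rest[j] for j in perm[n_val:])
            per_fold.append((train, val))
        splits[f] = per_fold
    return FoldPlan(fold_of, splits, n_folds, n_splits, seed)


@dataclass
class TrainedModel:
    kind: str                             # "svm" | "fcnn"
    estimator: object
    feature_names: List[str]
    seed: Optional[int] = None

    def scores(self, X: pd.DataFrame) -> np.ndarray:
        Xa = X[self.feature_names].to_numpy()
        if self.kind == "svm":
            return self.estimator.decision_function(Xa)
        return self.estimator.predict_proba(Xa)[:, 1]


def train_linear_svm(X: pd.DataFrame, y: np.ndarray) -> TrainedModel:
    """Hard-margin-like linear SVM (C = 1e6 approximates no regularization)."""
    Xa = X.to_numpy()
    if not np.isfinite(Xa).all():
        raise ValueError("non-finite inputs")
    est = SVC(kernel="linear", C=1e6)
    est.fit(Xa, np.asarray(y))
    return TrainedModel("svm", est, list(X.columns))


def train_fcnn(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    max_epochs: int = 200,
    patience: int = 20,
) -> TrainedModel:
    """Five-hidden-layer fully connected net (50-40-30-20-10).

    ReLU activations, sigmoid output with binary cross-entropy, Adam with
    default parameters (lr 1e-3, betas 0.9/0.999); training stops when the
    loss plateaus for ``patience`` epochs or at the epoch budget.
    Deterministic given the seed.
    """
    Xa = X.to_numpy()
    if not np.isfinite(Xa).all():
        raise ValueError("non-finite inputs")
    est = MLPClassifier(
        hidden_layer_sizes=(50, 40, 30, 20, 10),
        activation="relu",
        solver="adam",
        alpha=0.0,
        learning_rate_init=1e-3,
        beta_1=0.9,
        beta_2=0.999,
        max_iter=max_epochs,
        n_iter_no_change=patience,
        tol=1e-4,
        random_state=int(seed) % (2**31),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at the budget
        est.fit(Xa, np.asarray(y))
    if not np.isfinite(est.loss_):
        raise FloatingPointError(f"divergent training loss: {est.loss_}")
    return TrainedModel("fcnn", est, list(X.columns), seed=seed)


@dataclass
class FoldOutcome:
    test_fold: int
    test_auc: Optional[float]
    val_aucs: List[float]                 # one per resample (nan if undefined)
    best_split: int
    selected_features: List[str]
    n_models_trained: int
    n_test: int
    audit: dict = field(default_factory=dict)


@dataclass
class ExperimentResult:
    task: str
    contrast_combo: Tuple[str, ...]
    reduction_method: str
    classifier_kind: str
    folds: List[FoldOutcome]
    seed: int

    @property
    def fold_aucs(self) -> List[Optional[float]]:
        return [f.test_auc for f in self.folds]

    @property
    def mean_test_auc(self) -> float:
        vals = [a for a in self.fold_aucs if a is not None]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def n_models_trained(self) -> int:
        return sum(f.n_models_trained for f in self.folds)

    @property
    def selections_per_fold(self) -> List[List[str]]:
        return [f.selected_features for f in self.folds]

    def to_record(self) -> dict:
        return {
            "task": self.task,
            "contrast_combo": list(self.contrast_combo),
            "reduction_method": self.reduction_method,
            "classifier_kind": self.classifier_kind,
            "fold_aucs": self.fold_aucs,
            "mean_test_auc": self.mean_test_auc,
            "n_models_trained": self.n_models_trained,
            "seed": self.seed,
        }


def task_labels(cohort: pd.DataFrame, task: str) -> pd.Series:
    """0/1 labels indexed by tumor_id; rows with a missing label dropped.

    The positive class (scored high) is '+' for the receptor tasks and ILC
    for the histotype task.
    """
    neg, pos = TASKS[task]
    raw = cohort.set_index("tumor_id")[task].astype(str)
    out = raw.map({pos: 1, neg: 0})
    return out.dropna().astype(int)


def _concat_combo(
    features: Dict[str, pd.DataFrame], combo: Sequence[str]
) -> pd.DataFrame:
    parts = []
    for c in combo:
        part = features[c].copy()
        part.columns = [f"{c}__{f}" for f in part.columns]
        parts.append(part)
    return pd.concat(parts, axis=1)


def _train_one(kind: str, X: pd.DataFrame, y: np.ndarray, seed: int) -> TrainedModel:
    if kind == "svm":
        return train_linear_svm(X, y)
    if kind == "fcnn":
        return train_fcnn(X, y, seed=seed)
    raise ValueError(f"unknown classifier kind: {kind}")


def run_protocol(
    features: Dict[str, pd.DataFrame],
    cohort: pd.DataFrame,
    task: str,
    contrast_combo: Sequence[str],
    reduction_method: str,
    classifier_kind: str,
    plan: FoldPlan,
    seed: int = 0,
    relieff_k: int = 10,
    relieff_n: int = 32,
    lasso_target_min: int = 100,
) -> ExperimentResult:
    """Run one experiment cell (task x contrast combo x method) end to end.

    ``features`` maps contrast -> raw (unnormalized) feature table indexed by
    tumor_id.  Patient-wise leakage guards are asserted at run time.
    """
    y_all = task_labels(cohort, task)
    patient_of = cohort.set_index("tumor_id")["patient_id"]
    X_raw = _concat_combo(features, contrast_combo)
    ids = [t for t in y_all.index if t in X_raw.index]
    y_all = y_all.loc[ids]
    X_raw = X_raw.loc[ids]

    outcomes: List[FoldOutcome] = []
    for f in range(plan.n_folds):
        test_patients = plan.patients_in_fold(f)
        is_test = patient_of.loc[ids].isin(test_patients).to_numpy()
        test_ids = [t for t, b in zip(ids, is_test) if b]
        tv_ids = [t for t, b in zip(ids, is_test) if not b]
        if set(patient_of.loc[test_ids]) & set(patient_of.loc[tv_ids]):
            raise LeakageError("patient in both test and train+validation")

        norm = zscore_fit(X_raw.loc[tv_ids])
        X_tv = zscore_apply(norm, X_raw.loc[tv_ids])
        red = fit_reduction(
            reduction_method,
            X_tv,
            y_all.loc[tv_ids].to_numpy(),
            relieff_k=relieff_k,
            relieff_n=relieff_n,
            lasso_target_min=lasso_target_min,
            fit_population=f"fold{f}_trainval",
        )

        val_aucs: List[float] = []
        models: List[Optional[TrainedModel]] = []
        n_trained = 0
        for s, (train_p, val_p) in enumerate(plan.splits[f]):
            if (train_p | val_p) & test_patients:
                raise LeakageError("resample overlaps the test fold")
            tr_ids = [t for t in tv_ids if patient_of[t] in train_p]
            va_ids = [t for t in tv_ids if patient_of[t] in val_p]
            y_tr = y_all.loc[tr_ids].to_numpy()
            y_va = y_all.loc[va_ids].to_numpy()
            if len(set(y_tr)) < 2 or len(set(y_va)) < 2:
                val_aucs.append(float("nan"))
                models.append(None)
                continue
            mseed = int(
                np.random.SeedSequence([seed, f, s]).generate_state(1)[0] % (2**31)
            )
            model = _train_one(
                classifier_kind, red.select(X_tv.loc[tr_ids]), y_tr, mseed
            )
            n_trained += 1
            val_aucs.append(auc(model.scores(red.select(X_tv.loc[va_ids])), y_va))
            models.append(model)

        arr = np.asarray(val_aucs, dtype=np.float64)
        if np.all(np.isnan(arr)):
            warnings.warn(f"fold {f}: no valid resample; fold skipped", stacklevel=2)
            outcomes.append(
                FoldOutcome(f, None, val_aucs, -1, red.feature_names, n_trained, len(test_ids))
            )
            continue
        best = int(np.nanargmax(arr))  # ties: lowest index via argmax semantics
        model = models[best]
        assert model is not None

        y_te = y_all.loc[test_ids].to_numpy()
        test_auc: Optional[float] = None
        if len(set(y_te)) < 2:
            warnings.warn(
                f"fold {f}: single-class test labels for {task}; AUC undefined",
                stacklevel=2,
            )
        else:
            X_te = zscore_apply(norm, X_raw.loc[test_ids])
            test_auc = auc(model.scores(red.select(X_te)), y_te)
        outcomes.append(
            FoldOutcome(
                f,
                test_auc,
                val_aucs,
                best,
                red.feature_names,
                n_trained,
                len(test_ids),
                audit={
                    "test_patients": sorted(test_patients),
                    "fit_tumors": list(tv_ids),
                    "test_tumors": list(test_ids),
                },
            )
        )
    return ExperimentResult(
        task, tuple(contrast_combo), reduction_method, classifier_kind, outcomes, seed
    )


def audit_leakage(result: ExperimentResult, cohort: pd.DataFrame) -> int:
    """Recheck patient-wise disjointness from the stored audit records.

    Returns the number of violations found (0 when the protocol is clean).
    """
    patient_of = cohort.set_index("tumor_id")["patient_id"]
    violations = 0
    for fold in result.folds:
        if not fold.audit:
            continue
        test_p = set(fold.audit["test_patients"])
        fit_p = set(patient_of.loc[fold.audit["fit_tumors"]])
        test_t_p = set(patient_of.loc[fold.audit["test_tumors"]])
        if fit_p & test_p:
            violations += 1
        if not test_t_p <= test_p:
            violations += 1
    return violations
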