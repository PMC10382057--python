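"""Dimension reduction: ReliefF (top-32) and relaxed LASSO (>100 features).

Both selectors are fitted on train+validation rows only; the resulting
ordered feature-name list is then applied to any other rows by name lookup,
so test labels never influence the selection.

ReliefF is the canonical multi-neighbor variant: for every sample, the k
nearest hits (same class) and k nearest misses (other class) under Euclidean
distance update each feature's weight by the mean absolute feature
difference to misses minus that to hits.

LASSO uses squared loss on ±1 labels along a decreasing penalty path; the
selected penalty is the largest one whose active set exceeds the target
count (a "relaxed" penalty keeping over a hundred features).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path


@dataclass
class ReductionResult:
    method: str                       # "relieff" | "lasso"
    feature_names: List[str]          # ordered by score, best first
    scores: List[float]               # ReliefF weight or |coefficient|
    fit_population: str = ""          # identifier of the fitting rows
    params: dict = field(default_factory=dict)

    def select(self, rows: pd.DataFrame) -> pd.DataFrame:
        """Apply the frozen selection to any feature table by name."""
        return rows[self.feature_names]

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "method": self.method,
                    "feature_names": self.feature_names,
                    "scores": self.scores,
                    "fit_population": self.fit_population,
                    "params": self.params,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: Path) -> "ReductionResult":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**doc)


def relieff_weights(X: np.ndarray, y: np.ndarray, k_neighbors: int = 10) -> np.ndarray:
    """Canonical ReliefF feature weights.

    Iterates over every row; ties in neighbor distance are broken by row
    index for determinism.  Feature differences are used unscaled (inputs
    are expected to be z-scored already).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n, p = X.shape
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("ReliefF here requires exactly two classes")
    min_class = min(int((y == c).sum()) for c in classes)
    k = k_neighbors
    if min_class - 1 < k:
        k = max(1, min_class - 1)
        warnings.warn(
            f"class with {min_class} members: k_neighbors reduced to {k}",
            stacklevel=2,
        )
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    w = np.zeros(p)
    for i in range(n):
        same = (y == y[i]).nonzero()[0]
        same = same[same != i]
        other = (y != y[i]).nonzero()[0]
        hits = same[np.argsort(d2[i, same], kind="stable")[:k]]
        misses = other[np.argsort(d2[i, other], kind="stable")[:k]]
        w += np.abs(X[misses] - X[i]).sum(axis=0) / (n * k)
        w -= np.abs(X[hits] - X[i]).sum(axis=0) / (n * k)
    return w


def relieff(
    X: pd.DataFrame,
    y: np.ndarray,
    k_neighbors: int = 10,
    n_select: int = 32,
    fit_population: str = "",
) -> ReductionResult:
    """Select the ``n_select`` highest-weight features (ties: table order)."""
    if X.isna().to_numpy().any():
        raise ValueError("missing values in feature table")
    w = relieff_weights(X.to_numpy(), np.asarray(y), k_neighbors)
    order = np.argsort(-w, kind="stable")[: min(n_select, X.shape[1])]
    return ReductionResult(
        method="relieff",
        feature_names=[X.columns[j] for j in order],
        scores=[float(w[j]) for j in order],
        fit_population=fit_population,
        params={"k_neighbors": int(k_neighbors), "n_select": int(n_select)},
    )


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray,
    target_min: int = 100,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-3,
    fit_population: str = "",
) -> ReductionResult:
    """Largest penalty whose LASSO active set exceeds ``target_min`` features.

    ``y`` is taken as ±1 regression targets (squared loss).  If even the
    smallest penalty on the path activates no more than ``target_min``
    features (e.g. p <= target_min), all features are returned with a
    warning.
    """
    if X.isna().to_numpy().any():
        raise ValueError("missing values in feature table")
    Xa = X.to_numpy()
    ya = np.asarray(y, dtype=np.float64)
    n = len(ya)
    alpha_max = float(np.max(np.abs(Xa.T @ ya)) / n)
    if alpha_max <= 0:
        alpha_max = 1.0
    alphas = np.logspace(
        np.log10(alpha_max), np.log10(alpha_max * alpha_min_ratio), n_alphas
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter at tiny alphas
        alphas_out, coefs, _ = lasso_path(Xa, ya, alphas=alphas, tol=1e-6)
    active_sizes = (np.abs(coefs) > 0).sum(axis=0)
    ok = np.nonzero(active_sizes > target_min)[0]
    if ok.size == 0:
        warnings.warn(
            f"no penalty keeps more than {target_min} features; returning all",
            stacklevel=2,
        )
        coef = coefs[:, -1]
        chosen_alpha = float(alphas_out[-1])
        names = list(X.columns)
        scores = np.abs(coef)
    else:
        j = int(ok[0])  # path is in decreasing alpha: first hit = largest
        coef = coefs[:, j]
        chosen_alpha = float(alphas_out[j])
        active = np.nonzero(np.abs(coef) > 0)[0]
        order = active[np.argsort(-np.abs(coef[active]), kind="stable")]
        names = [X.columns[a] for a in order]
        scores = np.abs(coef[order])
    return ReductionResult(
        method="lasso",
        feature_names=list(names),
        scores=[float(s) for s in scores],
        fit_population=fit_population,
        params={"alpha": chosen_alpha, "target_min": int(target_min)},
    )


def fit_reduction(
    method: str,
    X: pd.DataFrame,
    y: np.ndarray,
    relieff_k: int = 10,
    relieff_n: int = 32,
    lasso_target_min: int = 100,
    fit_population: str = "",
) -> ReductionResult:
    if method == "relieff":
        return relieff(X, y, relieff_k, relieff_n, fit_population)
    if method == "lasso":
        return lasso_select(X, y, lasso_target_min, fit_population=fit_population)
    raise ValueError(f"unknown reduction method: {method}")
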