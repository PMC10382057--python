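"""AUROC computation and report tables.

AUC is the probability that a random positive outranks a random negative:
the Mann–Whitney U statistic divided by n+·n−, with ties counted 1/2.  The
positive class is scored high (ER+/PR+/HER2+/ILC), so an AUC below 0.5 is a
real finding, never silently flipped.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import CONTRAST_COMBOS, combo_name


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUROC; labels are 0/1 (or False/True)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite scores")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def result_table(
    results: Iterable, value: str = "mean_test_auc"
) -> pd.DataFrame:
    """Pivot experiment results into the tasks x contrast-combo layout.

    Rows: (task, methodology); columns: DCE, SUB, T2, DCE+SUB, DCE+T2,
    SUB+T2, DCE+SUB+T2.
    """
    cols = [combo_name(c) for c in CONTRAST_COMBOS]
    rows: Dict[tuple, Dict[str, float]] = {}
    for r in results:
        key = (r.task, f"{r.reduction_method}+{r.classifier_kind}")
        rows.setdefault(key, {})[combo_name(r.contrast_combo)] = getattr(r, value)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.reindex(columns=[c for c in cols if c in table.columns])
    table.index = pd.MultiIndex.from_tuples(table.index, names=["task", "method"])
    return table.sort_index()


def category_summary(selected_features: Sequence[str], inventory) -> Dict[str, int]:
    """Count selected features per inventory category (contrast prefixes like
    ``dce__`` are stripped before lookup).  Counts sum to the selection size."""
    counts = {c: 0 for c in inventory.category_names()}
    for name in selected_features:
        base = name.split("__", 1)[-1]
        counts[inventory.categories[base]] += 1
    return counts


def feature_stability(selections_per_fold: Sequence[Sequence[str]]) -> pd.Series:
    """Per-feature selection frequency across folds, plus use
    ``(freq >= 0.8).mean()`` externally for the headline stability number."""
    if len(selections_per_fold) < 2:
        raise ValueError("need at least two fold selections")
    n = len(selections_per_fold)
    all_names: List[str] = sorted({f for sel in selections_per_fold for f in sel})
    freq = {
        name: sum(name in set(sel) for sel in selections_per_fold) / n
        for name in all_names
    }
    return pd.Series(freq).sort_values(ascending=False)
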