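"""End-to-end orchestration: cohort -> features -> experiments -> reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .classify import ExperimentResult, FoldPlan, make_fold_plan, run_protocol
from .evaluate import result_table
from .features import FeatureConfig, extract_cohort_features
from .preprocess import apply_exclusions
from .synth import load_cohort
from .types import CONTRASTS, CONTRAST_COMBOS


def features_by_contrast(long_table: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Split the long (tumor x contrast) feature table into per-contrast
    tables indexed by tumor_id."""
    out = {}
    for c in CONTRASTS:
        sub = long_table[long_table["contrast"] == c]
        out[c] = sub.drop(columns=["contrast"]).set_index("tumor_id")
    return out


def prepare_cohort(
    cohort_dir: Path,
    min_size_mm: float = 5.0,
    size_window: Optional[Tuple[float, float]] = None,
    config: FeatureConfig = FeatureConfig(),
) -> Tuple[pd.DataFrame, Dict[str, pd.DataFrame], pd.DataFrame]:
    """Load, filter and featurize a cohort directory.

    Masks are smoothed first and tumor sizes recomputed from the smoothed
    masks before the exclusion rules run (masks destroyed by the smoothing —
    tiny or thread-like lesions — are logged as excluded).  Returns
    (included cohort table, per-contrast feature tables, exclusion log).
    """
    from .preprocess import smooth_mask, tumor_size_mm
    from .types import DegenerateMaskError, load_mask

    cohort = load_cohort(cohort_dir)
    cohort_dir = Path(cohort_dir)
    degenerate = []
    sizes = []
    for row in cohort.itertuples(index=False):
        try:
            m = smooth_mask(load_mask(cohort_dir / row.mask_path))
            sizes.append(tumor_size_mm(m))
        except DegenerateMaskError:
            degenerate.append(row.tumor_id)
            sizes.append(float("nan"))
    cohort = cohort.assign(size_mm=sizes)
    ok = ~cohort["tumor_id"].isin(degenerate)
    kept, log = apply_exclusions(cohort[ok].reset_index(drop=True), min_size_mm, size_window)
    log = pd.concat(
        [
            pd.DataFrame({"tumor_id": degenerate, "reason": "degenerate mask"}),
            log,
        ],
        ignore_index=True,
    )
    feats = extract_cohort_features(kept, cohort_dir, config=config)
    return kept, features_by_contrast(feats), log


def run_experiment_grid(
    cohort: pd.DataFrame,
    features: Dict[str, pd.DataFrame],
    tasks: Sequence[str] = ("er", "pr", "her2", "histotype"),
    combos: Sequence[Sequence[str]] = CONTRAST_COMBOS,
    reductions: Sequence[str] = ("relieff", "lasso"),
    classifiers: Sequence[str] = ("svm", "fcnn"),
    n_folds: int = 5,
    n_splits: int = 25,
    seed: int = 0,
    plan: Optional[FoldPlan] = None,
) -> List[ExperimentResult]:
    """Run every cell of the experiment grid under one shared fold plan."""
    plan = plan or make_fold_plan(cohort, n_folds, n_splits, seed)
    results = []
    for task in tasks:
        for combo in combos:
            for red in reductions:
                for clf in classifiers:
                    results.append(
                        run_protocol(
                            features, cohort, task, tuple(combo), red, clf,
                            plan, seed=seed,
                        )
                    )
    return results


def save_results(results: Sequence[ExperimentResult], out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "experiments.json", "w") as fh:
        json.dump([r.to_record() for r in results], fh, indent=1)
    table = result_table(results)
    table.to_csv(out_dir / "test_auc_table.csv", float_format="%.4f")
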