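"""Z-score normalization fitted on the train+validation rows only.

The fitted parameters are frozen and applied unchanged to train, validation
and test rows, so no test statistics leak into the scaling.  Zero-variance
features map to 0 and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd


@dataclass
class NormalizationParams:
    mean: pd.Series
    sd: pd.Series
    zero_sd_features: List[str] = field(default_factory=list)


def zscore_fit(table: pd.DataFrame) -> NormalizationParams:
    """Estimate per-feature mean/SD (population SD) from the given rows."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows to fit normalization")
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=0)
    zero = sd.index[sd <= 0].tolist()
    return NormalizationParams(mean=mean, sd=sd, zero_sd_features=zero)


def zscore_apply(params: NormalizationParams, rows: pd.DataFrame) -> pd.DataFrame:
    """Apply frozen parameters; zero-SD features become exactly 0."""
    rows = rows[params.mean.index]
    sd = params.sd.replace(0.0, np.nan)
    out = (rows - params.mean) / sd
    return out.fillna(0.0)
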