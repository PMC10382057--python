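import warnings

import numpy as np
import pytest

from mammotex.pipeline import prepare_cohort
from mammotex.synth import generate_cohort


@pytest.fixture(scope="session")
def base_cohort(tmp_path_factory):
    """One shared null-effect phantom cohort with extracted features."""
    d = tmp_path_factory.mktemp("cohort_base")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = generate_cohort(40, d, seed=101)
        kept, feats, log = prepare_cohort(d)
    return {"dir": d, "table": table, "kept": kept, "features": feats, "log": log}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
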