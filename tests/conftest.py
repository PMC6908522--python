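import numpy as np
import pandas as pd
import pytest

from coexmeta.datatypes import ExpressionStudy


def make_study(values, groups, study_id="S1", disease_class="LC", scale="glog2",
               features=None, samples=None):
    """Small ExpressionStudy from a plain array and group list."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    features = features or [f"g{i}" for i in range(m)]
    samples = samples or [f"s{j}" for j in range(n)]
    return ExpressionStudy(
        study_id=study_id,
        disease_class=disease_class,
        values=pd.DataFrame(values, index=features, columns=samples),
        group=pd.Series(groups, index=samples),
        scale=scale,
    )


@pytest.fixture
def tiny_study():
    """3 genes x 4 samples, groups 2/2, glog2 scale."""
    return make_study(
        [[1.0, 1.2, 3.0, 3.1],
         [2.0, 2.1, 2.0, 1.9],
         [5.0, 4.8, 1.0, 1.2]],
        ["control", "control", "case", "case"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
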