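import dataclasses

import numpy as np
import pandas as pd
import pytest

from mgrade import pipeline, simulate
from mgrade.datatypes import ExpressionMatrix


@pytest.fixture(scope="session")
def default_cohort():
    """The canonical fixture: n=400, 2000 genes, 30+30 signal, effect 1.5, HR 3."""
    return simulate.generate_cohort(simulate.DEFAULT_SPEC)


@pytest.fixture(scope="session")
def trained(default_cohort):
    """Full pipeline (DE -> GGI scan -> elimination -> final model) on the fixture."""
    return pipeline.train_pipeline(default_cohort.expr, default_cohort.clin, seed=0)


@pytest.fixture(scope="session")
def heldout_cohort():
    """Freshly simulated held-out cohort from the same generating process."""
    return simulate.generate_cohort(
        dataclasses.replace(simulate.DEFAULT_SPEC, n_samples=200, seed=90210)
    )


@pytest.fixture()
def tiny_expr():
    """3 genes x 2 samples with one missing value."""
    df = pd.DataFrame(
        [[1.5, 2.0], [np.nan, 0.25], [-3.0, 7.5]],
        index=["gA", "gB", "gC"],
        columns=["S1", "S2"],
    )
    return ExpressionMatrix(df)


def small_spec(**overrides):
    base = dataclasses.replace(
        simulate.DEFAULT_SPEC, n_samples=200, n_genes=100, n_signal_up=10, n_signal_down=10
    )
    return dataclasses.replace(base, **overrides)
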