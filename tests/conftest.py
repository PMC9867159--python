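import numpy as np
import pytest

import thermoselect as ts


@pytest.fixture(scope="session")
def geometry():
    return ts.FootGeometry(60, 36)


@pytest.fixture(scope="session")
def class_table():
    return ts.default_class_table()


@pytest.fixture(scope="session")
def small_cohort(geometry):
    """12 healthy + 16 diabetic subjects (imbalanced on purpose)."""
    return ts.make_cohort(12, 16, geometry=geometry, seed=11)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    return ts.extract_feature_table(small_cohort)


@pytest.fixture(scope="session")
def signal_tabular():
    """Strong-signal tabular benchmark: 5 informative of 30, effect 2."""
    df, informative = ts.make_tabular(
        ts.TabularSpec(n_per_class=100, n_features=30, n_informative=5, effect_size=2.0, seed=21)
    )
    return df, informative


def informative_names(informative):
    return {f"f{j:03d}" for j in sorted(informative)}
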