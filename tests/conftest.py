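import numpy as np
import pandas as pd
import pytest

from lateview.containers import CohortMeta, FeatureTable
from lateview.synthetic import CohortSpec, ViewSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]],
        index=["s1", "s2"],
        columns=["a", "b", "c", "d"],
    )
    return FeatureTable(values=values, modality="intensity", name="toy")


@pytest.fixture
def toy_meta():
    outcomes = pd.Series({f"S{i:02d}": 1 if i < 6 else 0 for i in range(15)})
    return CohortMeta.from_subjects(outcomes, visits=["baseline", "6M"])


@pytest.fixture(scope="session")
def tiny_cohort():
    """39-subject two-view single-visit cohort with moderate signal."""
    views = [
        ViewSpec("genus", "counts", 30, 4, effect_size=2.0, zero_frac=0.1),
        ViewSpec("imm", "npx", 20, 4, effect_size=2.0),
    ]
    spec = CohortSpec(
        n_subjects=39, n_positive=15, visits=["v0"], view_specs=views, seed=5
    )
    tables, meta = generate_cohort(spec)
    return tables, meta, spec
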