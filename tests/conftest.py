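import numpy as np
import pandas as pd
import pytest

import bodyatlas as ba


@pytest.fixture(scope="session")
def small_cohort():
    """500-participant default-structure cohort, generated once per session."""
    return ba.generate_cohort(ba.CohortConfig(n_participants=500, seed=11))


@pytest.fixture(scope="session")
def clean_small(small_cohort):
    table, report = ba.filter_missing(small_cohort.to_measure_table())
    return table, report


def make_table(values, heights=None, genders=None, kinds=None):
    """Assemble a MeasureTable from a plain array (helper for unit tests)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    idx = pd.Index([f"p{i}" for i in range(n)])
    cols = [f"m{j}" for j in range(p)]
    cov = pd.DataFrame(
        {
            "gender": genders if genders is not None else ["F", "M"] * (n // 2) + ["F"] * (n % 2),
            "age": np.linspace(40, 79, n),
            "height": heights if heights is not None else np.full(n, 170.0),
        },
        index=idx,
    )
    kind = pd.Series(kinds, index=cols) if kinds is not None else None
    return ba.MeasureTable(
        values=pd.DataFrame(values, index=idx, columns=cols),
        covariates=cov,
        measure_kind=kind,
    )
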