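import numpy as np
import pandas as pd
import pytest

import nonhdlrisk as nr


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Prepared synthetic cohort, n=8000 (shared across tests; do not mutate)."""
    cfg = nr.default_config(n_subjects=8000, seed=42)
    return nr.prepare_cohort(nr.generate_cohort(cfg))


@pytest.fixture(scope="session")
def midsize_cohort() -> pd.DataFrame:
    """Prepared synthetic cohort, n=40000, for model-fitting tests."""
    cfg = nr.default_config(n_subjects=40_000, seed=7)
    return nr.prepare_cohort(nr.generate_cohort(cfg))


def toy_records(times, causes, **cols) -> pd.DataFrame:
    """Minimal record table for survival-estimator unit tests."""
    n = len(times)
    base = {
        "subject_id": np.arange(n),
        "cohort_id": np.zeros(n, dtype=int),
        "sex": np.array(["female"] * n),
        "age_baseline": np.full(n, 50.0),
        "followup_years": np.asarray(times, dtype=float),
        "event_cause": np.asarray(causes, dtype=int),
    }
    base.update(cols)
    return pd.DataFrame(base)
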