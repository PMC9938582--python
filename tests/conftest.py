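import numpy as np
import pandas as pd
import pytest

import glycoresponse as gr


@pytest.fixture(scope="session")
def small_cohort():
    """88-patient cohort with a planted response effect on GP6."""
    cfg = gr.SimulationConfig(planted_orr_effects={"GP6": 1.0})
    return gr.simulate_cohort(cfg, seed=101)


@pytest.fixture(scope="session")
def null_cohort():
    """88-patient cohort with no planted effects."""
    return gr.simulate_cohort(gr.SimulationConfig(), seed=202)


@pytest.fixture(scope="session")
def preprocessed(small_cohort):
    pre = small_cohort.peaks[small_cohort.peaks.days_from_ici_start <= 0]
    g = gr.preprocess_chain(pre)
    values = g.values.set_axis(g.meta.loc[g.values.index, "patient_id"], axis=0)
    clinical = small_cohort.clinical.set_index("patient_id", drop=False)
    return values, clinical


def make_peak_table(areas: np.ndarray, batch=None, days=None) -> pd.DataFrame:
    """Wrap a raw area matrix in the canonical long-table layout."""
    n, p = areas.shape
    df = pd.DataFrame(areas, columns=[f"GP{i}" for i in range(1, p + 1)])
    df.insert(0, "days_from_ici_start", days if days is not None else 0)
    df.insert(0, "batch", batch if batch is not None else "B1")
    df.insert(0, "patient_id", [f"P{i:04d}" for i in range(1, n + 1)])
    df.insert(0, "sample_id", [f"S{i:04d}" for i in range(1, n + 1)])
    return df
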