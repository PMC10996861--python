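import numpy as np
import pandas as pd
import pytest

from cppscreen import CohortSpec, apply_windowing, select_nprime, synth_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """24-speaker cohort with short CPP streams (fast evaluation tests)."""
    return synth_cohort(CohortSpec(samples_per_speaker=(12, 30), seed=7))


@pytest.fixture(scope="session")
def small_windowed(small_cohort):
    return apply_windowing(small_cohort, select_nprime(small_cohort.counts))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_fold(n_sms: int, n_n: int, seed: int = 0) -> pd.DataFrame:
    """A windowed-table slice with the given class counts (7 CPP features)."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, count, mean in (("SMS", n_sms, 0.03), ("N", n_n, 0.05)):
        for i in range(count):
            row = {"Name": f"{label}{i // 10 + 1}.{i % 10 + 1}"}
            row.update({f"CPP{j + 1}": mean + 0.004 * rng.standard_normal() for j in range(7)})
            row.update({"Target": label, "Sex": "female", "Group": "young"})
            rows.append(row)
    return pd.DataFrame(rows)
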