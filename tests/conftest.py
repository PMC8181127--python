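import numpy as np
import pandas as pd
import pytest

from tpemet.io_config import TrialTable


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trial_frame(
    n_sites: int = 3,
    n_reps: int = 2,
    n_genos: int = 5,
    year: int = 2010,
    seed: int = 0,
) -> pd.DataFrame:
    """Small complete trial table: one sub-block per rep, no checks."""
    r = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        for rep in range(1, n_reps + 1):
            for g in range(n_genos):
                rows.append(
                    {
                        "cycle_year": year,
                        "site_id": f"S{s + 1}",
                        "group_label": "1",
                        "group_kind": "TPE",
                        "replicate": rep,
                        "sub_block": 1,
                        "genotype_id": f"G{g + 1}",
                        "is_local_check": False,
                        "grain_yield": 4.0 + 0.2 * g + r.normal(0, 0.3),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture()
def small_trials() -> TrialTable:
    return TrialTable(make_trial_frame())


@pytest.fixture()
def small_trials_csv(tmp_path, small_trials):
    path = tmp_path / "trials.csv"
    small_trials.to_csv(path)
    return path
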