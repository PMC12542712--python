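import warnings

import numpy as np
import pandas as pd
import pytest

import distprev as dp

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_config():
    """A small but non-trivial nested design used across unit tests."""
    return dp.SimConfig(n_states=4, districts_per_state=3,
                        clusters_per_district=4, mean_persons_per_cluster=20,
                        seed=42)


@pytest.fixture(scope="session")
def small_fit(small_config):
    """One fitted model on a small synthetic survey, shared across tests."""
    frame = dp.generate_frame(small_config)
    eff = dp.draw_random_effects(frame, small_config)
    persons = dp.simulate_individuals(frame, eff, small_config)
    table, _ = dp.build_outcome_table(persons, "hypertension")
    data = dp.ModelData.from_table(table)
    draws = dp.gibbs_fit(data, dp.MCMCConfig(burn_in=300, monitoring=1500,
                                             seed=7))
    return persons, table, draws


def make_outcome_table(status, cluster_id, district_id=0, state_id=0,
                       weight=None):
    """Hand-build a classified outcome table for direct sampler/estimator use."""
    n = len(status)
    return pd.DataFrame({
        "person_id": np.arange(n),
        "wave": 1,
        "state_id": np.resize(state_id, n),
        "district_id": np.resize(district_id, n),
        "cluster_id": np.resize(cluster_id, n),
        "sex": "female",
        "weight": np.ones(n) if weight is None else np.asarray(weight, float),
        "outcome": "hypertension",
        "status": np.asarray(status, int),
    })
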