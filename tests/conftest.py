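import numpy as np
import pandas as pd
import pytest

from sevmir.differential import classify_compartments, differential_test
from sevmir.synthetic_data import (
    SimulationConfig,
    generate_sequences_with_motif,
    simulate_count_experiment,
    simulate_interaction_tables,
)


@pytest.fixture(scope="session")
def small_config():
    """A fast default study configuration used across module tests."""
    return SimulationConfig(seed=11, n_mirnas=200)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """Sequences, counts, interaction tables and truth for one seed."""
    seqs, truth = generate_sequences_with_motif(small_config)
    counts, count_truth = simulate_count_experiment(
        small_config, carriers=truth.carrier_ids, mirna_ids=seqs.ids()
    )
    truth.true_log2fc = count_truth.true_log2fc
    rbp_table, mrna_table, markers = simulate_interaction_tables(
        small_config, truth, mirna_ids=seqs.ids()
    )
    return {
        "sequences": seqs,
        "counts": counts,
        "rbp": rbp_table,
        "mrna": mrna_table,
        "markers": markers,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def classified_diff(small_bundle):
    return classify_compartments(differential_test(small_bundle["counts"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_counts():
    """A hand-sized count matrix with both conditions and two replicates."""
    counts = pd.DataFrame(
        {
            "c1": [100, 50, 10, 200, 7],
            "c2": [110, 45, 12, 190, 9],
            "s1": [400, 52, 11, 210, 30],
            "s2": [380, 48, 13, 205, 28],
        },
        index=[f"m{i}" for i in range(1, 6)],
    )
    meta = pd.DataFrame(
        {
            "condition": ["cell", "cell", "sev", "sev"],
            "cell_line": ["L1", "L1", "L1", "L1"],
        },
        index=["c1", "c2", "s1", "s2"],
    )
    from sevmir.io_formats import CountMatrix

    return CountMatrix(counts=counts, sample_meta=meta)
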