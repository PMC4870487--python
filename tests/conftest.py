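import numpy as np
import pandas as pd
import pytest

from methylotype import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic dataset shared across read-only tests."""
    cfg = SimConfig(n_probes=1200, n_tumor_dm_probes=100,
                    n_methylator_probes=100, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture
def tiny_beta():
    """4 probes x 4 samples with exact decimal values."""
    return pd.DataFrame(
        [[0.10, 0.90, 0.50, 0.40],
         [0.20, 0.80, 0.60, 0.30],
         [0.05, 0.95, 0.55, 0.45],
         [0.15, 0.85, 0.65, 0.35]],
        index=pd.Index([f"cg{i}" for i in range(4)], name="probe_id"),
        columns=["s1", "s2", "s3", "s4"])


@pytest.fixture
def tiny_annotation():
    return pd.DataFrame({
        "gene_symbol": ["G1", "G2", "G3", "G4"],
        "region_category": ["Promoter", "TSS1500", "Body", "UTR3"],
        "cpg_class": ["island", "shore", "poor", "island"],
        "prc2_target": [True, False, False, True],
        "known_snp": [False, True, False, False],
    }, index=pd.Index([f"cg{i}" for i in range(4)], name="probe_id"))
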