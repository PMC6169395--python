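import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import spudgwas as sg

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_panel() -> sg.DosagePanel:
    """5 markers x 4 samples, hand-written, with one missing call."""
    vals = np.array(
        [
            [0, 1, 2, 3],
            [4, 4, 4, 4],
            [0, 4, np.nan, 2],
            [2, 2, 2, 2],
            [0, 0, 4, 4],
        ],
        dtype=float,
    )
    return sg.DosagePanel.from_values(
        [f"m{i}" for i in range(5)], ["s0", "s1", "s2", "s3"], vals
    )


@pytest.fixture(scope="session")
def sim_small() -> sg.SimPanel:
    """Small family-structured panel with a planted QTL, reused across tests."""
    cfg = sg.SimConfig(
        n_founders=12,
        n_samples=60,
        n_subpops=2,
        fst=0.1,
        n_chrom=3,
        markers_per_chrom=80,
        chrom_length_mb=50.0,
        offspring_per_family=6,
        traits=[
            sg.TraitSpec("qtl_trait", qtl=[(30, 1.3)], h2_polygenic=0.3),
            sg.TraitSpec("noise", residual_sd=1.0),
        ],
        missing_rate=0.02,
        seed=42,
    )
    return sg.simulate_panel(cfg)


@pytest.fixture(scope="session")
def sim_unrelated() -> sg.SimPanel:
    """Founders-only single-subpopulation panel (no kinship, no structure)."""
    cfg = sg.SimConfig(
        n_founders=80,
        n_samples=80,
        n_subpops=1,
        families=[],
        n_chrom=3,
        markers_per_chrom=100,
        chrom_length_mb=50.0,
        traits=[sg.TraitSpec("noise", residual_sd=1.0)],
        seed=7,
    )
    return sg.simulate_panel(cfg)
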