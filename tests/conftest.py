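import numpy as np
import pandas as pd
import pytest

from stresspheno.synthetic import (
    MotifGenSpec,
    PhysioGenSpec,
    UnitGenSpec,
    gen_motif_sequences,
    gen_physio_cohort,
    gen_units,
)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return gen_physio_cohort(PhysioGenSpec(seed=7))


@pytest.fixture(scope="session")
def small_units():
    """Small separated unit ensemble (fast; ground truth attached)."""
    spec = UnitGenSpec(n_msn=40, n_interneuron=10, duration_s=120.0, seed=11)
    return gen_units(spec)


@pytest.fixture(scope="session")
def block_motif_spec() -> MotifGenSpec:
    """12 motifs in 3 communities of 4, strong block structure."""
    partition = {m: m // 4 for m in range(12)}
    return MotifGenSpec(
        n_motifs=12,
        partition=partition,
        within_weight=1.0,
        between_weight=0.05,
        self_persistence=0.5,
        frames=10_000,
        n_mice=1,
        seed=3,
    )


@pytest.fixture(scope="session")
def block_motif_seqs(block_motif_spec):
    return gen_motif_sequences(block_motif_spec)
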