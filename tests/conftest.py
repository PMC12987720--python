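import numpy as np
import pytest

from pleioscan.simulate import LDBlockSpec, TraitArchitecture, simulate_ld_block


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_block():
    """A 25-variant AR(1) LD block with its allele frequencies."""
    spec = LDBlockSpec(n_variants=25, ar1_lambda=0.9, chrom=2,
                       base_pos=10_000_000, spacing_bp=50_000)
    return simulate_ld_block(spec, seed=42)


@pytest.fixture
def default_architecture():
    """Two line groups: discovery-only (slope 0) and shared (slope 0.43)."""
    return TraitArchitecture()
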