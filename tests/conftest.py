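import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))   # make oracles importable

from primatesplice.simulate import SimConfig, simulate_expression, simulate_reference


@pytest.fixture(scope="session")
def default_sim():
    """Default recovery fixture: 300 genes, all event classes planted,
    3-replicate main design plus a 6-replicate draw for usage analyses."""
    cfg = SimConfig(seed=1)
    ref = simulate_reference(cfg)
    expr = simulate_expression(ref)
    expr_usage = simulate_expression(ref, n_replicates=6)
    return ref, expr, expr_usage


@pytest.fixture(scope="session")
def null_sim():
    """Fixture with no planted events (type-I error surface)."""
    cfg = SimConfig(
        seed=2, n_gain=0, n_gain_canonicity=0, n_ss_exon=0, n_diu=0,
        n_deu=0, n_rank_switch=0, n_novel_peptide=0,
    )
    ref = simulate_reference(cfg)
    expr = simulate_expression(ref)
    return ref, expr


@pytest.fixture(scope="session")
def small_sim():
    """Small fixture for fast structural/unit checks."""
    cfg = SimConfig(
        seed=7, n_genes=40, n_gain=5, n_gain_canonicity=2, n_ss_exon=3,
        n_diu=4, n_deu=4, n_rank_switch=2, n_novel_peptide=2,
    )
    ref = simulate_reference(cfg)
    expr = simulate_expression(ref)
    return ref, expr


@pytest.fixture
def smoke_dir():
    return Path(__file__).parent / "data" / "smoke"
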