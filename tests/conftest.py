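import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated world shared across tests (4 strains, 12-domain
    pool, default event rates)."""
    from rhskit.simulate import SimulationConfig, simulate_strains

    cfg = SimulationConfig(n_strains=4, pool_size=12, n_decoy_orfs=5, seed=11)
    strains, truth = simulate_strains(cfg)
    return cfg, strains, truth


@pytest.fixture(scope="session")
def quiet_sim():
    """A simulation with no stochastic gene events (no pseudogenes, no
    orphan-immunity, no HGT) for exact-coordinate comparisons."""
    from rhskit.simulate import SimulationConfig, simulate_strains

    cfg = SimulationConfig(
        n_strains=3, pool_size=10, n_decoy_orfs=5, seed=7,
        p_pseudogenize=0.0, p_orphan_immunity=0.0, p_hgt=0.0,
        p_toxinless=0.0, p_n_truncated=0.0, p_t6ss_loss=0.0,
    )
    strains, truth = simulate_strains(cfg)
    return cfg, strains, truth


@pytest.fixture(scope="session")
def orphan_world():
    """A world with frequent orphan-immunity events (toxin lost, immunity
    kept) and no other gene events."""
    from rhskit.simulate import SimulationConfig, simulate_strains

    cfg = SimulationConfig(
        n_strains=3, pool_size=14, n_decoy_orfs=5, seed=21,
        p_orphan_immunity=0.5, p_pseudogenize=0.0, p_hgt=0.0,
        loci_per_strain_range=(2, 3), orphans_per_locus_range=(1, 2),
    )
    return simulate_strains(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def truth_toxins(truth, strain_id=None):
    """Truth rows for Rhs toxin genes with boolean columns cast."""
    g = truth.genes
    t = g[g.kind == "rhs_toxin"].copy()
    if strain_id is not None:
        t = t[t.strain_id == strain_id]
    for col in ("pseudogene", "short_control", "has_paar", "hgt"):
        t[col] = t[col].astype(bool)
    return t
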