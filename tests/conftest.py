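import pytest

from genemobility.simulator import FocalFamily, SimConfig, simulate_pangenome


@pytest.fixture(scope="session")
def small_clade():
    """Eight-tip clade with one mobile and one vertical focal family."""
    return simulate_pangenome(SimConfig(
        n_taxa=8, n_core_genes=30, subst_rate=0.02, seed=101,
        focal_families=[FocalFamily("mobile", hgt_rate=0.5),
                        FocalFamily("vertical", hgt_rate=0.0)]))


@pytest.fixture(scope="session")
def plain_genome():
    """One annotated ~45 kb genome with no focal families."""
    return simulate_pangenome(
        SimConfig(n_taxa=3, n_core_genes=40, seed=7)).assemblies[0]
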