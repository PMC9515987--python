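import numpy as np
import pytest

from inbredqtl import (
    assemble_panel,
    compute_kinship,
    inject_missingness,
    make_map,
    simulate_classic_subpanel,
    simulate_ri_subpanel,
)
from inbredqtl.panel import draw_founder_haplotypes


@pytest.fixture(scope="session")
def small_map():
    """5 chromosomes x 120 SNPs, 100 cM / 100 Mb each."""
    return make_map(5, 120, seed=11)


@pytest.fixture(scope="session")
def mixed_panel(small_map):
    """43-strain panel: 30 RI strains + 13 divergent classic inbreds,
    with 2% missing genotype calls."""
    founders = draw_founder_haplotypes(small_map, 2, seed=21)
    ri = simulate_ri_subpanel(
        small_map, 30, founders[0], founders[1], seed=22, subpopulation="RI1"
    )
    classic = simulate_classic_subpanel(small_map, 13, seed=23)
    return inject_missingness(assemble_panel(ri, classic), 0.02, seed=24)


@pytest.fixture(scope="session")
def complete_panel(small_map):
    """Same structure, no missing data."""
    founders = draw_founder_haplotypes(small_map, 2, seed=31)
    ri = simulate_ri_subpanel(
        small_map, 30, founders[0], founders[1], seed=32, subpopulation="RI1"
    )
    classic = simulate_classic_subpanel(small_map, 13, seed=33)
    return assemble_panel(ri, classic)


@pytest.fixture(scope="session")
def large_panel():
    """92-strain subpopulation-design panel: 33 + 30 RI strains from two
    founder pairs plus 29 classic inbreds; 5 chromosomes x 300 SNPs."""
    m = make_map(5, 300, seed=41)
    f1 = draw_founder_haplotypes(m, 2, seed=42)
    f2 = draw_founder_haplotypes(m, 2, seed=43)
    ri1 = simulate_ri_subpanel(m, 33, f1[0], f1[1], seed=44, subpopulation="RI1")
    ri2 = simulate_ri_subpanel(m, 30, f2[0], f2[1], seed=45, subpopulation="RI2")
    classic = simulate_classic_subpanel(m, 29, seed=46)
    return assemble_panel(ri1, ri2, classic)


@pytest.fixture(scope="session")
def mixed_kinship(mixed_panel):
    return compute_kinship(mixed_panel)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
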