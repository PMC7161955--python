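import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from iespipe import (  # noqa: E402
    SimulationConfig,
    assign_retention,
    build_junction_library,
    generate_genome_pair,
    neighbor_density,
    simulate_read_pairs,
)
from iespipe.types import IesAnnotation  # noqa: E402


@pytest.fixture()
def toy_junction():
    """The hand-checkable single-IES toy locus.

    MAC carries TA at p=5; inserting the IES gives the germline with one TA
    left of the IES core and the MAC's own TA to its right.
    """
    mac = {"chr": "CCCCCTAGGGGG"}
    ann = IesAnnotation("ies1", "chr", 5, "TAAAAT")
    germ = {"chr": mac["chr"][:5] + ann.sequence + mac["chr"][5:]}
    assert germ["chr"] == "CCCCCTAAAATTAGGGGG"
    return mac, germ, [ann]


@pytest.fixture(scope="session")
def small_instance():
    """A small but realistic simulated instance shared across tests."""
    cfg = SimulationConfig(replicon_length=20_000, n_ies=30, rng_seed=7)
    mac, germ, anns = generate_genome_pair(cfg)
    dens = neighbor_density(anns)
    truth = assign_retention(anns, dens, "uniform", 3, r=0.5, rho=0.5)
    reads = simulate_read_pairs(mac, germ, anns, truth, coverage=40, rng_seed=11)
    library = build_junction_library(mac, germ, anns)
    return {
        "config": cfg,
        "mac": mac,
        "germ": germ,
        "annotations": anns,
        "densities": dens,
        "truth": truth,
        "reads": reads,
        "library": library,
    }
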