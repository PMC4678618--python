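import numpy as np
import pytest

from mobilome import simulate as sim


@pytest.fixture(scope="session")
def small_genome():
    """Two mariner-style families (40 + 20 copies) in 300 kb with N-runs and
    two segmental duplications — shared across mining/simulator tests."""
    rng = np.random.default_rng(2)
    specs = []
    for fi, (n, sub) in enumerate([(40, "subA"), (20, "subB")]):
        anc, tir, orf = sim.make_ancestor(rng, f"fam{fi}", length=1300 + 5 * fi)
        specs.append(sim.FamilySpec(f"fam{fi}", sub, anc, tir, target_copies=n,
                                    dynamics_model="E", dynamics_params={"T": 0.06},
                                    orf_interval=orf))
    genome = sim.plant_genome(specs, 300_000, contig_count=2,
                              extras={"n_run_prob": 0.1, "segdup_count": 2},
                              rng_seed=9)
    return genome, specs


@pytest.fixture(scope="session")
def small_queries(small_genome):
    _genome, specs = small_genome
    rng = np.random.default_rng(3)
    return [sim.family_query_protein(s, rng) for s in specs]


@pytest.fixture(scope="session")
def mined_small(small_genome, small_queries):
    from mobilome import mine

    genome, _specs = small_genome
    return mine.mine_genome(genome.contigs, small_queries)


@pytest.fixture(scope="session")
def mite_fixture():
    return sim.build_mite_fixture(11)
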