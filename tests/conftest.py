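import numpy as np
import pytest

from uvhotspots.genome import ReferenceGenome
from uvhotspots.simulate import (
    SimulationConfig,
    generate_reference,
    simulate_tumors,
)


def make_random_genome(seed: int, length: int, gc: float = 0.5, name: str = "chr1"):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return ReferenceGenome({name: seq})


@pytest.fixture(scope="session")
def small_sim():
    """400 kb single-chromosome cohort in the linear (probability) regime."""
    cfg = SimulationConfig(
        seed=5,
        n_chromosomes=1,
        chromosome_length=400_000,
        n_genes=30,
        motifs_per_tier=6,
        load_range=(50, 2000),
    )
    bundle = generate_reference(cfg)
    ss, truth = simulate_tumors(cfg, bundle)
    return cfg, bundle, ss, truth


@pytest.fixture(scope="session")
def hotspot_sim():
    """400 kb cohort with heavy loads so individual positions recur often."""
    cfg = SimulationConfig(
        seed=9,
        n_chromosomes=1,
        chromosome_length=400_000,
        n_genes=30,
        motifs_per_tier=6,
        load_range=(200, 20_000),
    )
    bundle = generate_reference(cfg)
    ss, truth = simulate_tumors(cfg, bundle)
    return cfg, bundle, ss, truth


@pytest.fixture(scope="session")
def null_sim():
    """400 kb cohort without any motif vulnerability (f = 1)."""
    cfg = SimulationConfig(
        seed=13,
        n_chromosomes=1,
        chromosome_length=400_000,
        n_genes=30,
        motifs_per_tier=6,
        load_range=(50, 2000),
        vulnerability_factor=1.0,
        central_factor=1.0,
        cc_tt_rate=0.0,
    )
    bundle = generate_reference(cfg)
    ss, truth = simulate_tumors(cfg, bundle)
    return cfg, bundle, ss, truth
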