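import numpy as np
import pytest

from kelppop.alignment import Alignment
from kelppop.simulate import (
    PartitionSpec,
    RecombinantSpec,
    SimulationConfig,
    simulate_two_lineages,
)


@pytest.fixture(scope="session")
def default_sim():
    """The default two-lineage multilocus simulation (17 vs 8 samples)."""
    return simulate_two_lineages(SimulationConfig(seed=101))


@pytest.fixture()
def recomb_sim():
    """Factory: single-region two-lineage simulation with one spliced
    recombinant at known breakpoints."""

    def make(seed=0, length=1788, divergence=0.12, pi=0.002,
             begin=760, end=1650, n=4, post_noise=0.002):
        cfg = SimulationConfig(
            partitions=[PartitionSpec("COI", length, divergence, pi)],
            n_a=n, n_b=n, fixed_indels=[],
            recombinants=[RecombinantSpec("A", "B", "COI", begin, end,
                                          post_noise=post_noise, label="REC1")],
            seed=seed,
        )
        return simulate_two_lineages(cfg)

    return make


@pytest.fixture()
def random_alignment():
    """Factory: random ACGT alignment with optional missing states."""

    def make(rng, n, length, missing_rate=0.0):
        codes = rng.integers(0, 4, size=(n, length))
        chars = np.array(list("ACGT"))
        rows = []
        for i in range(n):
            row = chars[codes[i]].copy()
            if missing_rate > 0:
                mask = rng.random(length) < missing_rate
                gap_or_n = rng.random(length) < 0.5
                row[mask & gap_or_n] = "-"
                row[mask & ~gap_or_n] = "N"
            rows.append("".join(row))
        return Alignment([f"s{i:02d}" for i in range(n)], rows)

    return make
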