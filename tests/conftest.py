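import numpy as np
import pytest

from sammyseq import (
    Genome,
    IntervalSet,
    calls_to_intervals,
    call_domains,
    make_architecture,
    simulate_fraction_reads,
)

TOY_SIZES = {"chr1": 30_000_000, "chr2": 30_000_000}


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    return Genome.from_dict(TOY_SIZES)


@pytest.fixture(scope="session")
def default_arch():
    """The default study architecture: 10 planted domains of 1-5 Mb,
    S4/S2 contrast factor 3, on 2 x 30 Mb."""
    return make_architecture(TOY_SIZES, n_domains=10,
                             size_range=(1_000_000, 5_000_000),
                             enrichment_factor=3.0, seed=7)


@pytest.fixture(scope="session")
def default_reads(default_arch):
    """1 M reads per fraction at the default contrast."""
    return {
        "S2": simulate_fraction_reads(default_arch, "S2", 1_000_000, seed=1),
        "S4": simulate_fraction_reads(default_arch, "S4", 1_000_000, seed=2),
    }


@pytest.fixture(scope="session")
def default_calls(default_arch, default_reads):
    """Full-depth S4-vs-S2 domain calls at the default caller settings."""
    return call_domains(
        default_reads["S4"], default_reads["S2"], default_arch.genome,
        bin_size=10_000, gap_penalty=25.0, fdr=0.05,
        n_permutations=1000, seed=3,
    )


@pytest.fixture(scope="session")
def default_call_set(default_calls) -> IntervalSet:
    return calls_to_intervals(default_calls)


def random_interval_set(rng: np.random.Generator, genome: Genome,
                        n: int, max_len: int) -> IntervalSet:
    """Random (possibly overlapping) interval set within genome bounds."""
    tuples = []
    for _ in range(n):
        ci = rng.integers(len(genome.chroms))
        chrom, clen = genome.chroms[ci], genome.lengths[ci]
        length = int(rng.integers(1, max_len + 1))
        length = min(length, clen)
        start = int(rng.integers(0, clen - length + 1))
        tuples.append((chrom, start, start + length))
    return IntervalSet.from_tuples(tuples)
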