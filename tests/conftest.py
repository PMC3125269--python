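import numpy as np
import pytest

from beskit.io import BESRead, End
from beskit.simulate import SimConfig, simulate_bes, simulate_genomes


def make_read(bases: str, read_id: str = "cloneX_T7", quals=None, mask=()) -> BESRead:
    clone, _, end = read_id.rpartition("_")
    return BESRead(read_id=read_id, clone_id=clone,
                   end=End.FORWARD if end == "T7" else End.REVERSE,
                   bases=bases, quals=quals, mask=list(mask))


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture(scope="session")
def small_world():
    """A compact simulated survey reused across end-to-end tests."""
    cfg = SimConfig(seed=11, genome_len=400_000, n_chromosomes=2, n_clones=150,
                    insert_range=(30_000, 60_000), repeat_target_fraction=0.25,
                    rearrangement_rate=8.0, rearrangement_seg_range=(20_000, 60_000))
    source, reference, registry = simulate_genomes(cfg)
    reads = simulate_bes(cfg, source, registry)
    return cfg, source, reference, registry, reads
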