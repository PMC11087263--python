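import numpy as np
import pytest

from splinkmap import DEFAULT_PRIMERS, ToyGenome
from splinkmap._seq import revcomp


@pytest.fixture
def primers():
    return DEFAULT_PRIMERS


def make_ttaa_free(length: int, seed: int = 0) -> str:
    """Random DNA guaranteed to contain no TTAA (alphabet A/C/G only)."""
    rng = np.random.default_rng(seed)
    return "".join("ACG"[i] for i in rng.integers(0, 3, size=length))


def plant_ttaa(backbone: str, positions: list[int]) -> str:
    """Overwrite TTAA at each position of a TTAA-free backbone."""
    s = list(backbone)
    for p in positions:
        s[p : p + 4] = "TTAA"
    return "".join(s)


@pytest.fixture
def clean_genome():
    """One 2.5 kb contig whose only TTAAs sit at 5 known, well-spaced spots."""
    positions = [350, 750, 1150, 1550, 1950]
    seq = plant_ttaa(make_ttaa_free(2500, seed=3), positions)
    return ToyGenome(contigs=(("chr1", seq),)), positions


def brute_force_placements(read: str, genome: ToyGenome, max_mismatch: int):
    """Independent aligner oracle: scan every position on both strands.

    Returns the set of equally best placements as (contig, start, strand,
    mismatches) tuples, empty when nothing is within max_mismatch.
    """
    hits = {}
    for strand, s in (("+", read), ("-", revcomp(read))):
        for name, seq in genome.contigs:
            for start in range(len(seq) - len(s) + 1):
                mm = sum(a != b for a, b in zip(seq[start : start + len(s)], s))
                if mm <= max_mismatch:
                    hits[(name, start, strand)] = mm
    if not hits:
        return set()
    best = min(hits.values())
    return {(n, st, sd, mm) for (n, st, sd), mm in hits.items() if mm == best}
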