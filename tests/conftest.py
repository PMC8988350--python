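import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hypoximmune as hx

settings.register_profile(
    "package",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture
def toy_genome():
    return hx.GenomeModel({"chrA": 10_000, "chrB": 5_000})


@pytest.fixture
def mb_genome():
    return hx.GenomeModel({"chrA": 1_000_000})


def random_interval_collection(rng, genome, n, max_len=200):
    """Helper: n random valid intervals on the genome (may overlap)."""
    chroms = list(genome.entries)
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        clen = genome.entries[chrom]
        length = int(rng.integers(1, min(max_len, clen) + 1))
        start = int(rng.integers(0, clen - length + 1))
        out.append(hx.GenomicInterval(chrom, start, start + length))
    return hx.IntervalCollection(out, genome=genome)


def brute_force_overlap_count(sites, peaks, count_pairs=False):
    """All-pairs double-loop oracle for overlap counting."""
    if count_pairs:
        return sum(1 for s in sites for p in peaks if s.overlaps(p))
    return sum(1 for s in sites if any(s.overlaps(p) for p in peaks))


def naive_scan_positions(sequence, iupac):
    """Naive O(n*m) sliding-window oracle for plus-strand motif matching."""
    from hypoximmune.motifs import IUPAC_SETS

    seq = sequence.upper()
    m = len(iupac)
    return [
        i
        for i in range(len(seq) - m + 1)
        if all(seq[i + k] in IUPAC_SETS[sym] for k, sym in enumerate(iupac))
    ]
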