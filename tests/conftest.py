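import numpy as np
import pytest

from methmap import DEFAULT_ENZYMES, MethylomeTrack


@pytest.fixture
def enzymes():
    return DEFAULT_ENZYMES


def make_track(entries):
    """Build a track from (chrom, pos, strand, mark) tuples."""
    t = MethylomeTrack()
    for chrom, pos, strand, mark in entries:
        t.add(chrom, pos, strand, mark)
    return t


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def random_track(rng: np.random.Generator, seq: str, n_marks: int,
                 chrom: str = "chr1") -> MethylomeTrack:
    """Marks placed only on cytosines of the stated strand."""
    t = MethylomeTrack()
    c_pos = [i for i, b in enumerate(seq) if b == "C"]
    g_pos = [i for i, b in enumerate(seq) if b == "G"]
    used = set()
    for _ in range(n_marks):
        if rng.random() < 0.5 and c_pos:
            pos, strand = int(rng.choice(c_pos)), "+"
        elif g_pos:
            pos, strand = int(rng.choice(g_pos)), "-"
        else:
            continue
        if (pos, strand) in used:
            continue
        used.add((pos, strand))
        t.add(chrom, pos, strand, "5mC" if rng.random() < 0.5 else "5hmC")
    return t
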