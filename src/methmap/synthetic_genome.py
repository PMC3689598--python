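"""Synthetic genomes with a known cytosine methylome.

Generates reproducible toy genomes carrying the feature classes the three
restriction-based profiling chemistries interact with — genes with
exons/introns, CpG islands, tandem satellite arrays and interspersed
SINE/LINE/LTR-like elements — plus a per-cytosine ground-truth mark track
(none / 5mC / 5hmC) drawn from context-specific probabilities. The track is
the simulation ground truth against which site recovery is scored.

Coordinates are 0-based, half-open throughout; GFF3 conversion happens only
in the writer.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

MARK_5MC = "5mC"
MARK_5HMC = "5hmC"
MARKS = (MARK_5MC, MARK_5HMC)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PlacementError(RuntimeError):
    """Raised when a requested feature cannot be placed on the genome."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene span with exons; intron structure is implied by the gaps."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first
        transcribed base, strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class FeatureInterval:
    """A named genomic interval (repeat copy or CpG island)."""

    chrom: str
    start: int
    end: int
    name: str


@dataclass
class Annotations:
    genes: List[GeneModel] = field(default_factory=list)
    repeats: List[FeatureInterval] = field(default_factory=list)
    cpg_islands: List[FeatureInterval] = field(default_factory=list)


@dataclass
class GenomeSpec:
    """Parameters of a synthetic genome.

    ``interspersed_repeat_classes`` maps a class name (SINE/LINE/LTR-like)
    to ``(consensus_length, copy_count)``. ``array_len`` is the monomer copy
    count per satellite array. The default satellite monomer is an arbitrary
    fixed 23-mer labeled SAT-like; only its class structure matters.
    """

    chromosome_lengths: Sequence[int] = (200_000,)
    background_gc: float = 0.42
    n_genes: int = 10
    exons_per_gene: Tuple[int, int] = (2, 6)
    gene_len: Tuple[int, int] = (2_000, 15_000)
    promoter_len: int = 5_000
    n_cpg_islands: int = 10
    island_len: Tuple[int, int] = (500, 1_500)
    island_gc: float = 0.65
    island_cpg_rate: float = 0.10
    satellite_monomer: str = "GTACGTGGCTAGCCATAGAACCA"  # fixed 23-mer, SAT-like
    satellite_array_count: int = 0
    array_len: int = 100
    interspersed_repeat_classes: Mapping[str, Tuple[int, int]] = field(default_factory=dict)
    repeat_divergence: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not self.chromosome_lengths or any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError("background_gc must lie in [0, 1]")
        if not self.satellite_monomer:
            raise ValueError("satellite monomer must be non-empty")
        if self.promoter_len <= 0:
            raise ValueError("promoter_len must be positive")


@dataclass
class MarkModel:
    """Context-resolved mark probabilities.

    Contexts: CpG inside/outside islands (strand-symmetric draws), CHG/CHH
    (independent per strand). 5hmC at non-CpG cytosines is restricted to
    cytosines inside a CTAG occurrence, which is the context the
    TA-overhang chemistry can see. Repeat-class multipliers scale both mark
    probabilities inside repeats of that class; ``stage_overrides`` replaces
    any field for a named developmental stage (e.g. D7/D12).
    """

    p_mc_cpg_island: float = 0.7
    p_mc_cpg_nonisland: float = 0.2
    p_mc_noncpg: float = 0.0
    p_hmc_cpg: float = 0.05
    p_hmc_noncpg_ctag: float = 0.0
    repeat_multipliers: Mapping[str, float] = field(default_factory=dict)
    stage_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("p_mc_cpg_island", "p_mc_cpg_nonisland", "p_mc_noncpg",
                     "p_hmc_cpg", "p_hmc_noncpg_ctag"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_mc_cpg_island + self.p_hmc_cpg > 1.0 + 1e-12:
            raise ValueError("p(5mC)+p(5hmC) must be <= 1 in every context")
        if self.p_mc_cpg_nonisland + self.p_hmc_cpg > 1.0 + 1e-12:
            raise ValueError("p(5mC)+p(5hmC) must be <= 1 in every context")
        for m in self.repeat_multipliers.values():
            if m < 0:
                raise ValueError("repeat multipliers must be non-negative")

    def for_stage(self, stage: str) -> "MarkModel":
        """Resolve stage overrides into a concrete per-stage model."""
        if stage not in self.stage_overrides:
            if self.stage_overrides:
                raise KeyError(f"unknown stage {stage!r}; defined: "
                               f"{sorted(self.stage_overrides)}")
            return self
        over = dict(self.stage_overrides[stage])
        base = dataclasses.replace(self, stage_overrides={})
        for k, v in over.items():
            if not hasattr(base, k):
                raise KeyError(f"unknown MarkModel field {k!r} in stage override")
            setattr(base, k, v)
        base.validate()
        return base


class MethylomeTrack:
    """Per-cytosine mark assignment over a genome.

    Entries are keyed by (chrom, 0-based position, strand); each position
    appears at most once per strand and every marked position is a cytosine
    on the stated strand. CpG-context marks are strand-symmetric: the paired
    G-strand cytosine carries the same mark.
    """

    def __init__(self, entries: Optional[Mapping[Tuple[str, int, str], str]] = None,
                 metadata: Optional[Dict[str, object]] = None):
        self._entries: Dict[Tuple[str, int, str], str] = dict(entries or {})
        self.metadata: Dict[str, object] = dict(metadata or {})
        self._index: Optional[Dict[str, Tuple[List[int], List[Tuple[int, str, str]]]]] = None

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MethylomeTrack) and self._entries == other._entries

    def __iter__(self) -> Iterator[Tuple[str, int, str, str]]:
        for (chrom, pos, strand), mark in sorted(self._entries.items()):
            yield chrom, pos, strand, mark

    def add(self, chrom: str, pos: int, strand: str, mark: str) -> None:
        if mark not in MARKS:
            raise ValueError(f"unknown mark {mark!r}")
        key = (chrom, pos, strand)
        if key in self._entries:
            raise ValueError(f"duplicate entry at {key}")
        self._entries[key] = mark
        self._index = None

    def get(self, chrom: str, pos: int, strand: str) -> Optional[str]:
        return self._entries.get((chrom, pos, strand))

    def _build_index(self) -> None:
        by_chrom: Dict[str, List[Tuple[int, str, str]]] = {}
        for (chrom, pos, strand), mark in self._entries.items():
            by_chrom.setdefault(chrom, []).append((pos, strand, mark))
        self._index = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            self._index[chrom] = ([r[0] for r in rows], rows)

    def marks_in(self, chrom: str, start: int, end: int) -> List[Tuple[int, str, str]]:
        """All (pos, strand, mark) entries with start <= pos < end."""
        if self._index is None:
            self._build_index()
        assert self._index is not None
        if chrom not in self._index:
            return []
        positions, rows = self._index[chrom]
        lo = bisect_left(positions, start)
        hi = bisect_right(positions, end - 1)
        return rows[lo:hi]


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _island_seq(rng: np.random.Generator, length: int, gc: float, cpg_rate: float) -> np.ndarray:
    """GC- and CpG-dense segment: background at island GC with planted CG
    dinucleotides at roughly ``cpg_rate`` per position."""
    seq = _random_seq(rng, length, gc)
    n_cpg = int(length * cpg_rate / 2)
    if n_cpg and length >= 2:
        starts = rng.integers(0, length - 1, size=n_cpg)
        for s in starts:
            seq[s] = b"C"
            seq[s + 1] = b"G"
    return seq


def _place_interval(rng: np.random.Generator, chrom_lens: Sequence[int],
                    length: int, occupied: Dict[int, List[Tuple[int, int]]],
                    max_tries: int = 200) -> Tuple[int, int]:
    """Pick (chrom index, start) for a non-overlapping interval; bounded retries."""
    for _ in range(max_tries):
        ci = int(rng.integers(0, len(chrom_lens)))
        if chrom_lens[ci] < length:
            continue
        start = int(rng.integers(0, chrom_lens[ci] - length + 1))
        end = start + length
        if all(end <= s or start >= e for s, e in occupied[ci]):
            occupied[ci].append((start, end))
            return ci, start
    raise PlacementError(
        f"could not place a {length} bp feature after {max_tries} tries; "
        "chromosomes too small or too crowded for the requested features")


def generate_genome(spec: GenomeSpec) -> Tuple[Dict[str, str], Annotations]:
    """Generate a genome and its feature annotations from ``spec``.

    Returns FASTA-writable sequences plus gene models, repeat intervals and
    CpG-island intervals. Every declared feature count is realized or
    :class:`PlacementError` is raised. Same spec (including seed) yields
    byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(len(spec.chromosome_lengths))]
    seqs = [_random_seq(rng, l, spec.background_gc) for l in spec.chromosome_lengths]
    ann = Annotations()
    occupied: Dict[int, List[Tuple[int, int]]] = {i: [] for i in range(len(seqs))}

    # CpG islands: locally rewrite sequence; the written BED is ground truth.
    for k in range(spec.n_cpg_islands):
        length = int(rng.integers(spec.island_len[0], spec.island_len[1] + 1))
        ci, start = _place_interval(rng, spec.chromosome_lengths, length, occupied)
        seqs[ci][start:start + length] = _island_seq(rng, length, spec.island_gc,
                                                     spec.island_cpg_rate)
        ann.cpg_islands.append(FeatureInterval(chrom_names[ci], start, start + length,
                                               f"CpG_island_{k + 1}"))

    # Tandem satellite arrays: monomer repeated array_len times.
    monomer = spec.satellite_monomer.upper()
    for k in range(spec.satellite_array_count):
        length = len(monomer) * spec.array_len
        ci, start = _place_interval(rng, spec.chromosome_lengths, length, occupied)
        arr = np.frombuffer((monomer * spec.array_len).encode(), dtype="S1")
        seqs[ci][start:start + length] = arr
        ann.repeats.append(FeatureInterval(chrom_names[ci], start, start + length,
                                           "Satellite"))

    # Interspersed SINE/LINE/LTR-like elements: one consensus per class,
    # copies inserted with a small substitution divergence.
    for cls in sorted(spec.interspersed_repeat_classes):
        cons_len, copies = spec.interspersed_repeat_classes[cls]
        consensus = _random_seq(rng, cons_len, spec.background_gc)
        for _ in range(copies):
            ci, start = _place_interval(rng, spec.chromosome_lengths, cons_len, occupied)
            copy = consensus.copy()
            n_mut = rng.binomial(cons_len, spec.repeat_divergence)
            if n_mut:
                idx = rng.choice(cons_len, size=n_mut, replace=False)
                copy[idx] = rng.choice(_BASES, size=n_mut)
            seqs[ci][start:start + cons_len] = copy
            ann.repeats.append(FeatureInterval(chrom_names[ci], start, start + cons_len, cls))

    # Genes: annotation-only (sequence untouched). Exons are non-overlapping
    # sub-intervals of the gene span, first exon anchored at the span start.
    for g in range(spec.n_genes):
        glen = int(rng.integers(spec.gene_len[0], spec.gene_len[1] + 1))
        # leave promoter room on both sides so strand choice never clips
        for attempt in range(200):
            ci = int(rng.integers(0, len(seqs)))
            lo = spec.promoter_len
            hi = spec.chromosome_lengths[ci] - glen - spec.promoter_len
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            break
        else:
            raise PlacementError("could not place gene with promoter clearance")
        end = start + glen
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        n_ex = max(1, min(n_ex, glen // 200))
        bounds = np.sort(rng.choice(np.arange(1, glen // 100), size=2 * n_ex - 2,
                                    replace=False)) * 100 if n_ex > 1 else np.array([], dtype=int)
        edges = [0] + [int(b) for b in bounds] + [glen]
        exons = tuple((start + edges[2 * i], start + edges[2 * i + 1]) for i in range(n_ex))
        ann.genes.append(GeneModel(f"gene{g + 1:04d}", chrom_names[ci], start, end,
                                   strand, exons))

    ann.genes.sort(key=lambda g: (g.chrom, g.start))
    ann.repeats.sort(key=lambda r: (r.chrom, r.start))
    ann.cpg_islands.sort(key=lambda r: (r.chrom, r.start))
    genome = {name: seq.tobytes().decode() for name, seq in zip(chrom_names, seqs)}
    return genome, ann


# ---------------------------------------------------------------------------
# Methylome assignment
# ---------------------------------------------------------------------------

def _interval_mask(length: int, intervals: Iterable[Tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(0, s):min(length, e)] = True
    return mask


def assign_methylome(genome: Mapping[str, str], annotations: Annotations,
                     model: MarkModel, stage: str, seed: int) -> MethylomeTrack:
    """Draw a ground-truth mark track for ``stage``.

    Every cytosine receives an independent draw from its context-resolved
    probabilities: CpG cytosines draw once per CpG dinucleotide and the mark
    is mirrored to the opposite-strand cytosine; CHG/CHH cytosines draw
    independently per strand. Repeat-class multipliers scale the
    probabilities inside annotated repeats (the scaled pair is renormalised
    if it would exceed 1).
    """
    model.validate()
    m = model.for_stage(stage)
    rng = np.random.default_rng(seed)
    track = MethylomeTrack(metadata={"stage": stage, "seed": seed})

    rep_by_chrom: Dict[str, List[FeatureInterval]] = {}
    for r in annotations.repeats:
        rep_by_chrom.setdefault(r.chrom, []).append(r)
    isl_by_chrom: Dict[str, List[FeatureInterval]] = {}
    for r in annotations.cpg_islands:
        isl_by_chrom.setdefault(r.chrom, []).append(r)

    for chrom in sorted(genome):
        seq = genome[chrom]
        n = len(seq)
        arr = np.frombuffer(seq.encode(), dtype="S1")
        is_c = arr == b"C"
        is_g = arr == b"G"
        island = _interval_mask(n, ((i.start, i.end) for i in isl_by_chrom.get(chrom, [])))
        mult = np.ones(n)
        for r in rep_by_chrom.get(chrom, []):
            factor = m.repeat_multipliers.get(r.name, m.repeat_multipliers.get("other", 1.0))
            mult[r.start:r.end] = factor

        cpg_c = np.flatnonzero(is_c[:-1] & is_g[1:])  # C of each CpG, + strand

        def draw(positions: np.ndarray, p_mc: np.ndarray, p_hmc: np.ndarray,
                 emit) -> None:
            if positions.size == 0:
                return
            total = p_mc + p_hmc
            over = total > 1.0
            if np.any(over):  # renormalise multiplier overshoot
                p_mc = np.where(over, p_mc / total, p_mc)
                p_hmc = np.where(over, p_hmc / total, p_hmc)
            u = rng.random(positions.size)
            mc = u < p_mc
            hmc = (~mc) & (u < p_mc + p_hmc)
            for pos in positions[mc]:
                emit(int(pos), MARK_5MC)
            for pos in positions[hmc]:
                emit(int(pos), MARK_5HMC)

        # CpG context: one draw per dinucleotide, mirrored to the G-strand C.
        p_mc = np.where(island[cpg_c], m.p_mc_cpg_island, m.p_mc_cpg_nonisland) * mult[cpg_c]
        p_hmc = np.full(cpg_c.size, m.p_hmc_cpg) * mult[cpg_c]

        def emit_cpg(pos: int, mark: str) -> None:
            track.add(chrom, pos, "+", mark)
            track.add(chrom, pos + 1, "-", mark)

        draw(cpg_c, p_mc, p_hmc, emit_cpg)

        # Non-CpG cytosines, + strand: C not followed by G.
        if m.p_mc_noncpg > 0 or m.p_hmc_noncpg_ctag > 0:
            noncpg_plus = np.flatnonzero(is_c & ~np.concatenate([is_g[1:], [True]]))
            in_ctag_plus = np.zeros(n, dtype=bool)
            # C at i lies in a top-strand CTAG occurrence starting at i
            idx = 0
            while True:
                idx = seq.find("CTAG", idx)
                if idx < 0:
                    break
                in_ctag_plus[idx] = True
                # the minus-strand cytosine of the occurrence pairs with its G
                idx += 1
            p_mc2 = np.full(noncpg_plus.size, m.p_mc_noncpg) * mult[noncpg_plus]
            p_hmc2 = np.where(in_ctag_plus[noncpg_plus], m.p_hmc_noncpg_ctag, 0.0) * mult[noncpg_plus]
            draw(noncpg_plus, p_mc2, p_hmc2,
                 lambda pos, mark: track.add(chrom, pos, "+", mark))

            # Non-CpG cytosines, - strand: top-strand G not preceded by C.
            noncpg_minus = np.flatnonzero(is_g & ~np.concatenate([[True], is_c[:-1]]))
            # minus-strand C at top position j lies in CTAG if seq[j-3:j+1] == CTAG
            in_ctag_minus = np.zeros(n, dtype=bool)
            idx = 0
            while True:
                idx = seq.find("CTAG", idx)
                if idx < 0:
                    break
                if idx + 3 < n:
                    in_ctag_minus[idx + 3] = True
                idx += 1
            p_mc3 = np.full(noncpg_minus.size, m.p_mc_noncpg) * mult[noncpg_minus]
            p_hmc3 = np.where(in_ctag_minus[noncpg_minus], m.p_hmc_noncpg_ctag, 0.0) * mult[noncpg_minus]
            draw(noncpg_minus, p_mc3, p_hmc3,
                 lambda pos, mark: track.add(chrom, pos, "-", mark))

    return track


# ---------------------------------------------------------------------------
# Truth-track serialization
# ---------------------------------------------------------------------------

TRUTH_HEADER = "#chrom\tpos\tstrand\tmark"


def write_truth_set(track: MethylomeTrack, path) -> None:
    """Write the track as sorted TSV (chrom, 0-based pos, strand, mark)."""
    with open(path, "w") as fh:
        fh.write(TRUTH_HEADER + "\n")
        for chrom, pos, strand, mark in track:
            fh.write(f"{chrom}\t{pos}\t{strand}\t{mark}\n")


def read_truth_set(path) -> MethylomeTrack:
    """Read a truth TSV written by :func:`write_truth_set`."""
    track = MethylomeTrack()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, pos, strand, mark = parts
            if strand not in "+-" or mark not in MARKS:
                raise ValueError(f"{path}:{lineno}: bad strand/mark {strand!r}/{mark!r}")
            track.add(chrom, int(pos), strand, mark)
    return track
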