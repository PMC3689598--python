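"""Identification pipeline: reads -> contigs -> placements -> putative sites.

Reproduces the published analysis funnel: adaptor trimming, the HELP
internal-site read filter, greedy centroid clustering at 97% identity,
genomic placement filtered at >=92% identity over >=92% of the contig
length with multi-locus contigs discarded entirely, in-silico extension of
each placement end to the nearest recognition occurrence of the protocol's
primary enzyme (up to 1,000 bp, inclusive), and labeling of the cytosines
inside those occurrences as putatively 5mC (Me-RDA, HELP internal cocktail
sites) or 5hmC (HMe-RDA).

Clustering is a stated stand-in for USEARCH (greedy, reads processed in
decreasing length order, first centroid at >= the identity threshold wins);
the placement engine is an exact-seed (k=16) ungapped aligner, with PSL
import available as the escape hatch for externally produced alignments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import edlib
import numpy as np

from .library_sim import HELP_COCKTAIL, HME_RDA, ME_RDA, SimRead
from .restriction import EnzymeSpec, revcomp_iupac
from .synthetic_genome import MARK_5HMC, MARK_5MC, revcomp

#: Primary recognition sequence whose occurrences anchor fragment ends.
PRIMARY_RECOGNITION = {ME_RDA: "CCGG", HME_RDA: "CTAG", HELP_COCKTAIL: "AATT"}
#: Cocktail recognitions scanned inside HELP fragments.
HELP_COCKTAIL_RECOGNITIONS = ("CCGG", "CCGC", "GCGC")


@dataclass
class PipelineConfig:
    """Thresholds of the identification pipeline (inclusive throughout)."""

    protocol: str = ME_RDA
    cluster_identity: float = 0.97
    align_min_identity: float = 0.92
    align_min_coverage: float = 0.92
    extension_max: int = 1000
    min_read_len: int = 50
    seed_k: int = 16
    primary_recognition: Optional[str] = None
    help_filter_recognitions: Sequence[str] = HELP_COCKTAIL_RECOGNITIONS

    def __post_init__(self) -> None:
        for name in ("cluster_identity", "align_min_identity", "align_min_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.extension_max <= 0:
            raise ValueError("extension_max must be positive")
        if self.primary_recognition is None:
            self.primary_recognition = PRIMARY_RECOGNITION[self.protocol]


@dataclass
class Contig:
    contig_id: str
    consensus: str
    member_ids: Tuple[str, ...]

    @property
    def member_count(self) -> int:
        return len(self.member_ids)


@dataclass
class AlignmentRecord:
    """One passing genomic placement of a contig."""

    contig_id: str
    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float
    n_best_loci: int = 1


@dataclass
class ExtendedRecord:
    """A uniquely placed contig extended to its per-end primary sites."""

    record: AlignmentRecord
    start: int
    end: int
    left_site: Optional[int]   # occurrence start, or None if end unlabeled
    right_site: Optional[int]


@dataclass(frozen=True)
class PutativeSite:
    """A called cytosine position inside a recognition occurrence."""

    chrom: str
    position: int
    strand: str
    mark: str
    method: str
    stage: str
    contig_id: str
    end: str  # left | right | internal


@dataclass
class FunnelReport:
    """Pipeline funnel counts, one row per published metric."""

    raw_reads: int = 0
    cleaned_reads: int = 0
    validated_reads: Optional[int] = None
    consensus_sequences: int = 0
    aligned_sequences: int = 0
    unique_alignments: int = 0
    putative_sites: int = 0

    def rows(self) -> List[Tuple[str, object]]:
        return [
            ("Raw reads from library", self.raw_reads),
            ("Cleaned reads", self.cleaned_reads),
            ("Validated reads", self.validated_reads if self.validated_reads is not None else "N/A"),
            ("Consensus sequences", self.consensus_sequences),
            ("Sequences with genomic alignments", self.aligned_sequences),
            ("Sequences with unique alignment", self.unique_alignments),
            ("Putative methylated restriction sites", self.putative_sites),
        ]


# ---------------------------------------------------------------------------
# Read cleaning
# ---------------------------------------------------------------------------

def _matches_with_one_mismatch(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > 1:
                return False
    return True


def clean_reads(reads: Sequence[SimRead], adaptors: Sequence[str],
                config: PipelineConfig) -> Tuple[List[SimRead], Tuple[int, int]]:
    """Trim adaptors and drop short reads.

    A leading or trailing occurrence of any adaptor (or its reverse
    complement — reads are sequenced from either strand) is removed when it
    matches exactly or with one mismatch. Reads shorter than
    ``min_read_len`` after trimming are dropped. Returns the surviving reads
    and (raw, cleaned) counts.
    """
    variants = []
    for a in adaptors:
        if a:
            variants.append(a.upper())
            variants.append(revcomp(a.upper()))
    variants = sorted(set(variants), key=len, reverse=True)
    cleaned: List[SimRead] = []
    for read in reads:
        seq = read.sequence.upper()
        for a in variants:
            if len(seq) >= len(a) and _matches_with_one_mismatch(seq[:len(a)], a):
                seq = seq[len(a):]
                break
        for a in variants:
            if len(seq) >= len(a) and _matches_with_one_mismatch(seq[-len(a):], a):
                seq = seq[:-len(a)]
                break
        if len(seq) >= config.min_read_len:
            cleaned.append(SimRead(read.read_id, seq, read.source_fragment_id,
                                   read.stage, read.strand, read.n_errors))
    return cleaned, (len(reads), len(cleaned))


def filter_help_reads(reads: Sequence[SimRead],
                      recognitions: Sequence[str] = HELP_COCKTAIL_RECOGNITIONS,
                      protocol: str = HELP_COCKTAIL) -> List[SimRead]:
    """Keep only reads containing >=1 cocktail recognition on either strand.

    Reads without any internal methyl-sensitive site carry no methylation
    information. This filter belongs to the HELP chemistry only; calling it
    for another protocol is an error.
    """
    if protocol != HELP_COCKTAIL:
        raise ValueError("the internal-site read filter applies to the HELP protocol only")
    patterns = set()
    for r in recognitions:
        patterns.add(r.upper())
        patterns.add(revcomp_iupac(r))
    out = []
    for read in reads:
        seq = read.sequence.upper()
        if any(p in seq for p in patterns):
            out.append(read)
    return out


# ---------------------------------------------------------------------------
# Greedy centroid clustering
# ---------------------------------------------------------------------------

def _pair_identity(a: str, b: str) -> float:
    """Identity of an end-gap-free global alignment: matching columns over
    alignment columns."""
    res = edlib.align(a, b, mode="NW", task="path")
    cols = sum(int(n) for n in re.findall(r"(\d+)", res["cigar"]))
    return (cols - res["editDistance"]) / cols if cols else 0.0


def _oriented_identity(read_seq: str, centroid_seq: str) -> Tuple[float, str]:
    fwd = _pair_identity(read_seq, centroid_seq)
    rev = _pair_identity(revcomp(read_seq), centroid_seq)
    return (fwd, "+") if fwd >= rev else (rev, "-")


def cluster_reads(reads: Sequence[SimRead], config: PipelineConfig) -> List[Contig]:
    """Greedy centroid clustering at ``cluster_identity`` (inclusive).

    Reads are processed in decreasing length order (ties by read id), so the
    output is invariant under input shuffling. A read joins the first
    existing centroid whose pairwise identity (in its better orientation)
    reaches the threshold, else founds a new centroid. The consensus is the
    per-column majority over members aligned to the centroid; ties resolve
    to the centroid base.
    """
    ordered = sorted(reads, key=lambda r: (-len(r.sequence), r.read_id))
    centroids: List[str] = []
    members: List[List[Tuple[str, str, str]]] = []  # (read_id, oriented_seq, strand)
    exact: Dict[str, Tuple[int, str]] = {}  # seq -> (centroid idx, orientation)
    lens: List[int] = []
    t = config.cluster_identity
    for read in ordered:
        seq = read.sequence.upper()
        hit = exact.get(seq)
        if hit is not None:
            ci, orient = hit
            oriented = seq if orient == "+" else revcomp(seq)
            members[ci].append((read.read_id, oriented, orient))
            continue
        placed = False
        for ci, cseq in enumerate(centroids):
            # end-gap-free NW identity cannot reach t if lengths differ too much
            if abs(lens[ci] - len(seq)) > (1 - t) * max(lens[ci], len(seq)) + 1e-9:
                continue
            ident, orient = _oriented_identity(seq, cseq)
            if ident >= t - 1e-12:
                oriented = seq if orient == "+" else revcomp(seq)
                members[ci].append((read.read_id, oriented, orient))
                exact[seq] = (ci, orient)
                placed = True
                break
        if not placed:
            ci = len(centroids)
            centroids.append(seq)
            lens.append(len(seq))
            members.append([(read.read_id, seq, "+")])
            exact[seq] = (ci, "+")
    contigs: List[Contig] = []
    for ci, cseq in enumerate(centroids):
        consensus = _consensus(cseq, [m[1] for m in members[ci]])
        contigs.append(Contig(f"contig{ci + 1:05d}", consensus,
                              tuple(m[0] for m in members[ci])))
    return contigs


def _consensus(centroid: str, member_seqs: Sequence[str]) -> str:
    """Majority call per centroid column; ties keep the centroid base.
    Insertions relative to the centroid are ignored."""
    if len(member_seqs) == 1:
        return centroid
    counts: List[Dict[str, int]] = [dict() for _ in centroid]
    for seq in member_seqs:
        if seq == centroid:
            for i, b in enumerate(centroid):
                counts[i][b] = counts[i].get(b, 0) + 1
            continue
        res = edlib.align(seq, centroid, mode="NW", task="path")
        nice = edlib.getNiceAlignment(res, seq, centroid)
        col = 0
        for qb, tb in zip(nice["query_aligned"], nice["target_aligned"]):
            if tb == "-":
                continue  # insertion in member
            if qb != "-":
                counts[col][qb] = counts[col].get(qb, 0) + 1
            col += 1
    out = []
    for i, base in enumerate(centroid):
        c = counts[i]
        if not c:
            out.append(base)
            continue
        best = max(c.values())
        winners = sorted(b for b, v in c.items() if v == best)
        out.append(base if base in winners or len(winners) > 1 else winners[0])
    return "".join(out)


# ---------------------------------------------------------------------------
# Genomic placement
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Sorted-array index of all k-mers of a genome (2-bit packed)."""

    def __init__(self, genome: Mapping[str, str], k: int = 16):
        self.k = k
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.arrays: Dict[str, np.ndarray] = {}
        self._codes: Dict[str, np.ndarray] = {}
        self._order: Dict[str, np.ndarray] = {}
        code_of = np.full(256, -1, dtype=np.int64)
        for i, b in enumerate(b"ACGT"):
            code_of[b] = i
        for chrom, seq in self.genome.items():
            arr = code_of[np.frombuffer(seq.encode(), dtype=np.uint8)]
            self.arrays[chrom] = arr
            if len(arr) < k:
                self._codes[chrom] = np.empty(0, dtype=np.int64)
                self._order[chrom] = np.empty(0, dtype=np.int64)
                continue
            codes = np.zeros(len(arr) - k + 1, dtype=np.int64)
            valid = np.ones(len(arr) - k + 1, dtype=bool)
            for j in range(k):
                window = arr[j:len(arr) - k + 1 + j]
                codes = codes * 4 + np.where(window >= 0, window, 0)
                valid &= window >= 0
            codes[~valid] = -1
            order = np.argsort(codes, kind="stable")
            self._codes[chrom] = codes[order]
            self._order[chrom] = order

    def kmer_code(self, kmer: str) -> int:
        code = 0
        for ch in kmer:
            v = "ACGT".find(ch)
            if v < 0:
                return -1
            code = code * 4 + v
        return code

    def lookup(self, kmer: str, chrom: str) -> np.ndarray:
        code = self.kmer_code(kmer)
        if code < 0:
            return np.empty(0, dtype=np.int64)
        codes = self._codes[chrom]
        lo = np.searchsorted(codes, code, side="left")
        hi = np.searchsorted(codes, code, side="right")
        return self._order[chrom][lo:hi]


def _merge_placements(placements: List[AlignmentRecord]) -> List[AlignmentRecord]:
    """Merge placements overlapping >50% reciprocally, keeping the best
    identity, before counting loci."""
    placements = sorted(placements, key=lambda p: (-p.identity, p.chrom, p.start))
    kept: List[AlignmentRecord] = []
    for p in placements:
        merged = False
        for q in kept:
            if p.chrom != q.chrom:
                continue
            ov = min(p.end, q.end) - max(p.start, q.start)
            if ov > 0 and ov > 0.5 * (p.end - p.start) and ov > 0.5 * (q.end - q.start):
                merged = True
                break
        if not merged:
            kept.append(p)
    kept.sort(key=lambda p: (p.chrom, p.start))
    return kept


def align_contigs(contigs: Sequence[Contig], genome: Mapping[str, str],
                  config: PipelineConfig,
                  index: Optional[GenomeIndex] = None) -> List[AlignmentRecord]:
    """Place contigs on the genome (exact-seed, ungapped extension).

    Every full-length ungapped placement with identity >= the threshold is
    reported (coverage is 1.0 by construction); placements overlapping >50%
    reciprocally are merged before ``n_best_loci`` is counted. Gapped
    alignment is unnecessary at the 92/92 thresholds on substitution-only
    reads; externally produced PSL alignments can be imported instead.
    """
    if index is None:
        index = GenomeIndex(genome, config.seed_k)
    k = index.k
    records: List[AlignmentRecord] = []
    code_of = np.full(256, -9, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code_of[b] = i
    for contig in contigs:
        clen = len(contig.consensus)
        placements: Dict[Tuple[str, int, str], AlignmentRecord] = {}
        tried: Set[Tuple[str, int, str]] = set()
        if clen < k:
            continue
        for strand in ("+", "-"):
            qseq = contig.consensus if strand == "+" else revcomp(contig.consensus)
            qarr = code_of[np.frombuffer(qseq.encode(), dtype=np.uint8)]
            offsets = list(range(0, clen - k + 1, k))
            if offsets[-1] != clen - k:
                offsets.append(clen - k)
            for off in offsets:
                kmer = qseq[off:off + k]
                for chrom in index.genome:
                    garr_full = index.arrays[chrom]
                    for hit in index.lookup(kmer, chrom):
                        start = int(hit) - off
                        end = start + clen
                        if start < 0 or end > len(garr_full):
                            continue
                        key = (chrom, start, strand)
                        if key in tried:
                            continue
                        tried.add(key)
                        ident = float(np.mean(qarr == garr_full[start:end]))
                        if ident >= config.align_min_identity - 1e-12 \
                                and 1.0 >= config.align_min_coverage:
                            placements[key] = AlignmentRecord(
                                contig.contig_id, chrom, start, end, strand,
                                ident, 1.0)
        merged = _merge_placements(list(placements.values()))
        for rec in merged:
            rec.n_best_loci = len(merged)
            records.append(rec)
    return records


def filter_alignments(records: Sequence[AlignmentRecord], config: PipelineConfig
                      ) -> Tuple[List[AlignmentRecord], Dict[str, int]]:
    """Keep only uniquely placed contigs.

    Thresholds (inclusive) are re-applied so imported PSL records pass
    through the same gate; contigs with more than one passing placement are
    excluded entirely. Returns the kept records and the funnel counts
    (aligned contigs, uniquely placed contigs).
    """
    by_contig: Dict[str, List[AlignmentRecord]] = {}
    for r in records:
        if r.identity >= config.align_min_identity - 1e-12 and \
                r.coverage >= config.align_min_coverage - 1e-12:
            by_contig.setdefault(r.contig_id, []).append(r)
    kept: List[AlignmentRecord] = []
    for cid in sorted(by_contig):
        merged = _merge_placements(by_contig[cid])
        if len(merged) == 1:
            rec = merged[0]
            rec.n_best_loci = 1
            kept.append(rec)
    counts = {"aligned": len(by_contig), "unique": len(kept)}
    return kept, counts


# ---------------------------------------------------------------------------
# Extension to the nearest primary site and labeling
# ---------------------------------------------------------------------------

def _occurrence_starts(seq: str, recognition: str) -> np.ndarray:
    pat = re.compile("(?=" + recognition + ")")
    return np.array([m.start() for m in pat.finditer(seq)], dtype=np.int64)


def extend_to_site(record: AlignmentRecord, genome: Mapping[str, str],
                   config: PipelineConfig,
                   occurrences: Optional[np.ndarray] = None) -> ExtendedRecord:
    """Extend a placement to the nearest primary-recognition occurrence.

    For each end: if the boundary already lies within an occurrence, that
    occurrence is the end's site and no extension happens; otherwise the
    nearest outward occurrence within ``extension_max`` bp (inclusive,
    measured boundary-to-occurrence-start) is taken; if none exists the end
    is left unlabeled.
    """
    seq = genome[record.chrom]
    recog = config.primary_recognition
    rlen = len(recog)
    occs = occurrences if occurrences is not None else _occurrence_starts(seq, recog)
    start, end = record.start, record.end
    if start < 0 or end > len(seq):
        raise ValueError("placement interval outside chromosome bounds")

    left_site: Optional[int] = None
    i = int(np.searchsorted(occs, start, side="right")) - 1
    if i >= 0:
        o = int(occs[i])
        if o + rlen > start:          # boundary inside the occurrence
            left_site = o
        elif start - o <= config.extension_max:
            left_site = o

    right_site: Optional[int] = None
    # occurrence overlapping the right boundary: largest o with o < end <= o+rlen
    j = int(np.searchsorted(occs, end, side="left")) - 1
    if j >= 0 and int(occs[j]) + rlen >= end:
        right_site = int(occs[j])
    else:
        j2 = int(np.searchsorted(occs, end, side="left"))
        if j2 < len(occs) and int(occs[j2]) - end <= config.extension_max:
            right_site = int(occs[j2])

    new_start = min(start, left_site) if left_site is not None else start
    new_end = max(end, right_site + rlen) if right_site is not None else end
    return ExtendedRecord(record, new_start, new_end, left_site, right_site)


def _cpg_positions(seq: str, start: int, end: int) -> List[int]:
    return [i for i in range(max(0, start), min(len(seq) - 1, end - 1))
            if seq[i:i + 2] == "CG"]


def call_sites(extended: Sequence[ExtendedRecord], genome: Mapping[str, str],
               config: PipelineConfig, stage: str) -> List[PutativeSite]:
    """Label marked cytosines from extended placements.

    Me-RDA: the CpG cytosine inside each end's CCGG occurrence is labeled
    5mC. HMe-RDA: CTAG contains no CpG, so the cytosine of the occurrence
    itself is labeled 5hmC. HELP: every CpG cytosine inside every cocktail
    occurrence strictly between the two bounding TasI sites is labeled 5mC
    (both TasI ends must be identified). Duplicate (chrom, position, mark,
    method, stage) records are collapsed.
    """
    method = config.protocol
    recog = config.primary_recognition
    rlen = len(recog)
    seen: Set[Tuple[str, int, str]] = set()
    sites: List[PutativeSite] = []

    def emit(chrom: str, pos: int, mark: str, cid: str, which: str) -> None:
        key = (chrom, pos, mark)
        if key in seen:
            return
        seen.add(key)
        sites.append(PutativeSite(chrom, pos, "+", mark, method, stage, cid, which))

    for ext in extended:
        chrom = ext.record.chrom
        seq = genome[chrom]
        cid = ext.record.contig_id
        if method in (ME_RDA, HME_RDA):
            mark = MARK_5MC if method == ME_RDA else MARK_5HMC
            for which, o in (("left", ext.left_site), ("right", ext.right_site)):
                if o is None:
                    continue
                if method == ME_RDA:
                    for p in _cpg_positions(seq, o, o + rlen):
                        emit(chrom, p, mark, cid, which)
                else:
                    emit(chrom, o, mark, cid, which)  # C of the CTAG occurrence
        else:
            if ext.left_site is None or ext.right_site is None:
                continue
            lo = ext.left_site + rlen
            hi = ext.right_site
            for r in config.help_filter_recognitions:
                for pattern in {r.upper(), revcomp_iupac(r)}:
                    for m in re.finditer("(?=" + pattern + ")", seq[lo:hi]):
                        o = lo + m.start()
                        if o + len(pattern) > hi:
                            continue
                        for p in _cpg_positions(seq, o, o + len(pattern)):
                            emit(chrom, p, MARK_5MC, cid, "internal")

    for s in sites:  # every call must sit inside a relevant occurrence
        _validate_site(s, genome, config)
    sites.sort(key=lambda s: (s.chrom, s.position))
    return sites


def _validate_site(site: PutativeSite, genome: Mapping[str, str],
                   config: PipelineConfig) -> None:
    seq = genome[site.chrom]
    recogs = [config.primary_recognition] if site.method in (ME_RDA, HME_RDA) \
        else list(config.help_filter_recognitions)
    for r in recogs:
        for pattern in {r.upper(), revcomp_iupac(r)}:
            rl = len(pattern)
            for o in range(max(0, site.position - rl + 1), site.position + 1):
                if seq[o:o + rl] == pattern:
                    return
    raise AssertionError(
        f"called site {site} lies outside any relevant recognition occurrence")


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def run_site_calling(reads: Sequence[SimRead], genome: Mapping[str, str],
                     config: PipelineConfig, stage: str,
                     adaptors: Sequence[str] = (),
                     psl_records: Optional[Sequence[AlignmentRecord]] = None
                     ) -> Tuple[List[PutativeSite], List[Contig], FunnelReport]:
    """Full funnel from raw reads to putative sites plus the count report."""
    report = FunnelReport(raw_reads=len(reads))
    cleaned, (_, n_clean) = clean_reads(reads, adaptors, config)
    report.cleaned_reads = n_clean
    if config.protocol == HELP_COCKTAIL:
        cleaned = filter_help_reads(cleaned, config.help_filter_recognitions,
                                    config.protocol)
        report.validated_reads = len(cleaned)
    contigs = cluster_reads(cleaned, config)
    report.consensus_sequences = len(contigs)
    if psl_records is not None:
        records = list(psl_records)
    else:
        records = align_contigs(contigs, genome, config)
    kept, counts = filter_alignments(records, config)
    report.aligned_sequences = counts["aligned"]
    report.unique_alignments = counts["unique"]
    occ_cache = {chrom: _occurrence_starts(genome[chrom], config.primary_recognition)
                 for chrom in genome}
    extended = [extend_to_site(r, genome, config, occ_cache[r.chrom]) for r in kept]
    sites = call_sites(extended, genome, config, stage)
    report.putative_sites = len(sites)
    return sites, contigs, report
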