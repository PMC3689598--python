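"""Idealized simulators of the three enrichment chemistries.

Me-RDA / HMe-RDA model Tester/Driver subtraction as its limit behaviour: a
tester (insensitive-enzyme) fragment is enriched iff at least one of its
bounding cut positions is absent from the driver (sensitive isoschizomer)
unblocked cut set — the restriction site stayed uncut because it carried
the mark. The HELP cocktail simulator keeps the TasI fragments whose every
internal cocktail site is blocked (methylated fragments remain uncut and
amplify). Subtraction is modeled as ideal and complete; hybridization
kinetics are out of scope.

``fragments_to_reads`` stands in for sequencing of the amplicons: per-
fragment copies on random strands, optional ligated adaptor sequences, and
i.i.d. substitution errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .restriction import (EnzymeSpec, SimFragment, TERMINUS, digest,
                          find_sites, unblocked_cut_positions)
from .synthetic_genome import MARK_5HMC, MARK_5MC, MethylomeTrack, revcomp

ME_RDA = "ME_RDA"
HME_RDA = "HME_RDA"
HELP_COCKTAIL = "HELP_COCKTAIL"
PROTOCOLS = (ME_RDA, HME_RDA, HELP_COCKTAIL)

#: Tester-strand adaptor from the ligation chemistry (J-1B duplex oligo).
DEFAULT_ADAPTOR = "ACCGACGTCGACTATCCATGAACC"


@dataclass
class ProtocolConfig:
    """Configuration of one library chemistry.

    ``size_window`` is the validated amplicon size range, 100 bp – 1 kb by
    default (inclusive). Terminal fragments are excluded by default:
    amplification needs adaptors ligated at both ends, which a chromosome
    terminus cannot provide.
    """

    protocol: str
    tester_enzyme: Optional[EnzymeSpec] = None
    driver_enzyme: Optional[EnzymeSpec] = None
    frequent_cutter: Optional[EnzymeSpec] = None
    cocktail: Sequence[EnzymeSpec] = ()
    size_window: Tuple[int, int] = (100, 1000)
    exclude_terminal_fragments: bool = True

    def validate(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        lo, hi = self.size_window
        if lo >= hi:
            raise ValueError("size_window min must be below max")
        if self.protocol in (ME_RDA, HME_RDA):
            if self.tester_enzyme is None or self.driver_enzyme is None:
                raise ValueError("RDA protocols need tester and driver enzymes")
            if self.tester_enzyme.recognition.upper() != self.driver_enzyme.recognition.upper():
                raise ValueError(
                    "tester and driver must be isoschizomers (identical recognition); got "
                    f"{self.tester_enzyme.recognition} vs {self.driver_enzyme.recognition}")
        else:
            if self.frequent_cutter is None or not self.cocktail:
                raise ValueError("HELP needs a frequent cutter and a cocktail")


@dataclass
class EnrichedFragment:
    """A fragment surviving a protocol, with truth provenance.

    ``true_left_mark`` / ``true_right_mark`` report the mark present in the
    bounding recognition-site footprint (5hmC wins over 5mC if both occur in
    one footprint; ``none`` if unmarked). ``internal_site_marks`` lists the
    (position, mark) pairs inside internal cocktail footprints (HELP only).
    """

    fragment: SimFragment
    protocol: str
    sequence: str
    true_left_mark: str = "none"
    true_right_mark: str = "none"
    internal_site_marks: Tuple[Tuple[int, str], ...] = ()
    no_internal_site: bool = False

    @property
    def id(self) -> str:
        f = self.fragment
        return f"{f.chrom}:{f.start}-{f.end}"

    @property
    def length(self) -> int:
        return self.fragment.length


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    source_fragment_id: str
    stage: str
    strand: str
    n_errors: int


def _footprint_mark(track: Optional[MethylomeTrack], chrom: str,
                    start: int, end: int) -> str:
    """Summarise the marks inside a recognition footprint as a single state."""
    if track is None:
        return "none"
    marks = {m for _p, _s, m in track.marks_in(chrom, start, end)}
    if MARK_5HMC in marks:
        return MARK_5HMC
    if MARK_5MC in marks:
        return MARK_5MC
    return "none"


def _in_window(frag: SimFragment, config: ProtocolConfig) -> bool:
    lo, hi = config.size_window
    return lo <= frag.length <= hi


def simulate_rda(genome: Mapping[str, str], track: MethylomeTrack,
                 config: ProtocolConfig) -> List[EnrichedFragment]:
    """Simulate Me-RDA / HMe-RDA enrichment over a genome.

    Tester fragments are the insensitive-enzyme digest; a fragment is
    enriched iff at least one bounding cut position is absent from the
    sensitive driver's unblocked cut set (that bounding site carries the
    blocking mark). The validated size window and terminal-fragment
    exclusion are applied before reporting.
    """
    config.validate()
    if config.protocol not in (ME_RDA, HME_RDA):
        raise ValueError("simulate_rda requires an RDA protocol")
    tester, driver = config.tester_enzyme, config.driver_enzyme
    rlen = len(tester.recognition)
    enriched: List[EnrichedFragment] = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        frags = digest(seq, [tester], track, chrom)
        driver_cuts = unblocked_cut_positions(seq, [driver], track, chrom)
        for frag in frags:
            if config.exclude_terminal_fragments and frag.is_terminal:
                continue
            if not _in_window(frag, config):
                continue
            bounding = [s for s in (frag.left_site, frag.right_site) if s is not TERMINUS]
            if not any(s.cut_pos not in driver_cuts for s in bounding):
                continue
            left = _footprint_mark(track, chrom, frag.left_site.occurrence_start,
                                   frag.left_site.occurrence_start + rlen) \
                if frag.left_site is not TERMINUS else "none"
            right = _footprint_mark(track, chrom, frag.right_site.occurrence_start,
                                    frag.right_site.occurrence_start + rlen) \
                if frag.right_site is not TERMINUS else "none"
            enriched.append(EnrichedFragment(frag, config.protocol,
                                             seq[frag.start:frag.end], left, right))
    return enriched


def simulate_help(genome: Mapping[str, str], track: MethylomeTrack,
                  config: ProtocolConfig) -> List[EnrichedFragment]:
    """Simulate the HELP-cocktail chemistry.

    TasI fragments are computed on the plain sequence (TasI is insensitive);
    a fragment survives iff no cocktail enzyme has an unblocked cut strictly
    inside it. Fragments with no internal cocktail occurrence at all survive
    too and are flagged ``no_internal_site`` — they carry no methylation
    information and are removed downstream by the read filter.
    """
    config.validate()
    if config.protocol != HELP_COCKTAIL:
        raise ValueError("simulate_help requires the HELP protocol")
    retained: List[EnrichedFragment] = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        frags = digest(seq, [config.frequent_cutter], track, chrom)
        sites = []
        for enz in config.cocktail:
            rlen = len(enz.recognition)
            for c in find_sites(seq, enz, track, chrom):
                sites.append((c.cut_pos, c.blocked, c.occurrence_start, rlen))
        sites.sort()
        cut_positions = np.array([s[0] for s in sites], dtype=np.int64)
        for frag in frags:
            if config.exclude_terminal_fragments and frag.is_terminal:
                continue
            if not _in_window(frag, config):
                continue
            lo = np.searchsorted(cut_positions, frag.start, side="right")
            hi = np.searchsorted(cut_positions, frag.end, side="left")
            internal = sites[int(lo):int(hi)]
            if any(not blocked for _pos, blocked, _os, _rl in internal):
                continue
            marks: List[Tuple[int, str]] = []
            for _pos, _blocked, ostart, rlen in internal:
                for p, _s, m in track.marks_in(chrom, ostart, ostart + rlen):
                    marks.append((p, m))
            retained.append(EnrichedFragment(
                frag, HELP_COCKTAIL, seq[frag.start:frag.end],
                internal_site_marks=tuple(sorted(set(marks))),
                no_internal_site=not internal))
    return retained


def fragments_to_reads(fragments: Sequence[EnrichedFragment], coverage: int,
                       error_rate: float = 0.0,
                       adaptors: Tuple[str, str] = ("", ""),
                       seed: int = 0, stage: str = "") -> List[SimRead]:
    """Emit ``coverage`` reads per fragment with substitution errors.

    Each copy is drawn on a uniform random strand; adaptor sequences (left
    prepended, right appended, after strand choice) model the ligated
    duplexes. Substitutions are i.i.d. per base at ``error_rate``.
    """
    if not 0 <= error_rate < 0.2:
        raise ValueError("error_rate must lie in [0, 0.2)")
    rng = np.random.default_rng(seed)
    left, right = adaptors
    bases = np.frombuffer(b"ACGT", dtype="S1")
    reads: List[SimRead] = []
    for frag in fragments:
        for i in range(coverage):
            strand = "+" if rng.random() < 0.5 else "-"
            insert = frag.sequence if strand == "+" else revcomp(frag.sequence)
            seq = left + insert + right
            n_err = 0
            if error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                hit = np.flatnonzero(rng.random(arr.size) < error_rate)
                for j in hit:
                    old = arr[j]
                    choices = bases[bases != old]
                    arr[j] = choices[int(rng.integers(0, len(choices)))]
                n_err = int(hit.size)
                seq = arr.tobytes().decode()
            reads.append(SimRead(f"{frag.id}/{i}", seq, frag.id, stage, strand, n_err))
    return reads
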