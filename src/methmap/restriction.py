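"""Mark-aware in-silico restriction digestion.

Declarative enzyme models (recognition sequence, cut offset, which cytosine
marks block cleavage) and a digestion kernel over a genome plus a
:class:`~methmap.synthetic_genome.MethylomeTrack`. Blocking scope is the
whole recognition footprint on either strand: a site is blocked iff any
cytosine inside the occurrence carries a mark the enzyme is sensitive to.

The default registry covers the isoschizomer pairs MspI/HpaII (CCGG) and
FspBI/BfaI (CTAG), the frequent cutter TasI (/AATT), and the
methyl-sensitive cocktail HpaII + AciI + HinP1I. MspI and BfaI cut through
5mC but are blocked by an internal 5hmC; HpaII is blocked by both marks.
AciI and HinP1I default to HpaII-like sensitivity (blocked by both),
configurable through the registry file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .synthetic_genome import MARKS, MethylomeTrack, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class TERMINUS:
    """Sentinel for a fragment end at a chromosome terminus."""

    def __repr__(self) -> str:  # pragma: no cover
        return "TERMINUS"


TERMINUS = TERMINUS()


class ChromosomeMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition site, cut offset and sensitivity.

    ``cut_offset`` counts bases from the 5' edge of a top-strand occurrence
    to the top-strand cut. ``blocked_by`` is the set of cytosine marks that
    abolish cleavage. ``double_stranded_scan`` scans the reverse strand for
    non-palindromic recognitions.
    """

    name: str
    recognition: str
    cut_offset: int
    blocked_by: FrozenSet[str] = frozenset()
    double_stranded_scan: bool = True

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("recognition must be non-empty")
        bad = set(self.recognition.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"malformed IUPAC pattern {self.recognition!r}: {bad}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside recognition sequence")
        if not self.blocked_by <= set(MARKS):
            raise ValueError(f"unknown marks in blocked_by: {self.blocked_by}")

    @property
    def is_palindromic(self) -> bool:
        return revcomp_iupac(self.recognition) == self.recognition.upper()

    def regex(self) -> "re.Pattern[str]":
        return re.compile("(?=" + "".join(
            c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]"
            for c in self.recognition.upper()) + ")")


def revcomp_iupac(pattern: str) -> str:
    return pattern.upper().translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CutSite:
    """One recognition occurrence and its cleavage status."""

    chrom: str
    occurrence_start: int
    cut_pos: int
    strand: str
    blocked: bool
    blocking_marks: Tuple[Tuple[int, str], ...] = ()
    enzyme: str = ""


@dataclass(frozen=True)
class SimFragment:
    """A restriction fragment (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    left_site: object = TERMINUS
    right_site: object = TERMINUS

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_terminal(self) -> bool:
        return self.left_site is TERMINUS or self.right_site is TERMINUS


# ---------------------------------------------------------------------------
# Site finding and digestion
# ---------------------------------------------------------------------------

def find_sites(sequence: str, enzyme: EnzymeSpec, track: Optional[MethylomeTrack] = None,
               chrom: str = "chr1") -> List[CutSite]:
    """All recognition occurrences of ``enzyme`` in ``sequence``.

    Palindromic recognitions are reported once (+ strand). Non-palindromic
    ones are also scanned on the reverse strand when the enzyme's
    ``double_stranded_scan`` flag is set; for a minus-strand occurrence the
    top-strand cut position is ``start + len - cut_offset``. Occurrences
    containing N never cut. A site is blocked iff any cytosine in the
    occurrence footprint, on either strand, carries a mark in
    ``enzyme.blocked_by``.
    """
    seq = sequence.upper()
    rlen = len(enzyme.recognition)
    out: List[CutSite] = []

    def marks_in_footprint(start: int) -> Tuple[Tuple[int, str], ...]:
        if track is None:
            return ()
        return tuple((pos, mark) for pos, _strand, mark in
                     track.marks_in(chrom, start, start + rlen)
                     if mark in enzyme.blocked_by)

    def scan(pattern: str, strand: str, cut_from_start: int) -> None:
        pat = re.compile("(?=" + "".join(
            c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]"
            for c in pattern) + ")")
        for m in pat.finditer(seq):
            s = m.start()
            if "N" in seq[s:s + rlen]:
                continue
            blocking = marks_in_footprint(s)
            out.append(CutSite(chrom, s, s + cut_from_start, strand,
                               bool(blocking), blocking, enzyme.name))

    scan(enzyme.recognition.upper(), "+", enzyme.cut_offset)
    if not enzyme.is_palindromic and enzyme.double_stranded_scan:
        scan(revcomp_iupac(enzyme.recognition), "-", rlen - enzyme.cut_offset)
    out.sort(key=lambda c: (c.occurrence_start, c.strand))
    return out


def unblocked_cut_positions(sequence: str, enzymes: Iterable[EnzymeSpec],
                            track: Optional[MethylomeTrack] = None,
                            chrom: str = "chr1") -> Set[int]:
    """Union of unblocked top-strand cut positions of ``enzymes``."""
    cuts: Set[int] = set()
    for enz in enzymes:
        cuts.update(c.cut_pos for c in find_sites(sequence, enz, track, chrom)
                    if not c.blocked)
    return cuts


def digest(sequence: str, enzymes: Sequence[EnzymeSpec],
           track: Optional[MethylomeTrack] = None,
           chrom: str = "chr1") -> List[SimFragment]:
    """Digest ``sequence`` with every enzyme; fragments tile the sequence.

    Cuts occur at every unblocked cut site of every enzyme (deduplicated by
    position). Zero-length fragments from coincident cuts are suppressed.
    Chromosome ends carry the :data:`TERMINUS` sentinel.
    """
    if not enzymes:
        raise ValueError("at least one enzyme required")
    site_by_cut: Dict[int, CutSite] = {}
    for enz in enzymes:
        for c in find_sites(sequence, enz, track, chrom):
            if not c.blocked and 0 < c.cut_pos < len(sequence):
                site_by_cut.setdefault(c.cut_pos, c)
    cuts = sorted(site_by_cut)
    bounds = [0] + cuts + [len(sequence)]
    frags: List[SimFragment] = []
    for a, b in zip(bounds, bounds[1:]):
        if b <= a:
            continue
        frags.append(SimFragment(chrom, a, b,
                                 site_by_cut.get(a, TERMINUS),
                                 site_by_cut.get(b, TERMINUS)))
    return frags


def subtract_cut_sets(tester_cuts: Set[int], driver_cuts: Set[int],
                      tester_chrom: Optional[str] = None,
                      driver_chrom: Optional[str] = None) -> Set[int]:
    """Positions cut by the tester enzyme but not by the driver.

    Plain set difference; no containment between the inputs is assumed.
    When chromosome labels are supplied they must agree.
    """
    if tester_chrom is not None and driver_chrom is not None \
            and tester_chrom != driver_chrom:
        raise ChromosomeMismatchError(
            f"cut sets from different chromosomes: {tester_chrom} vs {driver_chrom}")
    return set(tester_cuts) - set(driver_cuts)


# ---------------------------------------------------------------------------
# Enzyme registry
# ---------------------------------------------------------------------------

def load_enzyme_registry(path=None) -> Dict[str, EnzymeSpec]:
    """Load enzymes from a registry TSV (name, recognition, offset,
    blocked_by comma-list or '-', double_stranded_scan). Defaults to the
    registry shipped with the package."""
    if path is None:
        text = resources.files("methmap").joinpath("data/enzymes.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    registry: Dict[str, EnzymeSpec] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"enzyme registry line {lineno}: expected 5 columns")
        name, recog, offset, blocked, ds = parts
        blocked_by = frozenset() if blocked == "-" else frozenset(blocked.split(","))
        registry[name] = EnzymeSpec(name, recog, int(offset), blocked_by,
                                    ds.lower() in ("1", "true", "yes"))
    return registry


DEFAULT_ENZYMES: Dict[str, EnzymeSpec] = load_enzyme_registry()
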