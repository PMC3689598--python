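"""Functional annotation and comparison of called sites.

Each site is classified into exactly one of promoter / exon / intron /
intergenic with precedence exon > intron > promoter > intergenic, and owned
by exactly one gene (ties to the smallest gene id) or one intergenic
interval. Promoters are the strand-aware 5 kb window upstream of the TSS.
Also provides repeat-class composition of contig sets, exact three-way set
comparisons between stages or methods, fixed-width coverage binning, and a
chi-square goodness-of-fit of library region proportions against the
genomic baseline.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree
from scipy import stats

from .site_caller import PutativeSite
from .synthetic_genome import Annotations, FeatureInterval, GeneModel

CATEGORIES = ("promoter", "exon", "intron", "intergenic")
REPEAT_CLASSES = ("SINE", "LINE", "LTR", "Satellite")


@dataclass(frozen=True)
class RegionAnnotation:
    site: PutativeSite
    category: str
    owner: str


@dataclass
class CompositionReport:
    """Repeat/CpG-island composition of a set of sequences or sites."""

    n_sequences: int
    n_with_repeat: int
    class_base_fraction: Dict[str, float]
    total_base_fraction: float
    n_in_island: int = 0
    island_fraction: float = 0.0

    @property
    def repeat_sequence_fraction(self) -> float:
        return self.n_with_repeat / self.n_sequences if self.n_sequences else 0.0


class GenomeAnnotationIndex:
    """Interval lookups over gene models: promoters, exons, gene spans and
    the derived intergenic intervals."""

    def __init__(self, genes: Sequence[GeneModel],
                 chrom_lengths: Mapping[str, int], promoter_len: int = 5000):
        self.promoter_len = promoter_len
        self.chrom_lengths = dict(chrom_lengths)
        self.exons: Dict[str, IntervalTree] = {}
        self.spans: Dict[str, IntervalTree] = {}
        self.promoters: Dict[str, IntervalTree] = {}
        for g in genes:
            if g.chrom not in self.chrom_lengths:
                raise KeyError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            self.spans.setdefault(g.chrom, IntervalTree())[g.start:g.end] = g.gene_id
            for s, e in g.exons:
                if e > s:
                    self.exons.setdefault(g.chrom, IntervalTree())[s:e] = g.gene_id
            p = self._promoter_interval(g)
            if p is not None:
                self.promoters.setdefault(g.chrom, IntervalTree())[p[0]:p[1]] = g.gene_id
        # intergenic = maximal intervals not covered by any gene span or promoter
        self.intergenic: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, length in self.chrom_lengths.items():
            covered = IntervalTree()
            for tree in (self.spans.get(chrom), self.promoters.get(chrom)):
                if tree:
                    for iv in tree:
                        covered[iv.begin:iv.end] = None
            covered.merge_overlaps(strict=False)
            gaps, cursor = [], 0
            for iv in sorted(covered):
                if iv.begin > cursor:
                    gaps.append((cursor, iv.begin))
                cursor = max(cursor, iv.end)
            if cursor < length:
                gaps.append((cursor, length))
            self.intergenic[chrom] = gaps

    def _promoter_interval(self, g: GeneModel) -> Optional[Tuple[int, int]]:
        """Strand-aware [TSS - promoter_len, TSS) window, clipped to the
        chromosome; for minus-strand genes the window extends downstream in
        genome coordinates."""
        if g.strand == "+":
            s, e = g.start - self.promoter_len, g.start
        else:
            s, e = g.end, g.end + self.promoter_len
        s = max(0, s)
        e = min(self.chrom_lengths[g.chrom], e)
        return (s, e) if e > s else None

    def intergenic_owner(self, chrom: str, pos: int) -> str:
        for s, e in self.intergenic.get(chrom, []):
            if s <= pos < e:
                return f"intergenic:{chrom}:{s}-{e}"
        return f"intergenic:{chrom}:{pos}"  # site inside covered gap edge case

    def classify(self, chrom: str, pos: int) -> Tuple[str, str]:
        """(category, owner) for one position, applying the precedence
        exon > intron > promoter > intergenic."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"site chromosome {chrom} absent from annotation")
        hits = self.exons.get(chrom, IntervalTree())[pos]
        if hits:
            return "exon", min(iv.data for iv in hits)
        hits = self.spans.get(chrom, IntervalTree())[pos]
        if hits:  # inside a gene but not an exon
            return "intron", min(iv.data for iv in hits)
        hits = self.promoters.get(chrom, IntervalTree())[pos]
        if hits:
            return "promoter", min(iv.data for iv in hits)
        return "intergenic", self.intergenic_owner(chrom, pos)


def classify_regions(sites: Sequence[PutativeSite], genes: Sequence[GeneModel],
                     chrom_lengths: Mapping[str, int],
                     promoter_len: int = 5000,
                     index: Optional[GenomeAnnotationIndex] = None
                     ) -> List[RegionAnnotation]:
    """Classify every site; each gets exactly one category and one owner."""
    idx = index or GenomeAnnotationIndex(genes, chrom_lengths, promoter_len)
    return [RegionAnnotation(s, *idx.classify(s.chrom, s.position)) for s in sites]


def category_fractions(annotations: Sequence[RegionAnnotation]) -> Dict[str, float]:
    n = len(annotations)
    counts = Counter(a.category for a in annotations)
    return {c: (counts.get(c, 0) / n if n else 0.0) for c in CATEGORIES}


def genomic_baseline(index: GenomeAnnotationIndex) -> Dict[str, float]:
    """Base-coverage fractions of the four categories over the genome,
    computed from the supplied annotation (the neutral reference column)."""
    totals = {c: 0 for c in CATEGORIES}
    for chrom, length in index.chrom_lengths.items():
        exon = index.exons.get(chrom, IntervalTree())
        span = index.spans.get(chrom, IntervalTree())
        prom = index.promoters.get(chrom, IntervalTree())
        events: List[int] = sorted({0, length}
                                   | {b for iv in exon for b in (iv.begin, iv.end)}
                                   | {b for iv in span for b in (iv.begin, iv.end)}
                                   | {b for iv in prom for b in (iv.begin, iv.end)})
        for a, b in zip(events, events[1:]):
            if b <= a or a >= length:
                continue
            b = min(b, length)
            mid = a
            if exon[mid]:
                cat = "exon"
            elif span[mid]:
                cat = "intron"
            elif prom[mid]:
                cat = "promoter"
            else:
                cat = "intergenic"
            totals[cat] += b - a
    total = sum(totals.values())
    return {c: totals[c] / total if total else 0.0 for c in CATEGORIES}


def region_proportion_test(annotations: Sequence[RegionAnnotation],
                           baseline: Mapping[str, float]) -> float:
    """Chi-square goodness-of-fit p-value of library category counts against
    the genomic baseline proportions."""
    counts = Counter(a.category for a in annotations)
    obs = [counts.get(c, 0) for c in CATEGORIES]
    n = sum(obs)
    if n == 0:
        return 1.0
    exp = [max(baseline[c], 1e-12) * n for c in CATEGORIES]
    scale = n / sum(exp)
    exp = [e * scale for e in exp]
    return float(stats.chisquare(obs, exp).pvalue)


# ---------------------------------------------------------------------------
# Repeat and island composition
# ---------------------------------------------------------------------------

def summarize_repeats(intervals: Sequence[Tuple[str, int, int]],
                      repeats: Sequence[FeatureInterval],
                      islands: Sequence[FeatureInterval] = (),
                      site_positions: Sequence[Tuple[str, int]] = ()
                      ) -> CompositionReport:
    """Repeat-class composition of a set of sequence intervals.

    A sequence "has repetitive content" iff >=1 bp overlaps any repeat
    interval; per-class base fractions are overlapped bases over total
    sequence bases. Unknown class names fall into an "other" bin. When site
    positions are supplied, the CpG-island membership count/fraction is
    reported alongside.
    """
    rep_trees: Dict[str, IntervalTree] = {}
    for r in repeats:
        cls = r.name if r.name in REPEAT_CLASSES else "other"
        rep_trees.setdefault(r.chrom, IntervalTree())[r.start:r.end] = cls
    total_bases = sum(e - s for _c, s, e in intervals)
    class_bases: Dict[str, int] = {c: 0 for c in (*REPEAT_CLASSES, "other")}
    n_with = 0
    for chrom, s, e in intervals:
        tree = rep_trees.get(chrom)
        if tree is None:
            continue
        hits = tree[s:e]
        if hits:
            n_with += 1
        for iv in hits:
            class_bases[iv.data] += min(e, iv.end) - max(s, iv.begin)
    frac = {c: (class_bases[c] / total_bases if total_bases else 0.0)
            for c in class_bases}
    isl_trees: Dict[str, IntervalTree] = {}
    for isl in islands:
        isl_trees.setdefault(isl.chrom, IntervalTree())[isl.start:isl.end] = isl.name
    n_isl = sum(1 for chrom, pos in site_positions
                if isl_trees.get(chrom) and isl_trees[chrom][pos])
    return CompositionReport(
        n_sequences=len(intervals), n_with_repeat=n_with,
        class_base_fraction=frac, total_base_fraction=sum(frac.values()),
        n_in_island=n_isl,
        island_fraction=(n_isl / len(site_positions) if site_positions else 0.0))


# ---------------------------------------------------------------------------
# Set comparisons and coverage bins
# ---------------------------------------------------------------------------

def compare_site_sets(set_a: Iterable, set_b: Iterable,
                      key: str = "position") -> Tuple[Tuple[int, int, int],
                                                      Tuple[Set, Set, Set]]:
    """Exact (onlyA, shared, onlyB) partition of two site collections.

    ``key='position'`` compares (chrom, position, mark); ``key='owner-region'``
    compares owner identifiers from :class:`RegionAnnotation` inputs. Both
    inputs must use the same key.
    """
    def keyed(items: Iterable) -> Set:
        out = set()
        for x in items:
            if key == "position":
                site = x.site if isinstance(x, RegionAnnotation) else x
                out.add((site.chrom, site.position, site.mark))
            elif key == "owner-region":
                if not isinstance(x, RegionAnnotation):
                    raise ValueError("owner-region comparison needs annotated sites")
                out.add(x.owner)
            else:
                raise ValueError(f"unknown comparison key {key!r}")
        return out

    a, b = keyed(set_a), keyed(set_b)
    only_a, shared, only_b = a - b, a & b, b - a
    return (len(only_a), len(shared), len(only_b)), (only_a, shared, only_b)


def coverage_bins(sites: Sequence[PutativeSite],
                  chrom_lengths: Mapping[str, int],
                  bin_bp: int = 1_000_000) -> Dict[str, List[int]]:
    """Per-bin site counts under half-open binning (a site at an exact bin
    boundary falls in the higher bin). bedGraph-writable."""
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    bins = {chrom: [0] * ((length + bin_bp - 1) // bin_bp)
            for chrom, length in chrom_lengths.items()}
    for s in sites:
        bins[s.chrom][s.position // bin_bp] += 1
    return bins
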