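# Methods

## The model

Three enrichment chemistries are modeled as set logic over in-silico
restriction digests of a genome carrying a known per-cytosine mark track
(`none` / `5mC` / `5hmC`).

**Digestion kernel.** An enzyme is a recognition sequence (IUPAC), a cut
offset from the 5′ edge of a top-strand occurrence, and the set of marks
that block cleavage. A site is blocked iff *any* cytosine inside the
recognition footprint, on either strand, carries a blocking mark. The
literature says an "internal" modified cytosine inhibits cleavage without
pinning down the position, so footprint-wide blocking is the conservative
reading; it is configurable per enzyme through the registry TSV
(`src/methmap/data/enzymes.tsv`). Defaults: MspI (CCGG, blocked by 5hmC
only), HpaII (CCGG, blocked by both marks), FspBI (CTAG, insensitive),
BfaI (CTAG, blocked by 5hmC), TasI (/AATT, insensitive), AciI (CCGC) and
HinP1I (GCGC) treated like HpaII. Two registry choices deserve note: the
5hmC sensitivity of AciI and HinP1I is not established, so they default to
the fully sensitive behaviour of the cocktail they belong to; and HinP1I is
stored with the standard G^CGC offset even though the cut is sometimes
printed GC/GC — both are overridable. AciI is the only non-palindromic
recognition and is scanned on both strands. Occurrences containing N never
cut; zero-length fragments from coincident cuts are suppressed.

**RDA subtraction (Me-RDA / HMe-RDA).** Subtraction is modeled as ideal and
complete: a tester (insensitive-enzyme) fragment is enriched iff at least
one bounding cut position is absent from the driver (sensitive
isoschizomer) unblocked cut set. The large driver excess and long
hybridization of the wet protocol justify treating the exact set difference
as the limit behaviour; hybridization kinetics, the single mung-bean
nuclease digestion and PCR bias are deliberately outside the model.
Fragments touching a chromosome terminus are excluded by default (no second
adaptor can ligate there), and the validated amplicon window defaults to
100 bp – 1 kb inclusive. Because the tester itself is blocked by 5hmC at
CCGG, no Me-RDA fragment is ever bounded by a hydroxymethylated site —
an invariant the tests assert.

**HELP cocktail.** TasI fragments are computed on the plain sequence; a
fragment survives iff no cocktail enzyme has an unblocked cut strictly
inside it. Fragments without any internal cocktail occurrence survive the
chemistry but carry no methylation information; they are flagged and
removed by the downstream read filter, mirroring the published in-silico
filter. The same 100 bp – 1 kb window is applied for symmetry (no window is
stated for this chemistry; it is configurable).

**Sequencing stand-in.** Each enriched fragment is emitted `coverage` times
on a uniform random strand, with optional ligated adaptor sequences (the
default is the J-1B tester adaptor duplex) and i.i.d. substitution errors.
Indels, PCR duplicates and chimeras are out of scope.

## The identification pipeline

Reads are trimmed of leading/trailing adaptor occurrences (exact or one
mismatch, either orientation) and dropped below 50 bp. HELP reads lacking
every cocktail recognition on both strands are removed ("validated reads").
Clustering is greedy centroid assignment at ≥97% identity, processing reads
in decreasing length (ties by id) so the result is invariant under input
shuffling; identity is matching columns over alignment columns of an
end-gap-free global alignment (edlib), taken in the better orientation; the
consensus is the per-column majority over members aligned to the centroid
with ties resolved to the centroid base. This is a stated stand-in for
USEARCH, not a claim of bit-parity.

Placement uses an exact-seed (k = 16, non-overlapping windows plus the tail
window) ungapped aligner; on substitution-only reads gapped alignment
cannot change the outcome at the 92/92 thresholds, and a PSL reader is
provided for externally produced alignments. Thresholds are inclusive
(≥ 0.92) because the published rule discards alignments *below* 92%.
Placements overlapping more than 50% reciprocally are merged before
counting loci; contigs with more than one passing placement are discarded
entirely. Each end of a surviving placement is extended outward to the
nearest occurrence of the protocol's primary recognition (HpaII's CCGG for
Me-RDA, the CTAG of the BfaI/FspBI pair for HMe-RDA, TasI's AATT for HELP)
up to 1,000 bp inclusive, measured boundary to occurrence start; a capped
end is left unlabeled rather than dropping the record, which keeps the
other end usable. Labeling: Me-RDA marks the CpG cytosine inside each
end's CCGG as 5mC; HMe-RDA labels the cytosine of the CTAG occurrence as
5hmC (CTAG contains no CpG, so the published phrasing "the CpGs at both
ends" cannot apply literally to this chemistry); HELP labels every CpG
cytosine inside every cocktail occurrence strictly between the two bounding
TasI sites, requiring both ends to be identified. Calls are deduplicated on
(chrom, position, mark, method, stage) — the same position found by two
methods stays two records, since methods are compared downstream — and
every call is verified to sit inside a relevant recognition occurrence.

## Annotation and comparisons

Promoters are the strand-aware 5 kb window upstream of the TSS (downstream
in genome coordinates for minus-strand genes). Classification precedence is
exon > intron > promoter > intergenic: gene-body evidence outranks a
neighbouring gene's promoter window because the site physically lies in
transcribed sequence. Owners are the winning gene (ties to the smallest
gene id) or the enclosing maximal intergenic interval, so ownership is
total and unique. The genomic baseline column is computed by base coverage
from the supplied annotation, so synthetic runs produce their own neutral
reference. The library-versus-genome proportion comparison is a chi-square
goodness-of-fit (the original analysis does not name its test). Repeat
composition counts a sequence as repeat-containing at ≥1 bp overlap and
reports per-class base fractions; coverage tracks use half-open binning.

## q-PCR quantification

ΔCt = Ct(digested) − Ct(undigested) at equal input mass; the
digestion-resistant (marked) proportion is efficiency^(−ΔCt) with perfect
doubling (efficiency 2.0, configurable) — the standard transform, adopted
because the source text states only that ΔCt "was calculated for analysis
of the proportion". Values above 1 (negative ΔCt) are clamped and flagged.
Stages are compared per target with an exact two-sided Wilcoxon rank-sum
test: all C(n, n_a) label assignments of the pooled mid-ranks are
enumerated and the smaller tail doubled (capped at 1); beyond a combined
n of 12 a normal approximation is used with a warning. With the published
three pools per stage the exact floor is p = 0.1, so no 3-vs-3 comparison
can reach 0.05 — a property the tests demonstrate rather than hide.

## The synthetic genome generator

The generator emulates the feature classes the chemistries interact with:
background sequence at a configurable GC (default 0.42, a mammalian-like
value), CpG islands synthesized by locally raising GC (0.65) and planting
CG dinucleotides (~0.10/bp) rather than by Gardiner-Garden criteria — the
pipeline consumes island annotations, it does not call islands, so the BED
written at generation time is the ground truth; tandem satellite arrays of
a fixed arbitrary 23-mer ("SAT-like", no claim of sequence identity to any
real satellite); interspersed SINE/LINE/LTR-like elements as diverged
copies (2% substitutions) of a per-class consensus; and genes with exons
placed with promoter clearance. Coordinates are 0-based half-open
everywhere; GFF3 conversion happens only in the writer. Feature placement
is non-overlapping with bounded retries; an impossible request raises
rather than silently under-delivering.

Marks are drawn independently per cytosine from context-resolved
probabilities: CpG draws are made once per dinucleotide and mirrored to the
opposite strand (strand-symmetric, no hemimethylation); CHG/CHH cytosines
draw independently per strand; 5hmC at non-CpG cytosines is restricted to
CTAG occurrences, the context the TA-overhang chemistry reads out.
Repeat-class multipliers scale both probabilities inside annotated repeats
(renormalised if the pair would exceed 1), and named stages (D7/D12 in the
demo) override any field — the demo raises the CTAG-context 5hmC rate from
0.15 to 0.30 between stages, emulating a developmental gain of
hydroxymethylation in repeats. No quantitative context-specific mark rates
are established for this system, so the defaults are round placeholder
values and every test states its own rates. There is no spatial
autocorrelation of marks and no population-level partial methylation in the
fragment simulator (partial methylation is representable only at the
q-PCR level); passing tests therefore validate pipeline logic, not the
statistical texture of real methylomes.

## Reproducibility and problem sizes

A single global seed fans out to per-stage seeds salted with the stage name
(`derive_seed`), so any stage reruns in isolation; identical configs yield
byte-identical artifacts, asserted down to the output bytes. The test suite
checks digestion against an independent scan-every-position oracle on 200
random 10 kb sequences across all seven enzymes, RDA soundness and
completeness against a brute-force re-derivation on a 2 Mb genome, and
end-to-end Me-RDA recovery on a repeat-free 2 Mb genome at 5× error-free
coverage (p(5mC|CpG) = 0.3), where recall of truly marked bounding sites is
≥95% (measured 100%) and roughly half of all calls are unmarked partner
ends — the false-positive mode inherent to labeling both ends of a fragment
that needs only one blocked site to be enriched. `scripts/acceptance.py`
re-measures these quantities at megabase scale in a few seconds.

## Known limitations

Ideal subtraction (no kinetic model), substitution-only sequencing errors,
no star activity or partial digestion, greedy clustering rather than
USEARCH itself, ungapped placement (PSL import is the escape hatch for real
data), and independent per-cytosine marks. The q-PCR significance floor at
three pools per stage is a property of the exact test, not of this
implementation.
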