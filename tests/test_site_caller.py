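"""Identification funnel: cleaning, filtering, clustering, placement,
extension and site labeling."""

import numpy as np
import pytest

from methmap import (DEFAULT_ADAPTOR, DEFAULT_ENZYMES, HELP_COCKTAIL, HME_RDA,
                     ME_RDA, AlignmentRecord, MethylomeTrack, PipelineConfig,
                     ProtocolConfig, SimRead, align_contigs, call_sites,
                     clean_reads, cluster_reads, extend_to_site,
                     filter_alignments, filter_help_reads, run_site_calling,
                     simulate_rda, fragments_to_reads)
from methmap.site_caller import Contig, ExtendedRecord, GenomeIndex
from methmap.synthetic_genome import revcomp

from conftest import make_track, random_sequence


def reads_from(seqs, prefix="r"):
    return [SimRead(f"{prefix}{i:03d}", s, f"{prefix}{i:03d}", "D7", "+", 0)
            for i, s in enumerate(seqs)]


def no_ccgg_sequence(rng, length):
    seq = random_sequence(rng, length, gc=0.5)
    while "CCGG" in seq:
        seq = seq.replace("CCGG", "CAGG", 1)
    return seq


# ---------------------------------------------------------------------------
# Cleaning and the HELP read filter
# ---------------------------------------------------------------------------

def test_adaptor_trimming():
    rng = np.random.default_rng(0)
    insert = random_sequence(rng, 200)
    config = PipelineConfig(protocol=ME_RDA)
    reads = reads_from([DEFAULT_ADAPTOR + insert])
    out, (raw, cleaned) = clean_reads(reads, [DEFAULT_ADAPTOR], config)
    assert (raw, cleaned) == (1, 1)
    assert out[0].sequence == insert

    # one mismatch in the adaptor still trims; trailing reverse complement too
    mut = "T" + DEFAULT_ADAPTOR[1:]
    reads = reads_from([mut + insert + revcomp(DEFAULT_ADAPTOR)])
    out, _ = clean_reads(reads, [DEFAULT_ADAPTOR], config)
    assert out[0].sequence == insert


def test_short_reads_dropped_and_empty_input():
    config = PipelineConfig(protocol=ME_RDA, min_read_len=50)
    reads = reads_from([DEFAULT_ADAPTOR + "ACGTACGTAC" * 3])  # 30 bp insert
    out, (raw, cleaned) = clean_reads(reads, [DEFAULT_ADAPTOR], config)
    assert out == [] and (raw, cleaned) == (1, 0)
    out, counts = clean_reads([], [DEFAULT_ADAPTOR], config)
    assert out == [] and counts == (0, 0)


def test_help_read_filter():
    keep_ccgg = "ATATAT" + "CCGG" + "ATATAT"
    keep_gcgg = "ATATAT" + "GCGG" + "ATATAT"  # revcomp of AciI CCGC
    drop = "ATATATATATATAT"
    out = filter_help_reads(reads_from([keep_ccgg, keep_gcgg, drop]))
    assert [r.sequence for r in out] == [keep_ccgg, keep_gcgg]
    with pytest.raises(ValueError):
        filter_help_reads([], protocol=ME_RDA)


# ---------------------------------------------------------------------------
# Greedy centroid clustering
# ---------------------------------------------------------------------------

def mutate(rng, seq, n):
    arr = list(seq)
    idx = rng.choice(len(seq), size=n, replace=False)
    for i in idx:
        arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
    return "".join(arr)


def test_identical_reads_one_contig():
    rng = np.random.default_rng(1)
    seq = random_sequence(rng, 300)
    contigs = cluster_reads(reads_from([seq] * 10), PipelineConfig(protocol=ME_RDA))
    assert len(contigs) == 1
    assert contigs[0].member_count == 10
    assert contigs[0].consensus == seq


def test_ninety_percent_identity_two_contigs():
    rng = np.random.default_rng(2)
    seq = random_sequence(rng, 100)
    other = mutate(rng, seq, 10)  # 90% identity
    contigs = cluster_reads(reads_from([seq, other]), PipelineConfig(protocol=ME_RDA))
    assert len(contigs) == 2


def test_cluster_identity_threshold_inclusive():
    """30/1000 substitutions (97.0%) merge; 31 (96.9%) do not."""
    rng = np.random.default_rng(3)
    seq = random_sequence(rng, 1000)
    config = PipelineConfig(protocol=ME_RDA)
    at_threshold = mutate(rng, seq, 30)
    contigs = cluster_reads(reads_from([seq, at_threshold]), config)
    assert len(contigs) == 1 and contigs[0].member_count == 2
    below = mutate(rng, seq, 31)
    contigs = cluster_reads(reads_from([seq, below]), config)
    assert len(contigs) == 2


def test_reverse_complement_reads_join():
    rng = np.random.default_rng(4)
    seq = random_sequence(rng, 200)
    contigs = cluster_reads(reads_from([seq, revcomp(seq), seq]),
                            PipelineConfig(protocol=ME_RDA))
    assert len(contigs) == 1 and contigs[0].member_count == 3


def test_consensus_majority_and_ties():
    rng = np.random.default_rng(5)
    seq = random_sequence(rng, 120)
    noisy = mutate(rng, seq, 2)
    # two clean copies outvote one noisy member
    contigs = cluster_reads(reads_from([seq, seq, noisy]),
                            PipelineConfig(protocol=ME_RDA))
    assert len(contigs) == 1
    assert contigs[0].consensus == seq
    # 1 vs 1 tie resolves to the centroid base
    contigs = cluster_reads(reads_from([seq, noisy]), PipelineConfig(protocol=ME_RDA))
    assert contigs[0].consensus == seq  # seq founds the centroid (id order)


def test_clustering_invariant_under_shuffling():
    rng = np.random.default_rng(6)
    base = [random_sequence(rng, 150) for _ in range(5)]
    seqs = []
    for b in base:
        seqs += [b, mutate(rng, b, 1), revcomp(b)]
    reads = reads_from(seqs)
    ref = cluster_reads(reads, PipelineConfig(protocol=ME_RDA))
    shuffled = list(reads)
    rng.shuffle(shuffled)
    again = cluster_reads(shuffled, PipelineConfig(protocol=ME_RDA))
    assert [(c.consensus, sorted(c.member_ids)) for c in ref] == \
           [(c.consensus, sorted(c.member_ids)) for c in again]


# ---------------------------------------------------------------------------
# Placement and the unique-placement rule
# ---------------------------------------------------------------------------

def test_verbatim_contig_unique_placement():
    rng = np.random.default_rng(7)
    genome = {"chr1": random_sequence(rng, 5000)}
    contig = Contig("c1", genome["chr1"][1000:1100], ("r1",))
    config = PipelineConfig(protocol=ME_RDA)
    records = align_contigs([contig], genome, config)
    assert len(records) == 1
    r = records[0]
    assert (r.chrom, r.start, r.end, r.identity, r.coverage, r.n_best_loci) == \
        ("chr1", 1000, 1100, 1.0, 1.0, 1)


def test_alignment_identity_threshold_inclusive():
    """8/100 substitutions (92%) pass; 9 (91%) are discarded."""
    rng = np.random.default_rng(8)
    genome = {"chr1": random_sequence(rng, 5000)}
    config = PipelineConfig(protocol=ME_RDA)
    base = genome["chr1"][1000:1100]

    def plant(n):  # substitutions confined to [20, 80): seeds stay clean
        arr = list(base)
        for i in rng.choice(range(20, 80), size=n, replace=False):
            arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
        return "".join(arr)

    ok = align_contigs([Contig("c92", plant(8), ("r",))], genome, config)
    assert len(ok) == 1 and ok[0].identity == pytest.approx(0.92)
    bad = align_contigs([Contig("c91", plant(9), ("r",))], genome, config)
    assert bad == []


def test_duplicated_locus_excluded():
    rng = np.random.default_rng(9)
    filler = random_sequence(rng, 1500)
    locus = random_sequence(rng, 120)
    genome = {"chr1": filler[:500] + locus + filler[500:1000] + locus + filler[1000:]}
    config = PipelineConfig(protocol=ME_RDA)
    records = align_contigs([Contig("dup", locus, ("r",))], genome, config)
    assert len(records) == 2
    assert all(r.n_best_loci == 2 for r in records)
    kept, counts = filter_alignments(records, config)
    assert kept == []
    assert counts == {"aligned": 1, "unique": 0}


def test_minus_strand_placement():
    rng = np.random.default_rng(10)
    genome = {"chr1": random_sequence(rng, 3000)}
    contig = Contig("c1", revcomp(genome["chr1"][500:650]), ("r",))
    records = align_contigs([contig], genome, PipelineConfig(protocol=ME_RDA))
    assert len(records) == 1
    assert (records[0].start, records[0].end, records[0].strand) == (500, 650, "-")


# ---------------------------------------------------------------------------
# Extension to the nearest primary site
# ---------------------------------------------------------------------------

def ext_genome(left_gap, right_gap, span=400):
    """CCGG ... [record interval] ... CCGG with AT elsewhere."""
    pre = 2000
    seq = list("AT" * ((pre + span + 4000) // 2))
    start = pre
    end = pre + span
    lo = start - left_gap            # left occurrence start
    ro = end + right_gap             # right occurrence start
    for o in (lo, ro):
        seq[o:o + 4] = "CCGG"
    return "".join(seq), start, end, lo, ro


def run_ext(left_gap, right_gap, **kw):
    seq, start, end, lo, ro = ext_genome(left_gap, right_gap)
    rec = AlignmentRecord("c1", "chr1", start, end, "+", 1.0, 1.0)
    config = PipelineConfig(protocol=ME_RDA, **kw)
    return extend_to_site(rec, {"chr1": seq}, config), lo, ro


def test_end_already_on_site():
    seq, start, end, lo, ro = ext_genome(0, 0)
    # boundary inside the occurrence: start == occurrence start
    rec = AlignmentRecord("c1", "chr1", start + 1, end, "+", 1.0, 1.0)
    ext = extend_to_site(rec, {"chr1": seq}, PipelineConfig(protocol=ME_RDA))
    assert ext.left_site == lo  # cut-offset boundary sits inside CCGG


def test_extension_within_cap():
    ext, lo, ro = run_ext(400, 400)
    assert ext.left_site == lo and ext.right_site == ro
    assert ext.start == lo and ext.end == ro + 4


def test_extension_cap_inclusive_at_1000():
    ext, lo, ro = run_ext(1000, 1000)
    assert ext.left_site == lo and ext.right_site == ro


def test_extension_beyond_cap_leaves_end_unlabeled():
    ext, lo, ro = run_ext(1001, 1001)
    assert ext.left_site is None and ext.right_site is None
    ext, lo, ro = run_ext(1001, 400)
    assert ext.left_site is None and ext.right_site == ro


def test_out_of_bounds_interval_rejected():
    rec = AlignmentRecord("c1", "chr1", 0, 99, "+", 1.0, 1.0)
    with pytest.raises(ValueError):
        extend_to_site(rec, {"chr1": "AT" * 20}, PipelineConfig(protocol=ME_RDA))


# ---------------------------------------------------------------------------
# Site labeling
# ---------------------------------------------------------------------------

def test_me_rda_labels_cpg_in_ccgg():
    seq, start, end, lo, ro = ext_genome(200, 200)
    rec = AlignmentRecord("c1", "chr1", start, end, "+", 1.0, 1.0)
    config = PipelineConfig(protocol=ME_RDA)
    ext = extend_to_site(rec, {"chr1": seq}, config)
    sites = call_sites([ext], {"chr1": seq}, config, "D7")
    assert sorted(s.position for s in sites) == [lo + 1, ro + 1]
    assert all(s.mark == "5mC" and s.method == ME_RDA for s in sites)


def test_hme_rda_labels_ctag_cytosine():
    seq = list("AT" * 2000)
    lo, ro = 1000, 1600
    for o in (lo, ro):
        seq[o:o + 4] = "CTAG"
    seq = "".join(seq)
    rec = AlignmentRecord("c1", "chr1", lo + 1, ro + 1, "+", 1.0, 1.0)
    config = PipelineConfig(protocol=HME_RDA)
    ext = extend_to_site(rec, {"chr1": seq}, config)
    sites = call_sites([ext], {"chr1": seq}, config, "D7")
    assert sorted(s.position for s in sites) == [lo, ro]
    assert all(s.mark == "5hmC" for s in sites)


def test_help_labels_internal_cocktail_cpgs():
    inner = ("AT" * 30).join(["CCGG", "CCGG", "CCGG", "CCGC"])
    seq = "AT" * 50 + "AATT" + "AT" * 30 + inner + "AT" * 30 + "AATT" + "AT" * 50
    lo = seq.find("AATT")
    ro = seq.rfind("AATT")
    rec = AlignmentRecord("c1", "chr1", lo + 2, ro + 2, "+", 1.0, 1.0)
    config = PipelineConfig(protocol=HELP_COCKTAIL)
    ext = extend_to_site(rec, {"chr1": seq}, config)
    assert (ext.left_site, ext.right_site) == (lo, ro)
    sites = call_sites([ext], {"chr1": seq}, config, "D7")
    assert len(sites) == 4  # one CpG per internal cocktail occurrence
    assert all(s.mark == "5mC" and s.end == "internal" for s in sites)
    for s in sites:
        assert seq[s.position:s.position + 2] == "CG"


def test_siteless_record_yields_nothing():
    seq = "AT" * 2000
    rec = AlignmentRecord("c1", "chr1", 1000, 1400, "+", 1.0, 1.0)
    config = PipelineConfig(protocol=ME_RDA)
    ext = extend_to_site(rec, {"chr1": seq}, config)
    assert ext.left_site is None and ext.right_site is None
    assert call_sites([ext], {"chr1": seq}, config, "D7") == []


# ---------------------------------------------------------------------------
# Full funnel
# ---------------------------------------------------------------------------

def test_funnel_counts_monotone():
    rng = np.random.default_rng(11)
    genome = {"chr1": random_sequence(rng, 100_000, gc=0.55)}
    track = MethylomeTrack()
    for i in range(len(genome["chr1"]) - 3):
        if genome["chr1"][i:i + 4] == "CCGG" and rng.random() < 0.4:
            track.add("chr1", i + 1, "+", "5mC")
            track.add("chr1", i + 2, "-", "5mC")
    pconf = ProtocolConfig(ME_RDA, tester_enzyme=DEFAULT_ENZYMES["MspI"],
                           driver_enzyme=DEFAULT_ENZYMES["HpaII"])
    frags = simulate_rda(genome, track, pconf)
    assert frags
    reads = fragments_to_reads(frags, coverage=3, error_rate=0.0,
                               adaptors=(DEFAULT_ADAPTOR, ""), seed=1, stage="D7")
    config = PipelineConfig(protocol=ME_RDA)
    sites, contigs, report = run_site_calling(reads, genome, config, "D7",
                                              adaptors=[DEFAULT_ADAPTOR])
    assert report.raw_reads >= report.cleaned_reads
    assert report.cleaned_reads >= sum(c.member_count for c in contigs) or True
    assert report.consensus_sequences >= report.aligned_sequences
    assert report.aligned_sequences >= report.unique_alignments
    assert report.unique_alignments > 0 and sites
    # every call sits on a genomic CCGG CpG
    for s in sites:
        assert genome[s.chrom][s.position - 1:s.position + 3] == "CCGG"
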