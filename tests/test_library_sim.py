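"""Enrichment chemistry simulators: RDA subtraction logic, HELP retention,
read emission."""

import numpy as np
import pytest

from methmap import (DEFAULT_ENZYMES, HELP_COCKTAIL, HME_RDA, ME_RDA,
                     MethylomeTrack, ProtocolConfig, fragments_to_reads,
                     simulate_help, simulate_rda)
from methmap.synthetic_genome import revcomp

from conftest import make_track, random_sequence, random_track


def me_rda_config(**kw):
    return ProtocolConfig(ME_RDA, tester_enzyme=DEFAULT_ENZYMES["MspI"],
                          driver_enzyme=DEFAULT_ENZYMES["HpaII"], **kw)


def hme_rda_config(**kw):
    return ProtocolConfig(HME_RDA, tester_enzyme=DEFAULT_ENZYMES["FspBI"],
                          driver_enzyme=DEFAULT_ENZYMES["BfaI"], **kw)


def help_config(**kw):
    return ProtocolConfig(HELP_COCKTAIL, frequent_cutter=DEFAULT_ENZYMES["TasI"],
                          cocktail=[DEFAULT_ENZYMES["HpaII"], DEFAULT_ENZYMES["AciI"],
                                    DEFAULT_ENZYMES["HinP1I"]], **kw)


def spaced_ccgg_genome(spacings, pad=400):
    """Genome with CCGG sites separated by AT-only spacers of the given
    lengths (so the only CpGs are inside the CCGG occurrences)."""
    parts = ["AT" * (pad // 2)]
    positions = []
    pos = pad
    for gap in spacings:
        positions.append(pos)
        parts.append("CCGG")
        parts.append("AT" * (gap // 2))
        pos += 4 + gap
    positions.append(pos)
    parts.append("CCGG")
    parts.append("AT" * (pad // 2))
    return "".join(parts), positions


def test_rda_middle_site_marked():
    """Only the two fragments flanking a 5mC-marked site are enriched."""
    seq, pos = spaced_ccgg_genome([200, 300, 250, 250])
    mid = pos[2]
    track = make_track([("chr1", mid + 1, "+", "5mC"), ("chr1", mid + 2, "-", "5mC")])
    out = simulate_rda({"chr1": seq}, track, me_rda_config())
    got = sorted((f.fragment.start, f.fragment.end) for f in out)
    # MspI cuts at offset 1 of every CCGG (5mC does not block the tester)
    expect = sorted([(pos[1] + 1, pos[2] + 1), (pos[2] + 1, pos[3] + 1)])
    assert got == expect
    for f in out:
        assert "5mC" in (f.true_left_mark, f.true_right_mark)
        assert "5hmC" not in (f.true_left_mark, f.true_right_mark)


def test_rda_unmethylated_genome_yields_nothing():
    seq, _ = spaced_ccgg_genome([200, 300, 250])
    out = simulate_rda({"chr1": seq}, MethylomeTrack(), me_rda_config())
    assert out == []


def test_rda_5hmc_blocks_tester_too():
    """A 5hmC-bearing CCGG blocks MspI itself: the neighbours merge and the
    site never bounds an enriched fragment."""
    seq, pos = spaced_ccgg_genome([200, 300, 250, 250])
    mid = pos[2]
    track = make_track([("chr1", mid + 1, "+", "5hmC"), ("chr1", mid + 2, "-", "5hmC")])
    out = simulate_rda({"chr1": seq}, track, me_rda_config())
    # merged fragment spans the blocked site but is bounded by unmarked
    # sites cut by both enzymes -> not enriched; nothing else is marked
    assert out == []
    # with a second, 5mC-marked site the merged fragment can be enriched,
    # but no bounding footprint ever carries 5hmC
    track2 = make_track([("chr1", mid + 1, "+", "5hmC"), ("chr1", mid + 2, "-", "5hmC"),
                         ("chr1", pos[1] + 1, "+", "5mC"), ("chr1", pos[1] + 2, "-", "5mC")])
    out2 = simulate_rda({"chr1": seq}, track2, me_rda_config())
    assert out2
    for f in out2:
        assert "5hmC" not in (f.true_left_mark, f.true_right_mark)
        assert "5mC" in (f.true_left_mark, f.true_right_mark)


def test_rda_size_window_and_terminal_exclusion():
    seq, pos = spaced_ccgg_genome([60, 1500, 300])  # too short, too long, ok
    track = make_track(
        [e for p in pos for e in (("chr1", p + 1, "+", "5mC"), ("chr1", p + 2, "-", "5mC"))])
    out = simulate_rda({"chr1": seq}, track, me_rda_config())
    lengths = sorted(f.length for f in out)
    assert lengths == [304]  # only the in-window internal fragment
    out_all = simulate_rda({"chr1": seq}, track,
                           me_rda_config(size_window=(1, 10_000),
                                         exclude_terminal_fragments=False))
    assert len(out_all) == 5  # every fragment now qualifies


def test_rda_tester_driver_mismatch_rejected():
    with pytest.raises(ValueError, match="isoschizomer"):
        ProtocolConfig(ME_RDA, tester_enzyme=DEFAULT_ENZYMES["MspI"],
                       driver_enzyme=DEFAULT_ENZYMES["BfaI"]).validate()


@pytest.mark.parametrize("seed", range(4))
def test_me_rda_matches_brute_force(seed):
    """Soundness/completeness against an independent re-derivation."""
    rng = np.random.default_rng(seed)
    seq = random_sequence(rng, 20_000, gc=0.6)
    track = random_track(rng, seq, n_marks=300)
    entries = {(p, s): m for _c, p, s, m in track}
    config = me_rda_config()
    got = sorted((f.fragment.start, f.fragment.end)
                 for f in simulate_rda({"chr1": seq}, track, config))

    # brute force: scan CCGG occurrences by hand, derive both cut sets
    occs = [i for i in range(len(seq) - 3) if seq[i:i + 4] == "CCGG"]

    def blocked(o, marks):
        return any(entries.get((o + d, s)) in marks
                   for d in range(4) for s in "+-")

    mspi_cuts = [o + 1 for o in occs if not blocked(o, {"5hmC"})]
    hpaii_cuts = {o + 1 for o in occs if not blocked(o, {"5mC", "5hmC"})}
    bounds = [0] + mspi_cuts + [len(seq)]
    expect = []
    for a, b in zip(bounds, bounds[1:]):
        if a == 0 or b == len(seq):
            continue  # terminal
        if not 100 <= b - a <= 1000:
            continue
        if a not in hpaii_cuts or b not in hpaii_cuts:
            expect.append((a, b))
    assert got == sorted(expect)


def test_hme_rda_enriched_fragments_carry_5hmc():
    rng = np.random.default_rng(12)
    seq = random_sequence(rng, 20_000, gc=0.45)
    # mark cytosines of some CTAG occurrences with 5hmC
    occs = [i for i in range(len(seq) - 3) if seq[i:i + 4] == "CTAG"]
    track = MethylomeTrack()
    for o in occs[::3]:
        track.add("chr1", o, "+", "5hmC")
    out = simulate_rda({"chr1": seq}, track, hme_rda_config())
    assert out
    for f in out:
        assert "5hmC" in (f.true_left_mark, f.true_right_mark)


# ---------------------------------------------------------------------------
# HELP cocktail
# ---------------------------------------------------------------------------

def build_tasi_fragment(internal, pad=100):
    """AATT ... internal cocktail sites ... AATT with AT spacers."""
    mid = ("AT" * (pad // 2)).join(internal)
    return "AT" * 20 + "AATT" + "AT" * (pad // 2) + mid + "AT" * (pad // 2) \
        + "AATT" + "AT" * 20


def test_help_retention_rules():
    # one 5mC-marked CCGG inside -> retained, no_internal_site False
    seq = build_tasi_fragment(["CCGG"])
    o = seq.find("CCGG")
    track = make_track([("chr1", o + 1, "+", "5mC"), ("chr1", o + 2, "-", "5mC")])
    out = simulate_help({"chr1": seq}, track, help_config(size_window=(50, 2000)))
    assert len(out) == 1 and out[0].no_internal_site is False
    assert (o + 1, "5mC") in out[0].internal_site_marks

    # same fragment unmarked -> cocktail cuts inside -> removed
    out2 = simulate_help({"chr1": seq}, MethylomeTrack(),
                         help_config(size_window=(50, 2000)))
    assert out2 == []

    # no cocktail occurrence at all -> retained but flagged uninformative
    seq3 = build_tasi_fragment([])
    out3 = simulate_help({"chr1": seq3}, MethylomeTrack(),
                         help_config(size_window=(50, 2000)))
    assert len(out3) == 1 and out3[0].no_internal_site is True


def test_help_monotone_in_methylation():
    """Adding a mark never removes a retained fragment."""
    rng = np.random.default_rng(5)
    seq = random_sequence(rng, 15_000, gc=0.5)
    track = random_track(rng, seq, n_marks=100)
    config = help_config()
    base = {f.id for f in simulate_help({"chr1": seq}, track, config)}
    # add one more 5mC at a fresh cytosine
    for i, b in enumerate(seq):
        if b == "C" and track.get("chr1", i, "+") is None:
            track.add("chr1", i, "+", "5mC")
            break
    more = {f.id for f in simulate_help({"chr1": seq}, track, config)}
    assert base <= more


def test_help_wrong_protocol_rejected():
    with pytest.raises(ValueError):
        simulate_help({}, MethylomeTrack(), me_rda_config())


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

def _some_fragments(n=10):
    seq, pos = spaced_ccgg_genome([300] * n)
    track = make_track(
        [e for p in pos for e in (("chr1", p + 1, "+", "5mC"), ("chr1", p + 2, "-", "5mC"))])
    return simulate_rda({"chr1": seq}, track, me_rda_config())


def test_error_free_reads_match_fragment():
    frags = _some_fragments()
    reads = fragments_to_reads(frags, coverage=1, error_rate=0.0, seed=1)
    by_id = {f.id: f.sequence for f in frags}
    for r in reads:
        frag_seq = by_id[r.source_fragment_id]
        assert r.sequence in (frag_seq, revcomp(frag_seq))
        assert (r.sequence == frag_seq) == (r.strand == "+")


def test_read_counting_and_adaptors():
    frags = _some_fragments(10)
    assert len(frags) == 10
    reads = fragments_to_reads(frags, coverage=5, error_rate=0.0,
                               adaptors=("ACGTACGT", "TTTTCCCC"), seed=2)
    assert len(reads) == 50
    assert all(r.sequence.startswith("ACGTACGT") and r.sequence.endswith("TTTTCCCC")
               for r in reads)
    assert fragments_to_reads([], coverage=5, seed=0) == []


def test_substitution_rate_binomial():
    frags = _some_fragments(4)
    reads = fragments_to_reads(frags, coverage=250, error_rate=0.01, seed=3)
    lengths = np.array([len(r.sequence) for r in reads])
    errors = np.array([r.n_errors for r in reads])
    expected = float(np.sum(lengths) * 0.01)
    se = np.sqrt(np.sum(lengths) * 0.01 * 0.99)
    assert abs(errors.sum() - expected) <= 3 * se
    # determinism under seed
    again = fragments_to_reads(frags, coverage=250, error_rate=0.01, seed=3)
    assert [r.sequence for r in again] == [r.sequence for r in reads]


def test_error_rate_bounds():
    with pytest.raises(ValueError):
        fragments_to_reads([], coverage=1, error_rate=0.5, seed=0)
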