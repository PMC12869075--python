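import pytest

from ncs_atlas.rlfs import RIZ, extend_rez, find_riz, riz_records, scan_rlfs
from ncs_atlas.seqio import NucleotideSequence, reverse_complement

from oracles import random_dna, rez_oracle, riz_oracle, rlfs_oracle


def test_find_riz_m2_only_example():
    out = find_riz("GGGGAGGGG")
    assert len(out) == 1
    riz = out[0]
    assert (riz.start, riz.end, riz.model, riz.tract_count) == (0, 9, "m2", 2)
    assert riz.g_fraction == pytest.approx(8 / 9)


def test_find_riz_m1_three_tracts():
    out = find_riz("GGGTGGGTGGG")
    assert [(r.start, r.end, r.model) for r in out] == [(0, 11, "m1")]


def test_find_riz_gap_limit():
    # 11-nt gap breaks the chain; 10 nt is admissible (G fraction stays >= 50%)
    assert find_riz("GGGGGG" + "A" * 11 + "GGGGGG") == []
    assert len(find_riz("GGGGGG" + "A" * 10 + "GGGGGG")) == 1


def test_find_riz_g_fraction_floor():
    # chaining across a 10-nt gap would drop G fraction below 50%
    s = "GGGG" + "A" * 10 + "GGGG"  # 8 G / 18 nt < 50%
    assert find_riz(s) == []


def test_riz_oracle_equivalence(rng):
    for _ in range(60):
        s = random_dna(rng, int(rng.integers(100, 400)), gc=0.6)
        got = [(r.start, r.end, r.model) for r in find_riz(s)]
        assert got == riz_oracle(s), s


def _riz_for(seq_prefix):
    riz = find_riz(seq_prefix)
    assert riz, "constructed RIZ not detected"
    return riz[0]


def test_extend_rez_g_block_then_a_run():
    # an 11-nt gap keeps the G block out of the RIZ chain
    s = "GGGGAGGGG" + "A" * 11 + "G" * 100 + "A" * 500
    riz = _riz_for(s)
    assert (riz.start, riz.end) == (0, 9)
    rez = extend_rez(s, riz)
    want = rez_oracle(s, riz.end)
    assert (rez.start, rez.end) == want
    # maximal end is set by the whole-window 40% G bound: 100 G / 250 nt
    assert (rez.start, rez.end) == (20, 270)
    assert rez.g_fraction == pytest.approx(0.4)


def test_extend_rez_none_without_qualifying_window():
    s = "GGGGAGGGG" + "A" * 300
    riz = _riz_for(s)
    assert extend_rez(s, riz) is None
    assert rez_oracle(s, riz.end) is None


def test_extend_rez_none_when_too_close_to_end():
    s = "GGGGAGGGG" + "G" * 50  # < 100 nt downstream
    riz = find_riz(s)[0]
    assert extend_rez(s, riz) is None


def test_extend_rez_matches_window_oracle(rng):
    for _ in range(25):
        s = random_dna(rng, 500, gc=0.55)
        for riz in find_riz(s):
            got = extend_rez(s, riz)
            want = rez_oracle(s, riz.end)
            if want is None:
                assert got is None
            else:
                assert (got.start, got.end) == want


def test_extend_rez_monotone_under_downstream_g():
    s = "GGGGAGGGG" + "ATAT" * 20 + "GGAT" * 30
    riz = _riz_for(s)
    base = extend_rez(s, riz)
    extended = extend_rez(s + "G" * 200, riz)
    assert extended is not None
    if base is not None:
        assert extended.end >= base.end


TOY = "GGGGAGGGG" + "ATATATATAT" + "GGAT" * 30 + "T" * 60


def test_scan_rlfs_constructed_positive():
    locus = NucleotideSequence("toy", TOY)
    records = scan_rlfs(locus)
    assert [r.strand for r in records] == ["+"]
    r = records[0]
    assert r.start == 0
    assert (r.detail.riz_start, r.detail.riz_end, r.detail.model) == (0, 9, "m2")
    assert r.detail.linker_len == r.detail.rez_start - r.detail.riz_end


def test_scan_rlfs_strand_symmetry():
    locus = NucleotideSequence("toy", TOY)
    rc = NucleotideSequence("toy_rc", reverse_complement(TOY))
    fwd = scan_rlfs(locus)
    rev = scan_rlfs(rc)
    assert [r.strand for r in rev] == ["-"]
    assert (rev[0].start, rev[0].end) == (locus.length - fwd[0].end, locus.length - fwd[0].start)
    assert rev[0].sequence == fwd[0].sequence


def _g_skewed_dna(rng, length):
    # G-biased background so initiation and elongation zones actually occur
    return "".join(rng.choice(list("ACGT"), size=length, p=[0.18, 0.12, 0.45, 0.25]))


def test_scan_rlfs_matches_brute_force_oracle(rng):
    for _ in range(15):
        s = _g_skewed_dna(rng, 500)
        got = [(r.start, r.end, r.detail.model) for r in scan_rlfs(NucleotideSequence("s", s)) if r.strand == "+"]
        want = [(a, b, model) for a, b, model, _, _ in rlfs_oracle(s)]
        assert sorted(got) == sorted(want)


def test_emitted_records_satisfy_all_zone_constraints(rng):
    checked = 0
    for _ in range(10):
        s = _g_skewed_dna(rng, 600)
        locus = NucleotideSequence("s", s)
        for r in scan_rlfs(locus):
            d = r.detail
            strand_seq = s if r.strand == "+" else reverse_complement(s)
            n = len(s)
            if r.strand == "+":
                riz_seq = strand_seq[d.riz_start : d.riz_end]
                rez_seq = strand_seq[d.rez_start : d.rez_end]
            else:
                riz_seq = strand_seq[n - d.riz_end : n - d.riz_start]
                rez_seq = strand_seq[n - d.rez_end : n - d.rez_start]
            assert 0 <= d.linker_len <= 50
            assert 100 <= len(rez_seq) <= 2000
            assert 2 * riz_seq.count("G") >= len(riz_seq)
            assert 5 * rez_seq.count("G") >= 2 * len(rez_seq)
            tract_min, count_min = (3, 3) if d.model == "m1" else (4, 2)
            assert d.tract_count >= count_min
            assert riz_seq.startswith("G" * tract_min) and riz_seq.endswith("G" * tract_min)
            checked += 1
    assert checked > 0


def test_riz_records_mirror_details():
    locus = NucleotideSequence("toy", TOY)
    rlfs = scan_rlfs(locus)
    rizs = riz_records(rlfs)
    assert [(z.start, z.end) for z in rizs] == [(r.detail.riz_start, r.detail.riz_end) for r in rlfs]
    assert all(z.motif_class == "RIZ" for z in rizs)
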