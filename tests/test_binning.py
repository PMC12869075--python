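import numpy as np
import pytest
from scipy import stats

from ncs_atlas.binning import (
    bin_counts, cooccurrence_sets, coverage_profile, make_bins, pearson,
)
from ncs_atlas.motifs import MotifRecord

from oracles import coverage_oracle, pearson_oracle


def _motifs(intervals, cls="G4", strand="+"):
    return [MotifRecord(cls, s, e, strand, "") for s, e in intervals]


def test_coverage_example_and_empty():
    depth = coverage_profile(_motifs([(0, 10), (5, 15)]), 20)
    assert list(depth[:20]) == [1] * 5 + [2] * 5 + [1] * 5 + [0] * 5
    assert not coverage_profile([], 20).any()


def test_coverage_matches_membership_oracle_and_conserves_mass(rng):
    for _ in range(15):
        n = 200
        intervals = []
        for _ in range(rng.integers(0, 20)):
            s = int(rng.integers(0, n - 1))
            e = int(rng.integers(s + 1, n + 1))
            intervals.append((s, e))
        depth = coverage_profile(_motifs(intervals), n)
        assert np.array_equal(depth, coverage_oracle(intervals, n))
        assert depth.sum() == sum(e - s for s, e in intervals)


def test_make_bins_examples():
    bins = make_bins(1000, 100)
    assert len(bins) == 100 and all(b.end - b.start == 10 for b in bins)
    bins = make_bins(1005, 100)
    assert [b.end - b.start for b in bins[:-1]] == [10] * 99
    assert bins[-1].end - bins[-1].start == 15


def test_make_bins_tile_exactly(rng):
    for _ in range(20):
        length = int(rng.integers(100, 5000))
        n = int(rng.integers(1, 100))
        bins = make_bins(length, n)
        assert bins[0].start == 0 and bins[-1].end == length
        assert all(a.end == b.start for a, b in zip(bins, bins[1:]))
        assert [b.index for b in bins] == list(range(1, n + 1))
    with pytest.raises(ValueError):
        make_bins(10, 11)


def test_bin_counts_start_anchor_and_conservation():
    bins = make_bins(100, 10)
    motifs = _motifs([(20, 25), (29, 60), (99, 100)])  # second spans bins 3-6
    counts = bin_counts(motifs, bins)
    assert list(counts) == [0, 0, 2, 0, 0, 0, 0, 0, 0, 1]
    assert counts.sum() == len(motifs)


def test_bin_counts_strand_filter():
    bins = make_bins(100, 10)
    motifs = _motifs([(5, 10)], strand="+") + _motifs([(15, 20)], strand="-")
    assert bin_counts(motifs, bins).sum() == 2
    assert list(bin_counts(motifs, bins, strand="-")) == [0, 1] + [0] * 8


def test_cooccurrence_degenerate_cases():
    a = np.array([1, 0, 2, 0])
    sets = cooccurrence_sets({"x": a, "y": np.zeros(4, dtype=int)})
    assert sets[frozenset({"x"})] == 2 and sets[frozenset()] == 2
    sets = cooccurrence_sets({"x": a, "y": a})
    assert sets[frozenset({"x", "y"})] == 2 and sets[frozenset({"x"})] == 0
    assert len(sets) == 4  # every Venn cell reported, empty ones as 0


def test_cooccurrence_matches_set_algebra(rng):
    for _ in range(20):
        counts = {c: rng.integers(0, 3, size=50) for c in ("A", "B", "C")}
        sets = cooccurrence_sets(counts)
        assert sum(sets.values()) == 50
        # brute-force set algebra
        present = {c: {i for i in range(50) if counts[c][i] > 0} for c in counts}
        for key, n in sets.items():
            cell = set(range(50))
            for c in counts:
                cell &= present[c] if c in key else (set(range(50)) - present[c])
            assert len(cell) == n


def test_pearson_examples_and_errors(rng):
    x = rng.normal(size=30)
    assert pearson(x, x).r == pytest.approx(1.0)
    assert pearson(x, -x).r == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="constant"):
        pearson(x, np.zeros(30))
    with pytest.raises(ValueError, match="at least 3"):
        pearson([1, 2], [3, 4])


def test_pearson_matches_formula_and_t_test(rng):
    x = rng.normal(size=40)
    y = 0.5 * x + rng.normal(size=40)
    res = pearson(x, y)
    assert res.r == pytest.approx(pearson_oracle(x, y))
    t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
    assert res.p == pytest.approx(2 * stats.t.sf(abs(t), res.n - 2))


def test_pearson_symmetry_and_affine_invariance(rng):
    x = rng.normal(size=25)
    y = rng.normal(size=25)
    assert pearson(x, y).r == pytest.approx(pearson(y, x).r)
    assert pearson(3.0 * x + 7.0, y).r == pytest.approx(pearson(x, y).r)
    assert pearson(-2.0 * x + 1.0, y).r == pytest.approx(-pearson(x, y).r)
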