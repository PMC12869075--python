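import numpy as np
import pytest

from ncs_atlas.binning import make_bins, bin_counts
from ncs_atlas.gc import base_composition
from ncs_atlas.motifs import MotifRecord
from ncs_atlas.regions import assign_to_regions, summarize_regions, summary_frame
from ncs_atlas.signal import bin_signal, correlate_signal
from ncs_atlas.synth import (
    MotifPlant, RegionPlan, SyntheticLocusSpec, default_locus_spec, generate_locus,
    generate_signal, recovered_plants,
)


def test_determinism_byte_identical(small_spec):
    l1, r1, t1 = generate_locus(small_spec, 42)
    l2, r2, t2 = generate_locus(small_spec, 42)
    assert l1.residues == l2.residues
    assert r1 == r2
    assert t1.planted == t2.planted
    l3, _, _ = generate_locus(small_spec, 43)
    assert l3.residues != l1.residues


def test_regions_partition_and_gc_targets(small_spec):
    locus, regions, _ = generate_locus(small_spec, 7)
    assert regions[0].start == 0 and regions[-1].end == locus.length
    for plan, region in zip(small_spec.regions, regions):
        got = base_composition(locus.residues[region.start : region.end]).gc_percent
        # 600+ nt per region; planted motifs perturb composition slightly
        assert abs(got - 100 * plan.gc) < 6.0


def test_gc_target_recovery_within_two_points_at_10kb():
    spec = SyntheticLocusSpec([RegionPlan("r", 10000, 0.62)], [])
    for seed in range(5):
        locus, _, _ = generate_locus(spec, seed)
        assert abs(base_composition(locus).gc_percent - 62.0) < 2.0


def test_planted_motifs_recovered_exactly(small_spec):
    _, _, truth = generate_locus(small_spec, 11)
    for cls in ("G4", "iM", "RLFS"):
        interfered = {id(p) for p in truth.interfering(cls)}
        clean = [p for p in truth.planted_by_class(cls) if id(p) not in interfered]
        rec = recovered_plants(truth, cls)
        for p in clean:
            assert p in rec, (cls, p)


def test_zero_plant_spec_reports_everything_spurious():
    spec = SyntheticLocusSpec([RegionPlan("r", 8000, 0.7)], [])
    _, _, truth = generate_locus(spec, 3)
    for cls in ("G4", "iM", "RLFS"):
        assert truth.spurious[cls] == truth.scans[cls]
        assert truth.planted_by_class(cls) == []


def test_planted_region_counts_recovered_exactly(small_spec):
    _, regions, truth = generate_locus(small_spec, 5)
    planted_records = [
        MotifRecord(p.motif_class, p.start, p.end, p.strand, "") for p in truth.planted
    ]
    df = summary_frame(summarize_regions(assign_to_regions(planted_records, regions), regions))
    for cls in ("G4", "iM", "RLFS"):
        want = truth.region_counts(cls)
        sub = df[(df.motif_class == cls) & (df.region != "locus")]
        got = dict(zip(sub.region, sub["count"]))
        assert {k: v for k, v in got.items() if v} == want


def test_bin_counts_of_planted_ground_truth(small_spec):
    locus, _, truth = generate_locus(small_spec, 9)
    bins = make_bins(locus.length, 50)
    planted_records = [
        MotifRecord(p.motif_class, p.start, p.end, p.strand, "") for p in truth.planted
    ]
    for cls in ("G4", "iM", "RLFS"):
        recs = [m for m in planted_records if m.motif_class == cls]
        assert np.array_equal(bin_counts(recs, bins), truth.bin_counts(bins, cls))


def test_plant_collision_and_fit_errors():
    spec = SyntheticLocusSpec(
        [RegionPlan("r", 1000, 0.5)],
        [MotifPlant("G4", "+", "r", 100), MotifPlant("G4", "+", "r", 105)],
    )
    with pytest.raises(ValueError, match="collision"):
        generate_locus(spec, 0)
    spec = SyntheticLocusSpec([RegionPlan("r", 100, 0.5)], [MotifPlant("RLFS", "+", "r", 10)])
    with pytest.raises(ValueError, match="fit"):
        generate_locus(spec, 0)


def test_default_spec_matches_study_locus_shape():
    locus, regions, truth = generate_locus(default_locus_spec(), 1)
    assert locus.length == 46838
    assert [r.name for r in regions] == [
        "promoter", "5ETS", "18S", "ITS1", "5.8S", "ITS2", "28S", "3ETS", "IGS"
    ]
    assert len(truth.planted) == 13


def _recovered_r(target, seed, noise_sd=0.0):
    rng = np.random.default_rng(seed)
    bins = make_bins(5000, 100)
    counts = rng.poisson(2.0, size=100).astype(float)
    while np.ptp(counts) == 0:
        counts = rng.poisson(2.0, size=100).astype(float)
    track = generate_signal(bins, counts, target, noise_sd, seed)
    return correlate_signal(bin_signal(track, bins), counts).r


def test_signal_noise_free_extremes():
    assert _recovered_r(-1.0, 4) == pytest.approx(-1.0)
    assert _recovered_r(1.0, 4) == pytest.approx(1.0)


def test_signal_zero_target_unbiased():
    rs = [_recovered_r(0.0, seed) for seed in range(50)]
    assert abs(np.mean(rs)) < 0.05


def test_signal_target_recovery_minus_half():
    rs = np.array([_recovered_r(-0.5, seed) for seed in range(40)])
    assert np.mean(np.abs(rs + 0.5) <= 0.15) >= 0.9


def test_signal_degenerate_inputs_error():
    bins = make_bins(1000, 10)
    with pytest.raises(ValueError, match="constant|degenerate"):
        generate_signal(bins, np.ones(10), -0.5, 0.0, 1)
    with pytest.raises(ValueError, match="target_r"):
        generate_signal(bins, np.arange(10.0), -1.5, 0.0, 1)
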