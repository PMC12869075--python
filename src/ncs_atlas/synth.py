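"""Synthetic rDNA-like loci with known ground truth.

The generator emulates the structure of a reconstructed ribosomal DNA
repeat: an ordered plan of named regions, each with its own background
GC fraction (low in promoter/IGS, very high in the transcribed
spacers), plus planted motif instances (G4, iM, full three-zone RLFS)
at known strand-specific positions, and a per-bin signal track with a
tunable Pearson correlation to planted-motif counts.

Background bases are drawn i.i.d. per region with G and C equiprobable
within the GC mass.  Planted motifs are written over the background
with a 1-nt non-tract flank on each side so that greedy tract matching
cannot extend a plant into adjacent background.  Because the background
itself can contain pattern matches (almost surely, in high-GC regions),
a post-pass re-scans the finished locus and *reports* every hit that is
not an exactly recovered plant — nothing is scrubbed, so the background
composition stays faithful and tests account for spurious hits
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .binning import Bin
from .motifs import MotifRecord, scan_g4, scan_im
from .rlfs import scan_rlfs
from .seqio import NucleotideSequence, Region, reverse_complement
from .signal import SignalTrack


@dataclass(frozen=True)
class RegionPlan:
    name: str
    length: int
    gc: float  # target GC fraction in (0, 1)


@dataclass(frozen=True)
class MotifPlant:
    """One motif to plant: class, strand, host region and offset within it.

    ``params`` tunes the construction (tract/loop lengths for G4/iM;
    model, gap, linker and REZ length for RLFS).
    """

    motif_class: str  # "G4" | "iM" | "RLFS"
    strand: str  # "+" | "-"
    region: str
    offset: int
    params: Mapping[str, int | str] = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticLocusSpec:
    regions: Sequence[RegionPlan]
    plants: Sequence[MotifPlant]
    locus_id: str = "synthetic_locus"


@dataclass(frozen=True)
class PlantedMotif:
    """Ground-truth record of one plant on the forward locus axis."""

    motif_class: str
    strand: str
    start: int
    end: int
    region: str
    sequence: str  # as read on the plant's strand
    riz_start: int | None = None  # RLFS only, forward axis
    riz_end: int | None = None


@dataclass
class GroundTruth:
    planted: list[PlantedMotif]
    spurious: dict[str, list[MotifRecord]]
    scans: dict[str, list[MotifRecord]]

    def planted_by_class(self, cls: str) -> list[PlantedMotif]:
        return [p for p in self.planted if p.motif_class == cls]

    def region_counts(self, cls: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.planted_by_class(cls):
            out[p.region] = out.get(p.region, 0) + 1
        return out

    def bin_counts(self, bins: Sequence[Bin], cls: str) -> np.ndarray:
        counts = np.zeros(len(bins), dtype=np.int64)
        edges = np.array([b.start for b in bins] + [bins[-1].end])
        for p in self.planted_by_class(cls):
            idx = int(np.searchsorted(edges, p.start, side="right")) - 1
            counts[idx] += 1
        return counts

    def interfering(self, cls: str) -> list[PlantedMotif]:
        """Plants of *cls* overlapped by a same-class, same-strand spurious hit."""
        out = []
        for p in self.planted_by_class(cls):
            for s in self.spurious.get(cls, []):
                if s.strand == p.strand and s.start < p.end and p.start < s.end:
                    out.append(p)
                    break
        return out


def _motif_sequence(plant: MotifPlant) -> tuple[str, int | None, int | None]:
    """Construct the plant's residues on its own strand.

    Returns (sequence, riz_start, riz_end) with RIZ offsets relative to
    the sequence start (RLFS only).
    """
    p = dict(plant.params)
    if plant.motif_class == "G4":
        tract = "G" * int(p.get("tract_len", 3))
        loop = ("AT" * 7)[: int(p.get("loop_len", 3))]
        return loop.join([tract] * 4), None, None
    if plant.motif_class == "iM":
        tract = "C" * int(p.get("tract_len", 3))
        loop = ("TA" * 7)[: int(p.get("loop_len", 4))]
        return loop.join([tract] * 4), None, None
    if plant.motif_class == "RLFS":
        model = str(p.get("model", "m2"))
        gap = "A" * int(p.get("gap_len", 2))
        if model == "m2":
            riz = gap.join(["GGGG"] * 2)
        else:
            riz = gap.join(["GGG"] * 3)
        linker = ("AT" * 30)[: int(p.get("linker_len", 10))]
        rez_len = int(p.get("rez_len", 120))
        rez = ("GGAT" * ((rez_len + 3) // 4))[:rez_len]  # 50% G throughout
        return riz + linker + rez, 0, len(riz)
    raise ValueError(f"unknown motif class {plant.motif_class!r}")


_TRACT_BASE = {"G4": "G", "iM": "C", "RLFS": "G"}


def generate_locus(
    spec: SyntheticLocusSpec, seed: int
) -> tuple[NucleotideSequence, list[Region], GroundTruth]:
    """Generate a locus, its region annotation, and full ground truth.

    Deterministic: identical spec + seed give byte-identical output.
    Raises on colliding plants (overlapping intervals including flanks).
    """
    rng = np.random.default_rng(seed)
    regions: list[Region] = []
    pos = 0
    chunks: list[np.ndarray] = []
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for rp in spec.regions:
        if not (0.0 < rp.gc < 1.0):
            raise ValueError(f"region {rp.name}: GC target must be in (0,1)")
        probs = np.array([(1 - rp.gc) / 2, rp.gc / 2, rp.gc / 2, (1 - rp.gc) / 2])
        chunks.append(rng.choice(bases, size=rp.length, p=probs))
        regions.append(Region(rp.name, pos, pos + rp.length))
        pos += rp.length
    arr = np.concatenate(chunks)
    by_name = {r.name: r for r in regions}

    planted: list[PlantedMotif] = []
    occupied: list[tuple[int, int]] = []
    for plant in spec.plants:
        host = by_name[plant.region]
        seq_own, rs, re_ = _motif_sequence(plant)
        start = host.start + plant.offset
        end = start + len(seq_own)
        if plant.offset < 0 or end > host.end:
            raise ValueError(f"plant {plant} does not fit inside region {plant.region}")
        flank = "T" if _TRACT_BASE[plant.motif_class] == "G" else "A"
        written = flank + seq_own + flank
        if plant.strand == "-":
            written = reverse_complement(written)
        w_start, w_end = start - 1, end + 1
        if w_start < 0 or w_end > len(arr):
            raise ValueError(f"plant {plant} flanks run off the locus")
        for a, b in occupied:
            if w_start < b and a < w_end:
                raise ValueError(f"plant collision at [{w_start},{w_end}) vs [{a},{b})")
        occupied.append((w_start, w_end))
        arr[w_start:w_end] = np.frombuffer(written.encode(), dtype=np.uint8)
        if plant.motif_class == "RLFS" and rs is not None:
            if plant.strand == "+":
                riz_iv = (start + rs, start + re_)
            else:
                riz_iv = (end - re_, end - rs)
        else:
            riz_iv = (None, None)
        planted.append(
            PlantedMotif(
                plant.motif_class, plant.strand, start, end, plant.region, seq_own,
                riz_iv[0], riz_iv[1],
            )
        )

    locus = NucleotideSequence(spec.locus_id, arr.tobytes().decode())
    scans = {"G4": scan_g4(locus), "iM": scan_im(locus), "RLFS": scan_rlfs(locus)}
    spurious = {cls: _spurious(scans[cls], planted, cls) for cls in scans}
    return locus, regions, GroundTruth(planted, spurious, scans)


def _recovers(rec: MotifRecord, p: PlantedMotif) -> bool:
    """Does a scanned record recover a plant exactly?

    Canonical tract motifs require the exact interval and strand.  RLFS
    records recover a plant when strand, record start and the planted
    initiation zone coincide (the elongation zone legitimately extends
    into qualifying background, so the end is not constrained).
    """
    if rec.strand != p.strand:
        return False
    if p.motif_class in ("G4", "iM"):
        return rec.start == p.start and rec.end == p.end
    d = rec.detail
    return d.riz_start == p.riz_start and d.riz_end == p.riz_end


def _spurious(
    records: Sequence[MotifRecord], planted: Sequence[PlantedMotif], cls: str
) -> list[MotifRecord]:
    plants = [p for p in planted if p.motif_class == cls]
    return [r for r in records if not any(_recovers(r, p) for p in plants)]


def recovered_plants(truth: GroundTruth, cls: str) -> list[PlantedMotif]:
    plants = truth.planted_by_class(cls)
    return [p for p in plants if any(_recovers(r, p) for r in truth.scans[cls])]


def generate_signal(
    bins: Sequence[Bin],
    planted_counts: Sequence[float],
    target_r: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    baseline: float = 10.0,
    scale: float = 3.0,
) -> SignalTrack:
    """Per-bin signal with expected Pearson r = ``target_r`` vs counts.

    The standardized counts are mixed with seeded unit Gaussian noise as
    ``target_r * z + sqrt(1 - target_r**2) * g`` (so noise-free
    |target_r| = 1 is exact), then mapped affinely onto a positive
    coverage-like scale; ``noise_sd`` adds further independent noise on
    top of the calibrated mixture (attenuating the expectation, for
    robustness experiments).  Emitted as one constant value per bin.
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target_r must lie in [-1, 1]")
    c = np.asarray(planted_counts, dtype=float)
    if len(c) != len(bins):
        raise ValueError("counts length must equal number of bins")
    if np.ptp(c) == 0:
        raise ValueError("degenerate (constant) counts vector")
    rng = np.random.default_rng(seed)
    z = (c - c.mean()) / c.std()
    g = rng.standard_normal(len(c))
    s = target_r * z + np.sqrt(max(1.0 - target_r**2, 0.0)) * g
    if noise_sd:
        s = s + noise_sd * rng.standard_normal(len(c))
    values = baseline + scale * s
    starts = np.array([b.start for b in bins], dtype=np.int64)
    ends = np.array([b.end for b in bins], dtype=np.int64)
    return SignalTrack(starts, ends, values, source=f"synthetic(seed={seed})")


# --- study-condition defaults -------------------------------------------------

#: region plan mirroring the reconstructed human rDNA repeat: real region
#: lengths (promoter fixed at 2,000 nt; IGS = backbone minus transcription
#: unit) and the reported per-region GC levels (%GC: spacers ~79-84, 18S
#: 56.07, 5.8S 57.32, 28S 69.23, promoter/IGS ~45).
DEFAULT_REGION_PLAN = (
    RegionPlan("promoter", 2000, 0.45),
    RegionPlan("5ETS", 3657, 0.84),
    RegionPlan("18S", 1869, 0.5607),
    RegionPlan("ITS1", 1077, 0.80),
    RegionPlan("5.8S", 157, 0.5732),
    RegionPlan("ITS2", 1167, 0.82),
    RegionPlan("28S", 5070, 0.6923),
    RegionPlan("3ETS", 361, 0.79),
    RegionPlan("IGS", 31480, 0.45),
)

#: default plant plan: a strand-mixed spread across low- and high-GC regions
DEFAULT_PLANTS = (
    MotifPlant("RLFS", "+", "promoter", 100, {"model": "m2"}),
    MotifPlant("RLFS", "-", "18S", 300, {"model": "m1"}),
    MotifPlant("RLFS", "+", "IGS", 2000, {"model": "m2", "rez_len": 160}),
    MotifPlant("RLFS", "-", "IGS", 8000, {"model": "m1", "linker_len": 0}),
    MotifPlant("G4", "+", "promoter", 700),
    MotifPlant("G4", "+", "18S", 900, {"tract_len": 4}),
    MotifPlant("G4", "-", "18S", 1400, {"loop_len": 5}),
    MotifPlant("G4", "+", "IGS", 5000),
    MotifPlant("G4", "-", "IGS", 12000, {"tract_len": 5, "loop_len": 7}),
    MotifPlant("iM", "+", "promoter", 1500),
    MotifPlant("iM", "+", "IGS", 15000, {"tract_len": 4}),
    MotifPlant("iM", "-", "IGS", 20000, {"loop_len": 6}),
    MotifPlant("iM", "+", "18S", 100, {"tract_len": 3, "loop_len": 8}),
)


def default_locus_spec() -> SyntheticLocusSpec:
    """The default synthetic study locus (46,838 nt, 9 regions, 13 plants)."""
    return SyntheticLocusSpec(DEFAULT_REGION_PLAN, DEFAULT_PLANTS)
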