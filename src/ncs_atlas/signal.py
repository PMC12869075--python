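"""Integration of an external per-base signal track with binned motif counts.

The contractual signal input is 4-column bedGraph (a bigWig converted
externally, or any per-base coverage export).  Positions not covered by
any interval carry signal 0.  Per-bin means, min-max normalization to
[0, 1], bin-wise directionality against motif counts, and Pearson
correlation reproduce the polymerase-occupancy comparison workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .binning import Bin, CorrelationResult, pearson


@dataclass(frozen=True)
class SignalTrack:
    """Sorted, non-overlapping (start, end, value) intervals on the locus."""

    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("ragged signal track")

    def __len__(self) -> int:
        return len(self.starts)


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a validated, sorted SignalTrack.

    Overlapping intervals or non-numeric values are errors; an empty
    file is a valid all-zero track.
    """
    starts, ends, values = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 bedGraph columns")
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: {err}") from None
            if not np.isfinite(v):
                raise ValueError(f"{path}:{ln}: non-finite value")
            if e <= s:
                raise ValueError(f"{path}:{ln}: empty or inverted interval")
            starts.append(s)
            ends.append(e)
            values.append(v)
    order = np.argsort(starts, kind="stable")
    st = np.array(starts, dtype=np.int64)[order]
    en = np.array(ends, dtype=np.int64)[order]
    va = np.array(values, dtype=float)[order]
    if np.any(st[1:] < en[:-1]):
        i = int(np.nonzero(st[1:] < en[:-1])[0][0])
        raise ValueError(
            f"{path}: overlapping intervals [{st[i]},{en[i]}) and [{st[i+1]},{en[i+1]})"
        )
    return SignalTrack(st, en, va, source=str(path))


def bin_signal(track: SignalTrack, bins: Sequence[Bin]) -> np.ndarray:
    """Mean signal per bin; uncovered positions contribute 0 to the mean."""
    means = np.zeros(len(bins))
    for i, b in enumerate(bins):
        ov_start = np.maximum(track.starts, b.start)
        ov_end = np.minimum(track.ends, b.end)
        ov = np.maximum(ov_end - ov_start, 0)
        means[i] = float(np.dot(ov, track.values)) / (b.end - b.start)
    return means


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """Rescale to [0, 1]; a constant vector is an error (undefined rescale)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise ValueError("min-max normalization undefined for a constant vector")
    return (v - lo) / (hi - lo)


@dataclass(frozen=True)
class DirectionalityResult:
    """Fraction of adjacent-bin steps where two tracks move oppositely.

    Steps where either track is unchanged are excluded from the
    denominator and reported as ties.
    """

    fraction_opposite: float
    n_steps_used: int
    n_ties_excluded: int


def directionality(signal_binned: Sequence[float], counts_binned: Sequence[float]) -> DirectionalityResult:
    s = np.asarray(signal_binned, dtype=float)
    c = np.asarray(counts_binned, dtype=float)
    if s.shape != c.shape or s.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 bins")
    ds, dc = np.diff(s), np.diff(c)
    moved = (ds != 0) & (dc != 0)
    n_used = int(moved.sum())
    n_ties = int(ds.size - n_used)
    if n_used == 0:
        raise ValueError("all adjacent-bin steps are ties; directionality undefined")
    opposite = int(np.sum(np.sign(ds[moved]) != np.sign(dc[moved])))
    return DirectionalityResult(opposite / n_used, n_used, n_ties)


def correlate_signal(signal_binned: Sequence[float], counts_binned: Sequence[float]) -> CorrelationResult:
    """Pearson correlation of per-bin signal vs counts.

    Computed on min-max-normalized vectors for parity with plotted
    tracks; Pearson r is affine-invariant so this matches the raw r.
    """
    return pearson(minmax_normalize(signal_binned), minmax_normalize(counts_binned))


def write_signal_bedgraph(
    bins: Sequence[Bin], values: Sequence[float], path: str | Path, *, chrom: str = "locus"
) -> None:
    with open(path, "w") as fh:
        for b, v in zip(bins, values):
            fh.write(f"{chrom}\t{b.start}\t{b.end}\t{float(v):.6g}\n")
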