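"""Per-base coverage profiles, fixed-count binning, co-occurrence, Pearson.

The locus is divided into a fixed number of consecutive non-overlapping
bins: width = floor(locus_len / n) with the final bin absorbing the
remainder (this shifts the last boundary relative to even division and
is recorded in output metadata).  Motifs are counted into bins by their
forward-axis start position, strands pooled by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import MotifRecord


@dataclass(frozen=True)
class Bin:
    index: int  # 1-based, matching report tables
    start: int
    end: int


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with a two-tailed t-test p-value."""

    r: float
    p: float
    n: int


def coverage_profile(
    motifs: Sequence[MotifRecord], locus_len: int,
    motif_class: str | None = None, strand: str | None = None,
) -> np.ndarray:
    """Per-position depth: number of (filtered) motif intervals covering each base."""
    delta = np.zeros(locus_len + 1, dtype=np.int64)
    for m in motifs:
        if motif_class is not None and m.motif_class != motif_class:
            continue
        if strand is not None and m.strand != strand:
            continue
        delta[m.start] += 1
        delta[m.end] -= 1
    return np.cumsum(delta[:-1])


def make_bins(locus_len: int, n: int = 100) -> list[Bin]:
    """n consecutive non-overlapping bins tiling [0, locus_len)."""
    if n > locus_len:
        raise ValueError(f"cannot make {n} bins from a {locus_len}-nt locus")
    width = locus_len // n
    bins = [Bin(i + 1, i * width, (i + 1) * width) for i in range(n - 1)]
    bins.append(Bin(n, (n - 1) * width, locus_len))
    return bins


def bin_counts(
    motifs: Sequence[MotifRecord], bins: Sequence[Bin], *, strand: str | None = None
) -> np.ndarray:
    """Motif-start counts per bin (strands pooled unless ``strand`` given)."""
    edges = np.array([b.start for b in bins] + [bins[-1].end])
    starts = np.array(
        [m.start for m in motifs if strand is None or m.strand == strand], dtype=np.int64
    )
    if starts.size == 0:
        return np.zeros(len(bins), dtype=np.int64)
    idx = np.searchsorted(edges, starts, side="right") - 1
    if idx.min() < 0 or idx.max() >= len(bins):
        raise ValueError("motif start outside binned range")
    return np.bincount(idx, minlength=len(bins)).astype(np.int64)


def bin_table(
    bins: Sequence[Bin], counts_by_class: Mapping[str, np.ndarray],
    signal_mean: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the per-bin table (raw columns; normalization is explicit)."""
    df = pd.DataFrame(
        {
            "bin": [b.index for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
        }
    )
    for cls, counts in counts_by_class.items():
        df[f"count_{cls}"] = np.asarray(counts)
    if signal_mean is not None:
        df["signal_mean"] = np.asarray(signal_mean, dtype=float)
    df.attrs["binning"] = "width = floor(locus_len/n); final bin absorbs remainder"
    return df


def cooccurrence_sets(counts_by_class: Mapping[str, np.ndarray]) -> dict[frozenset, int]:
    """Exclusive Venn partition of bins by class presence (count > 0).

    Returns counts for each of the 2**k subsets of the class set, keyed
    by frozenset of present classes; frozenset() is the all-absent cell.
    Values sum to the number of bins.
    """
    classes = sorted(counts_by_class)
    presence = {c: np.asarray(counts_by_class[c]) > 0 for c in classes}
    n_bins = len(next(iter(presence.values())))
    if any(len(v) != n_bins for v in presence.values()):
        raise ValueError("class count vectors differ in length")
    out: dict[frozenset, int] = {}
    for mask in range(2 ** len(classes)):
        out[frozenset(c for k, c in enumerate(classes) if mask >> k & 1)] = 0
    for i in range(n_bins):
        key = frozenset(c for c in classes if presence[c][i])
        out[key] += 1
    return out


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with two-tailed p from t = r*sqrt((n-2)/(1-r^2)), n-2 df.

    Constant input is an error (r undefined), never silently 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def correlation_matrix(counts_by_class: Mapping[str, np.ndarray]) -> pd.DataFrame:
    classes = sorted(counts_by_class)
    mat = pd.DataFrame(index=classes, columns=classes, dtype=float)
    for a in classes:
        for b in classes:
            mat.loc[a, b] = 1.0 if a == b else pearson(counts_by_class[a], counts_by_class[b]).r
    return mat


def write_coverage_bedgraph(
    depth: np.ndarray, path: str | Path, *, chrom: str = "locus"
) -> None:
    """Run-length-compressed bedGraph of a per-base depth vector."""
    depth = np.asarray(depth)
    change = np.nonzero(np.diff(depth))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(depth)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{s}\t{e}\t{depth[s]}\n")
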