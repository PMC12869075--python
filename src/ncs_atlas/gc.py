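"""GC landscape: base composition, windowed GC content and GC skew.

GC content of a window is (G + C) / (total bases) in percent, where the
denominator counts every base including N; N never counts as G or C.
GC skew is (G - C) / (G + C) and is undefined (reported as missing,
never 0) where a window holds no G or C at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import NucleotideSequence, Region

_BASES = "ACGTN"


@dataclass(frozen=True)
class CompositionSummary:
    """Raw counts and percentages of A/T/G/C/N for one sequence or region."""

    name: str
    length: int
    counts: dict[str, int]
    percents: dict[str, float]
    gc_percent: float
    at_percent: float

    def as_row(self) -> dict:
        row = {"name": self.name, "length": self.length}
        for b in _BASES:
            row[f"count_{b}"] = self.counts[b]
        for b in _BASES:
            row[f"pct_{b}"] = self.percents[b]
        row["gc_percent"] = self.gc_percent
        row["at_percent"] = self.at_percent
        return row


@dataclass(frozen=True)
class WindowTrack:
    """Per-window values of one statistic along a sequence.

    ``values`` holds NaN where the statistic is undefined (see ``defined``).
    GC content is in percent [0, 100]; GC skew is a fraction in [-1, +1].
    """

    kind: str  # "gc_content" | "gc_skew"
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    defined: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start": self.starts, "end": self.ends, "value": self.values, "defined": self.defined}
        )


def _counts(seq: str) -> dict[str, int]:
    return {b: seq.count(b) for b in _BASES}


def base_composition(seq: NucleotideSequence | str, name: str | None = None) -> CompositionSummary:
    """Exact base counts and percentages; errors on an empty sequence."""
    residues = seq if isinstance(seq, str) else seq.residues
    label = name if name is not None else (getattr(seq, "id", None) or "sequence")
    n = len(residues)
    if n == 0:
        raise ValueError("empty sequence")
    counts = _counts(residues)
    percents = {b: 100.0 * counts[b] / n for b in _BASES}
    gc = 100.0 * (counts["G"] + counts["C"]) / n
    at = 100.0 * (counts["A"] + counts["T"]) / n
    return CompositionSummary(label, n, counts, percents, gc, at)


def _window_starts(length: int, window: int, step: int, keep_partial: bool) -> np.ndarray:
    if window > length:
        raise ValueError(f"window {window} exceeds sequence length {length}")
    if step < 1 or window < 1:
        raise ValueError("window and step must be >= 1")
    if keep_partial:
        starts = np.arange(0, length, step)
    else:
        starts = np.arange(0, length - window + 1, step)
    return starts


def _cum_base(residues: str, base: str) -> np.ndarray:
    arr = np.frombuffer(residues.encode(), dtype=np.uint8)
    return np.concatenate([[0], np.cumsum(arr == ord(base))])


def gc_windows(
    seq: NucleotideSequence | str,
    window: int = 100,
    step: int = 1,
    *,
    keep_partial: bool = True,
) -> WindowTrack:
    """Windowed GC content in percent.

    A trailing partial window is kept by default with its actual size as
    denominator; ``keep_partial=False`` drops it.
    """
    residues = seq if isinstance(seq, str) else seq.residues
    n = len(residues)
    starts = _window_starts(n, window, step, keep_partial)
    ends = np.minimum(starts + window, n)
    cg = _cum_base(residues, "G") + _cum_base(residues, "C")
    gc = cg[ends] - cg[starts]
    sizes = ends - starts
    values = 100.0 * gc / sizes
    return WindowTrack("gc_content", starts, ends, values, np.ones(len(starts), dtype=bool))


def gc_skew_windows(
    seq: NucleotideSequence | str,
    window: int = 100,
    step: int | None = None,
    *,
    keep_partial: bool = True,
) -> WindowTrack:
    """Windowed GC skew (G - C)/(G + C); default non-overlapping tiles.

    Windows with G + C = 0 are flagged undefined and carry NaN.
    """
    residues = seq if isinstance(seq, str) else seq.residues
    n = len(residues)
    if step is None:
        step = window
    starts = _window_starts(n, window, step, keep_partial)
    ends = np.minimum(starts + window, n)
    cg_ = _cum_base(residues, "G")
    cc_ = _cum_base(residues, "C")
    g = (cg_[ends] - cg_[starts]).astype(float)
    c = (cc_[ends] - cc_[starts]).astype(float)
    denom = g + c
    defined = denom > 0
    values = np.full(len(starts), np.nan)
    values[defined] = (g[defined] - c[defined]) / denom[defined]
    return WindowTrack("gc_skew", starts, ends, values, defined)


def region_composition(
    seq: NucleotideSequence, regions: Sequence[Region]
) -> pd.DataFrame:
    """Composition table: one row per region plus a whole-locus row."""
    rows = [base_composition(seq.residues[r.start : r.end], name=r.name).as_row() for r in regions]
    rows.append(base_composition(seq, name="locus").as_row())
    return pd.DataFrame(rows)


def write_track_bedgraph(track: WindowTrack, path: str | Path, *, chrom: str = "locus") -> None:
    """Write defined windows of a track as 4-column bedGraph."""
    with open(path, "w") as fh:
        for s, e, v, d in zip(track.starts, track.ends, track.values, track.defined):
            if d:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
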