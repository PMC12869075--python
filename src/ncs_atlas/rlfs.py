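"""Quantitative R-loop forming sequence (RLFS) model.

An RLFS is three consecutive zones on one strand:

* RIZ  (initiation zone): clustered G tracts with >= 50% G overall.
  Model m1 chains >= 3 tracts of >= 3 Gs; model m2 chains >= 2 tracts
  of >= 4 Gs; inter-tract gaps are 1-10 nt of any composition.
* linker: 0-50 nt, any composition.
* REZ  (elongation zone): 100-2,000 nt with >= 40% G over its full
  extent, supporting stable R-loop propagation.

G-fraction thresholds use exact integer arithmetic:
count(G) * 2 >= span for 50%, count(G) * 5 >= span * 2 for 40%.

RIZ emission is one maximal extension per (left anchor tract, model);
m1 and m2 hits are kept separately even when overlapping, which is why
several reported RLFS can share an origin but differ in length.  REZ
selection is deterministic: among linker start positions the candidate
with the largest end wins, ties broken by the shortest linker.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .motifs import MotifRecord
from .seqio import NucleotideSequence, reverse_complement

_G_RUN = re.compile("G+")

#: model -> (min tract length, min number of tracts)
RIZ_MODELS: dict[str, tuple[int, int]] = {"m1": (3, 3), "m2": (4, 2)}

GAP_MAX = 10
LINKER_MAX = 50
REZ_MIN = 100
REZ_MAX = 2000


@dataclass(frozen=True)
class RIZ:
    """R-loop initiation zone on the scanned strand (0-based half-open)."""

    start: int
    end: int
    model: str
    g_fraction: float
    tract_count: int


@dataclass(frozen=True)
class REZ:
    """R-loop elongation zone on the scanned strand."""

    start: int
    end: int
    g_fraction: float


@dataclass(frozen=True)
class RLFSDetail:
    """Zone decomposition of one RLFS, on the forward locus axis."""

    model: str
    riz_start: int
    riz_end: int
    linker_len: int
    rez_start: int
    rez_end: int
    riz_g_fraction: float
    rez_g_fraction: float
    tract_count: int


def _g_prefix(residues: str) -> np.ndarray:
    arr = np.frombuffer(residues.encode(), dtype=np.uint8)
    return np.concatenate([[0], np.cumsum(arr == ord("G"))]).astype(np.int64)


def find_riz(seq: NucleotideSequence | str, models: Sequence[str] = ("m1", "m2")) -> list[RIZ]:
    """Detect RIZ candidates on a single strand.

    For each model independently, every maximal G run meeting the
    model's tract minimum anchors a chain that extends rightward
    tract-by-tract while inter-tract gaps stay <= 10 nt and the overall
    G fraction of the growing span stays >= 50%; the maximal extension
    per anchor is emitted when it reaches the model's tract count.
    """
    residues = seq if isinstance(seq, str) else seq.residues
    runs = [(m.start(), m.end()) for m in _G_RUN.finditer(residues)]
    cg = _g_prefix(residues)
    out: list[RIZ] = []
    for model in models:
        tract_min, count_min = RIZ_MODELS[model]
        qual = [(s, e) for s, e in runs if e - s >= tract_min]
        for i, (a_start, a_end) in enumerate(qual):
            end = a_end
            count = 1
            for s, e in qual[i + 1 :]:
                gap = s - end
                if gap > GAP_MAX:
                    break
                span = e - a_start
                if (cg[e] - cg[a_start]) * 2 < span:  # G fraction would drop below 50%
                    break
                end = e
                count += 1
            if count >= count_min:
                span = end - a_start
                frac = (cg[end] - cg[a_start]) / span
                out.append(RIZ(a_start, end, model, frac, count))
    out.sort(key=lambda r: (r.start, r.model))
    return out


def extend_rez(
    seq: NucleotideSequence | str,
    riz: RIZ,
    *,
    linker_max: int = LINKER_MAX,
    rez_min: int = REZ_MIN,
    rez_max: int = REZ_MAX,
) -> REZ | None:
    """Find the elongation zone downstream of a RIZ, or None.

    Candidate starts s run over [riz.end, riz.end + linker_max]; for each,
    the longest window [s, e) with length in [rez_min, rez_max] and
    whole-window G fraction >= 40% is considered.  The candidate with the
    largest e wins; ties prefer the smallest s (shortest linker).
    """
    residues = seq if isinstance(seq, str) else seq.residues
    n = len(residues)
    cg = _g_prefix(residues)
    best: tuple[int, int] | None = None  # (e, s) with max e then min s
    for s in range(riz.end, min(riz.end + linker_max, n) + 1):
        e_hi = min(s + rez_max, n)
        if e_hi - s < rez_min:
            break  # later starts have even less room
        lengths = np.arange(rez_min, e_hi - s + 1)
        ends = s + lengths
        ok = (cg[ends] - cg[s]) * 5 >= lengths * 2
        idx = np.nonzero(ok)[0]
        if idx.size == 0:
            continue
        e = int(ends[idx[-1]])
        if best is None or e > best[0]:
            best = (e, s)
    if best is None:
        return None
    e, s = best
    return REZ(s, e, (cg[e] - cg[s]) / (e - s))


def _scan_strand(residues: str) -> list[tuple[RIZ, REZ]]:
    hits = []
    for riz in find_riz(residues):
        rez = extend_rez(residues, riz)
        if rez is not None:
            hits.append((riz, rez))
    return hits


def scan_rlfs(locus: NucleotideSequence) -> list[MotifRecord]:
    """Full RLFS scan on both strands, records on the forward locus axis.

    One record per successful (RIZ, REZ) pair; overlapping records across
    anchors and models are expected and kept.
    """
    n = locus.length
    records: list[MotifRecord] = []
    for strand, residues in (("+", locus.residues), ("-", reverse_complement(locus.residues))):
        for riz, rez in _scan_strand(residues):
            s, e = riz.start, rez.end
            seq = residues[s:e]
            if strand == "+":
                detail = RLFSDetail(
                    riz.model, riz.start, riz.end, rez.start - riz.end, rez.start, rez.end,
                    riz.g_fraction, rez.g_fraction, riz.tract_count,
                )
                records.append(MotifRecord("RLFS", s, e, "+", seq, detail))
            else:
                detail = RLFSDetail(
                    riz.model, n - riz.end, n - riz.start, rez.start - riz.end,
                    n - rez.end, n - rez.start, riz.g_fraction, rez.g_fraction, riz.tract_count,
                )
                records.append(MotifRecord("RLFS", n - e, n - s, "-", seq, detail))
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    return records


def riz_records(rlfs: Sequence[MotifRecord]) -> list[MotifRecord]:
    """Initiation-zone intervals of RLFS records, as class-"RIZ" records.

    Used where co-occurrence is anchored on initiation zones rather than
    whole RLFS spans.
    """
    out = []
    for r in rlfs:
        d = r.detail
        out.append(MotifRecord("RIZ", d.riz_start, d.riz_end, r.strand, "", d))
    out.sort(key=lambda r: (r.start, r.end, r.strand))
    return out


def write_rlfs_tsv(records: Sequence[MotifRecord], path: str | Path, *, chrom: str = "locus") -> None:
    """Tabular export with the zone decomposition of every record."""
    cols = (
        "chrom\tstart\tend\tstrand\tmodel\triz_start\triz_end\tlinker_len\t"
        "rez_start\trez_end\triz_g_fraction\trez_g_fraction\ttract_count\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for r in records:
            d = r.detail
            fh.write(
                f"{chrom}\t{r.start}\t{r.end}\t{r.strand}\t{d.model}\t{d.riz_start}\t"
                f"{d.riz_end}\t{d.linker_len}\t{d.rez_start}\t{d.rez_end}\t"
                f"{d.riz_g_fraction:.4f}\t{d.rez_g_fraction:.4f}\t{d.tract_count}\n"
            )
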