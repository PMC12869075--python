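"""G-quadruplex and i-motif detection via a shared tract-and-loop engine.

Both canonical motifs are four base tracts separated by short loops:

* G4:  G3+ N1-7 G3+ N1-7 G3+ N1-7 G3+   (tracts of >= 3 G, unbounded)
* iM:  C3-10 N1-12 C3-10 N1-12 C3-10 N1-12 C3-10

Matching is leftmost, non-overlapping, with greedy tract quantifiers
(a run of 6 Gs is one tract, not two); loops may contain any base,
including the tract base and N.  N never satisfies a tract.  Scanning
the reverse complement yields "-"-strand records mapped back to forward
coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import NucleotideSequence, reverse_complement


@dataclass(frozen=True)
class TractMotifSpec:
    """Four-tract motif grammar: tract base, tract length bounds, loop bounds."""

    name: str
    tract_base: str
    tract_min: int
    tract_max: int | None  # None = unbounded
    loop_min: int
    loop_max: int
    n_tracts: int = 4

    def __post_init__(self) -> None:
        if self.tract_base not in "GC":
            raise ValueError("tract base must be G or C")
        if self.tract_min < 1 or self.loop_min < 1 or self.n_tracts < 2:
            raise ValueError("invalid motif spec")

    def regex(self) -> re.Pattern[str]:
        hi = "" if self.tract_max is None else str(self.tract_max)
        tract = f"{self.tract_base}{{{self.tract_min},{hi}}}"
        loop = f"[ACGTN]{{{self.loop_min},{self.loop_max}}}"
        return re.compile(f"(?:{tract}{loop}){{{self.n_tracts - 1}}}{tract}")


#: canonical G-quadruplex pattern G3+ N1-7 x4
G4_SPEC = TractMotifSpec("G4", "G", 3, None, 1, 7)
#: canonical i-motif pattern C3-10 N1-12 x4
IM_SPEC = TractMotifSpec("iM", "C", 3, 10, 1, 12)


@dataclass(frozen=True)
class MotifRecord:
    """One predicted structure on the forward locus axis.

    ``sequence`` is the matched residues as read on the matched strand:
    for "-" records it equals the reverse complement of locus[start:end].
    ``detail`` carries class-specific payload (RLFS zones).
    """

    motif_class: str  # "G4" | "iM" | "RLFS"
    start: int
    end: int
    strand: str  # "+" | "-"
    sequence: str
    detail: object | None = None
    region: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def scan_tract_motif(
    seq: NucleotideSequence | str, spec: TractMotifSpec, *, strand: str = "+"
) -> list[MotifRecord]:
    """Single-strand scan: leftmost non-overlapping greedy matches.

    Coordinates are on the scanned sequence axis; ``strand`` is recorded
    verbatim (mapping to forward coordinates is the caller's job).
    """
    residues = seq if isinstance(seq, str) else seq.residues
    pattern = spec.regex()
    return [
        MotifRecord(spec.name, m.start(), m.end(), strand, m.group(0))
        for m in pattern.finditer(residues)
    ]


def _map_minus(records: Iterable[MotifRecord], locus_len: int) -> list[MotifRecord]:
    """Mirror records found on the reverse complement onto forward coordinates."""
    return [
        MotifRecord(r.motif_class, locus_len - r.end, locus_len - r.start, "-", r.sequence, r.detail)
        for r in records
    ]


def scan_both_strands(locus: NucleotideSequence, spec: TractMotifSpec) -> list[MotifRecord]:
    """Scan forward strand and reverse complement; merge, sorted by (start, strand)."""
    fwd = scan_tract_motif(locus, spec, strand="+")
    rev = scan_tract_motif(reverse_complement(locus), spec, strand="-")
    merged = fwd + _map_minus(rev, locus.length)
    merged.sort(key=lambda r: (r.start, r.end, r.strand))
    return merged


def scan_g4(locus: NucleotideSequence) -> list[MotifRecord]:
    """Canonical G-quadruplex-forming sequences on both strands."""
    return scan_both_strands(locus, G4_SPEC)


def scan_im(locus: NucleotideSequence) -> list[MotifRecord]:
    """Canonical i-motif-forming sequences on both strands."""
    return scan_both_strands(locus, IM_SPEC)


def write_motifs_bed(
    records: Sequence[MotifRecord], path: str | Path, *, chrom: str = "locus"
) -> None:
    """BED6: name = motif class, score = 0, strand column used."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{chrom}\t{r.start}\t{r.end}\t{r.motif_class}\t0\t{r.strand}\n")


def write_motifs_tsv(
    records: Sequence[MotifRecord], path: str | Path, *, chrom: str = "locus"
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tclass\tstrand\tsequence\n")
        for r in records:
            fh.write(f"{chrom}\t{r.start}\t{r.end}\t{r.motif_class}\t{r.strand}\t{r.sequence}\n")
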