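"""Sequence and region I/O, locus reconstruction, coordinate conventions.

All coordinates in this package are 0-based half-open on the forward
(deposited) strand of the locus.  BED input/output uses the same
convention; TSV region tables may declare 1-based inclusive coordinates
and are converted on load.  Strand "+" denotes the deposited strand
(displayed as "non-template" under the default label mapping, because
ribosomal RNA genes are deposited in the sense orientation); "-" denotes
its reverse complement (displayed "template").
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")

#: display names attached to "+" / "-"; flip via ``strand_display(mapping=...)``
DEFAULT_STRAND_DISPLAY = {"+": "non-template", "-": "template"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


class RegionError(ValueError):
    """Raised for invalid region annotations (overlap, bounds, duplicates)."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified DNA sequence over the 5-letter alphabet {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise SequenceAlphabetError(
                f"{self.id}: illegal character {self.residues[pos]!r} at offset {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __getitem__(self, key) -> str:
        return self.residues[key]


@dataclass(frozen=True)
class Region:
    """A named interval on the locus, 0-based half-open, strand-agnostic."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RegionError(f"region {self.name}: invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def normalize_residues(raw: str, *, id: str = "?", strict: bool = True) -> str:
    """Upper-case *raw* and enforce the {A,C,G,T,N} alphabet.

    In lenient mode, unknown characters (IUPAC ambiguity codes etc.) are
    mapped to N; in strict mode they raise naming the offending offset.
    """
    up = raw.upper()
    if set(up) <= ALPHABET:
        return up
    if strict:
        pos = next(i for i, c in enumerate(up) if c not in ALPHABET)
        raise SequenceAlphabetError(f"{id}: illegal character {up[pos]!r} at offset {pos}")
    return "".join(c if c in ALPHABET else "N" for c in up)


def read_fasta(path: str | Path, *, strict: bool = True) -> list[NucleotideSequence]:
    """Read a FASTA file into a list of :class:`NucleotideSequence`.

    Residues are normalized to upper case.  ``strict=True`` rejects any
    character outside {A,C,G,T,N}; ``strict=False`` maps them to N.
    Raises ``ValueError("no records")`` on an empty file.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    out = []
    for rec in records:
        out.append(NucleotideSequence(rec.id, normalize_residues(str(rec.seq), id=rec.id, strict=strict)))
    return out


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path, *, width: int = 70) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def reverse_complement(seq: NucleotideSequence | str) -> NucleotideSequence | str:
    """Reverse complement with A<->T, G<->C, N<->N."""
    if isinstance(seq, str):
        return seq.translate(_COMPLEMENT)[::-1]
    return NucleotideSequence(seq.id, seq.residues.translate(_COMPLEMENT)[::-1])


def validate_regions(regions: Sequence[Region], locus_len: int) -> list[Region]:
    """Sort and validate a region list: in-bounds, non-overlapping, unique names."""
    rs = sorted(regions, key=lambda r: r.start)
    names = [r.name for r in rs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise RegionError(f"duplicate region names: {dupes}")
    offenders = []
    for r in rs:
        if r.end > locus_len:
            offenders.append(f"{r.name} [{r.start},{r.end}) exceeds locus length {locus_len}")
    for a, b in zip(rs, rs[1:]):
        if b.start < a.end:
            offenders.append(f"{a.name} [{a.start},{a.end}) overlaps {b.name} [{b.start},{b.end})")
    if offenders:
        raise RegionError("; ".join(offenders))
    return rs


def build_locus(
    backbone: NucleotideSequence,
    backbone_regions: Sequence[Region],
    promoter_len: int = 2000,
    *,
    locus_id: str | None = None,
) -> tuple[NucleotideSequence, list[Region]]:
    """Reconstruct the analysis locus by prepending promoter sequence.

    The deposited rDNA repeat starts at the 5'ETS; the promoter lies at
    the far end of the IGS, abutting the repeat junction.  The final
    ``promoter_len`` nucleotides of the backbone are copied in front of
    the full backbone, all region coordinates shift by ``promoter_len``,
    and a new "promoter" region [0, promoter_len) is prepended.

    With ``promoter_len == 0`` the backbone is returned unchanged.
    """
    regions = validate_regions(backbone_regions, backbone.length)
    if promoter_len == 0:
        return backbone, list(regions)
    igs = [r for r in regions if r.name == "IGS"]
    igs_len = igs[0].length if igs else backbone.length
    if promoter_len < 0 or promoter_len > igs_len:
        raise ValueError(f"promoter_len {promoter_len} outside [0, IGS length {igs_len}]")
    residues = backbone.residues[-promoter_len:] + backbone.residues
    shifted = [Region(r.name, r.start + promoter_len, r.end + promoter_len) for r in regions]
    out_regions = [Region("promoter", 0, promoter_len)] + shifted
    locus = NucleotideSequence(locus_id or f"{backbone.id}_locus", residues)
    return locus, validate_regions(out_regions, locus.length)


def load_regions(
    path: str | Path,
    locus_len: int,
    *,
    one_based: bool = False,
) -> list[Region]:
    """Load regions from BED (0-based half-open) or name/start/end TSV.

    BED is detected by a leading chrom column (4 columns, numeric cols 2-3).
    A 3-column ``name  start  end`` table is read directly; set
    ``one_based=True`` if its coordinates are 1-based inclusive.
    """
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) >= 4 and parts[1].lstrip("-").isdigit() and parts[2].lstrip("-").isdigit():
                name, start, end = parts[3], int(parts[1]), int(parts[2])  # BED4+
            elif len(parts) >= 3:
                name, start, end = parts[0], int(parts[1]), int(parts[2])
            else:
                raise RegionError(f"{path}:{ln}: cannot parse region line {line!r}")
            if one_based:
                start -= 1
            regions.append(Region(name, start, end))
    return validate_regions(regions, locus_len)


def write_regions_bed(regions: Sequence[Region], path: str | Path, *, chrom: str = "locus") -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{chrom}\t{r.start}\t{r.end}\t{r.name}\n")


def strand_display(strand: str, mapping: dict[str, str] | None = None) -> str:
    """Human-readable name ("non-template"/"template") for a strand symbol."""
    mapping = mapping or DEFAULT_STRAND_DISPLAY
    return mapping[strand]
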