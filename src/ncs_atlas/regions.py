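"""Strand-specific regional assignment and quantification of motifs.

Each motif is assigned to the unique region containing its start
position on the forward locus axis, regardless of how far it extends
into neighbouring regions.  Summaries report, per region and motif
class: total count, per-strand counts, density (count / region length,
also per kb) and proportion of the class total in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .motifs import MotifRecord
from .seqio import Region


@dataclass(frozen=True)
class RegionSummary:
    region: str
    region_length: int
    motif_class: str
    count: int
    plus_count: int
    minus_count: int
    density: float  # per nt
    density_per_kb: float
    proportion_percent: float


def assign_to_regions(
    motifs: Sequence[MotifRecord], regions: Sequence[Region]
) -> list[MotifRecord]:
    """Label every motif with the region containing its forward-axis start.

    Regions must cover every motif start; an uncovered start is an error.
    """
    rs = sorted(regions, key=lambda r: r.start)
    out = []
    for m in motifs:
        region = next((r for r in rs if r.contains(m.start)), None)
        if region is None:
            raise ValueError(
                f"motif {m.motif_class} [{m.start},{m.end}) start lies outside all regions"
            )
        out.append(replace(m, region=region.name))
    return out


def summarize_regions(
    assigned: Sequence[MotifRecord], regions: Sequence[Region]
) -> list[RegionSummary]:
    """Per-region, per-class counts/densities/proportions plus locus rows."""
    classes = sorted({m.motif_class for m in assigned})
    locus_len = max(r.end for r in regions) if regions else 0
    rows: list[RegionSummary] = []
    for cls in classes:
        cls_motifs = [m for m in assigned if m.motif_class == cls]
        total = len(cls_motifs)
        for r in sorted(regions, key=lambda r: r.start):
            sub = [m for m in cls_motifs if m.region == r.name]
            plus = sum(1 for m in sub if m.strand == "+")
            rows.append(
                RegionSummary(
                    r.name, r.length, cls, len(sub), plus, len(sub) - plus,
                    len(sub) / r.length, 1000.0 * len(sub) / r.length,
                    100.0 * len(sub) / total if total else 0.0,
                )
            )
        plus_total = sum(1 for m in cls_motifs if m.strand == "+")
        rows.append(
            RegionSummary(
                "locus", locus_len, cls, total, plus_total, total - plus_total,
                total / locus_len if locus_len else 0.0,
                1000.0 * total / locus_len if locus_len else 0.0,
                100.0 if total else 0.0,
            )
        )
    return rows


def summary_frame(summaries: Sequence[RegionSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def write_summary_csv(summaries: Sequence[RegionSummary], path: str | Path) -> None:
    summary_frame(summaries).to_csv(path, index=False)
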