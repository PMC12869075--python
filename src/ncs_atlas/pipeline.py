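"""End-to-end pipeline: chain every analysis stage on one locus.

``run_pipeline`` is deterministic given identical inputs and config and
writes only plain-text artifacts (FASTA, BED, bedGraph, CSV, JSON).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binning import (
    bin_counts, bin_table, cooccurrence_sets, correlation_matrix, coverage_profile,
    make_bins, write_coverage_bedgraph,
)
from .gc import gc_skew_windows, gc_windows, region_composition, write_track_bedgraph
from .motifs import scan_g4, scan_im, write_motifs_bed, write_motifs_tsv
from .regions import assign_to_regions, summarize_regions, write_summary_csv
from .rlfs import riz_records, scan_rlfs, write_rlfs_tsv
from .seqio import build_locus, load_regions, read_fasta, write_fasta, write_regions_bed
from .signal import bin_signal, correlate_signal, directionality, read_bedgraph


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    fasta: str
    regions: str
    out_dir: str
    signal_bedgraph: str | None = None
    promoter_len: int = 0  # 0 = input locus is already reconstructed
    gc_window: int = 100
    gc_step: int = 1
    skew_window: int = 100
    n_bins: int = 100
    scan_classes: tuple[str, ...] = ("RLFS", "G4", "iM")
    cooccurrence_anchor: str = "RIZ"  # "RIZ" | "RLFS"
    identity_mode: str = "alignment_columns"
    strand_display: tuple[str, str] = ("non-template", "template")
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["scan_classes"] = tuple(d["scan_classes"])
        d["strand_display"] = tuple(d["strand_display"])
        return cls(**d)


def run_pipeline(config: RunConfig) -> Path:
    """Run locus build, GC landscape, scans, quantification, bins, signal.

    Returns the output directory.  Every stage error propagates with the
    stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    (out / "version.txt").write_text(f"ncs-atlas {__version__}\n")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"stage {name}: {err}") from err

    seqs = stage("read_fasta", read_fasta, config.fasta)
    backbone = seqs[0]
    backbone_regions = stage("load_regions", load_regions, config.regions, backbone.length)
    locus, regions = stage("build_locus", build_locus, backbone, backbone_regions, config.promoter_len)
    write_fasta([locus], out / "locus.fasta")
    write_regions_bed(regions, out / "locus.bed")

    comp = stage("region_composition", region_composition, locus, regions)
    comp.to_csv(out / "composition.csv", index=False)
    gc_track = stage("gc_windows", gc_windows, locus, config.gc_window, config.gc_step)
    write_track_bedgraph(gc_track, out / "gc_content.bedgraph", chrom=locus.id)
    skew = stage("gc_skew_windows", gc_skew_windows, locus, config.skew_window)
    write_track_bedgraph(skew, out / "gc_skew.bedgraph", chrom=locus.id)

    scanners = {"RLFS": scan_rlfs, "G4": scan_g4, "iM": scan_im}
    motifs = {}
    for cls in config.scan_classes:
        motifs[cls] = stage(f"scan_{cls}", scanners[cls], locus)
    if "RLFS" in motifs:
        write_rlfs_tsv(motifs["RLFS"], out / "rlfs.tsv", chrom=locus.id)
    for cls in ("G4", "iM"):
        if cls in motifs:
            write_motifs_bed(motifs[cls], out / f"{cls.lower()}.bed", chrom=locus.id)
            write_motifs_tsv(motifs[cls], out / f"{cls.lower()}.tsv", chrom=locus.id)

    assigned = []
    for cls, recs in motifs.items():
        assigned += stage("assign_to_regions", assign_to_regions, recs, regions)
    summaries = stage("summarize_regions", summarize_regions, assigned, regions)
    write_summary_csv(summaries, out / "region_summary.csv")

    for cls, recs in motifs.items():
        for strand in "+-":
            depth = coverage_profile(recs, locus.length, strand=strand)
            tag = "plus" if strand == "+" else "minus"
            write_coverage_bedgraph(depth, out / f"coverage_{cls.lower()}_{tag}.bedgraph", chrom=locus.id)

    bins = stage("make_bins", make_bins, locus.length, config.n_bins)
    counts = {cls: bin_counts(recs, bins) for cls, recs in motifs.items()}
    if config.cooccurrence_anchor == "RIZ" and "RLFS" in motifs:
        counts_cooc = dict(counts)
        counts_cooc["RIZ"] = bin_counts(riz_records(motifs["RLFS"]), bins)
        counts_cooc.pop("RLFS")
    else:
        counts_cooc = counts
    venn = cooccurrence_sets(counts_cooc)
    venn_rows = [
        {"subset": "+".join(sorted(k)) if k else "(none)", "bins": v}
        for k, v in sorted(venn.items(), key=lambda kv: sorted(kv[0]))
    ]
    pd.DataFrame(venn_rows).to_csv(out / "cooccurrence.csv", index=False)
    correlation_matrix(counts_cooc).to_csv(out / "class_correlation.csv")

    signal_mean = None
    if config.signal_bedgraph:
        track = stage("read_bedgraph", read_bedgraph, config.signal_bedgraph)
        signal_mean = stage("bin_signal", bin_signal, track, bins)
        rows = []
        for cls, c in counts.items():
            corr = correlate_signal(signal_mean, c)
            dres = directionality(signal_mean, c)
            rows.append(
                {
                    "class": cls, "r": corr.r, "p": corr.p, "n": corr.n,
                    "fraction_opposite": dres.fraction_opposite,
                    "n_steps_used": dres.n_steps_used,
                    "n_ties_excluded": dres.n_ties_excluded,
                }
            )
        pd.DataFrame(rows).to_csv(out / "signal_integration.csv", index=False)

    bt = bin_table(bins, counts, signal_mean)
    bt.to_csv(out / "bin_table.csv", index=False)
    return out
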