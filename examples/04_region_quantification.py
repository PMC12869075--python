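"""Strand-specific regional quantification (counts, density, proportion).

Motifs are assigned to the region containing their start position on
the forward axis, regardless of how far they extend, and summarized per
region and class.
"""

import ncs_atlas as na
from ncs_atlas.regions import summary_frame

locus, regions, _ = na.generate_locus(na.default_locus_spec(), seed=1)
motifs = na.scan_rlfs(locus) + na.scan_g4(locus) + na.scan_im(locus)
assigned = na.assign_to_regions(motifs, regions)
df = summary_frame(na.summarize_regions(assigned, regions))

view = df[df.motif_class == "RLFS"][
    ["region", "region_length", "count", "plus_count", "minus_count",
     "density_per_kb", "proportion_percent"]
].round(2)
print("RLFS per region (locus row = whole-locus totals):\n")
print(view.to_string(index=False))
print("\nDensity (per kb) corrects for the very different region lengths; "
      "proportion is each region's share of the class total.")
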