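"""Scan both strands for the three motif classes.

G4:   G3+ N1-7  x4      (four G-tracts, short loops)
iM:   C3-10 N1-12 x4    (four C-tracts, flexible loops)
RLFS: RIZ (G-clustered, >=50% G) + linker (0-50 nt) + REZ (100-2,000 nt,
      >=40% G)

Counts include hits arising from the GC-rich background, exactly as a
scan of a real locus would; the generator's ground truth separates
planted from spurious hits (see 03_planted_ground_truth.py).
"""

import ncs_atlas as na

locus, regions, _ = na.generate_locus(na.default_locus_spec(), seed=1)

for name, scan in (("RLFS", na.scan_rlfs), ("G4", na.scan_g4), ("iM", na.scan_im)):
    hits = scan(locus)
    plus = sum(h.strand == "+" for h in hits)
    print(f"{name:5s}: {len(hits):4d} hits ({plus} on '+'/non-template, "
          f"{len(hits) - plus} on '-'/template)")

rlfs = na.scan_rlfs(locus)
r = rlfs[0]
d = r.detail
print(f"\nfirst RLFS: [{r.start}, {r.end}) strand {r.strand}, model {d.model}, "
      f"RIZ [{d.riz_start}, {d.riz_end}) G-fraction {d.riz_g_fraction:.2f}, "
      f"linker {d.linker_len} nt, REZ length {d.rez_end - d.rez_start} nt "
      f"G-fraction {d.rez_g_fraction:.2f}")
print("The three-zone decomposition is what distinguishes an R-loop forming "
      "sequence from a plain G-rich patch.")
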