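"""Integrating an external occupancy track with binned motif counts.

A synthetic per-bin polymerase-occupancy-like signal is generated with
a target Pearson correlation of -0.5 to the RLFS bin counts (the
anti-correlation regime), then recovered by the integration pipeline:
per-bin means, min-max normalization, bin-wise directionality and
Pearson correlation.
"""

import ncs_atlas as na

locus, regions, truth = na.generate_locus(na.default_locus_spec(), seed=1)
bins = na.make_bins(locus.length, 100)
counts = na.bin_counts(truth.scans["RLFS"], bins).astype(float)

track = na.generate_signal(bins, counts, target_r=-0.5, noise_sd=0.0, seed=2)
signal = na.bin_signal(track, bins)

corr = na.correlate_signal(signal, counts)
frac = na.directionality(na.minmax_normalize(signal), na.minmax_normalize(counts))
print(f"recovered Pearson r = {corr.r:.2f} (target -0.50), p = {corr.p:.2g}, n = {corr.n}")
print(f"opposite-direction steps: {100 * frac.fraction_opposite:.0f}% "
      f"({frac.n_steps_used} steps used, {frac.n_ties_excluded} ties excluded)")
print("\nr near the target shows the calibration of the generator; the "
      "directionality fraction is the local, bin-to-bin view of the same "
      "inverse relationship.")
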