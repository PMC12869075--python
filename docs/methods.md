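# Methods

## Coordinates, strands, alphabet

All intervals are 0-based half-open on the forward (deposited) strand;
BED output uses the same convention, and report tables that humans read
are 1-based inclusive only where explicitly labelled. Strand `+` is the
deposited strand and is displayed as "non-template", `-` as "template";
rRNA genes are deposited in the sense orientation, so this matches the
direction of RNA polymerase I transcription, but the mapping is a single
configurable switch (`strand_display`) because orientation cannot be
inferred from sequence alone. Residues are upper-cased on input and
restricted to {A,C,G,T,N}; in lenient mode other IUPAC codes become N.
N never satisfies a G- or C-tract and never counts as G or C, but it
does count in window denominators ("total bases").

## Locus reconstruction

The deposited human-type rDNA repeat begins at the 5′ETS, with the
promoter lying at the far end of the IGS across the repeat junction.
`build_locus` therefore copies the final `promoter_len` nucleotides of
the backbone in front of the full backbone and shifts all annotations.
The promoter length is exact and configurable with default 2,000 nt; a
fixed rule is required for determinism because only an approximate
promoter extent is ever stated for this locus. Note the promoter
sequence then exists twice on the reconstructed locus (once up front,
once inside the IGS), so locus-wide totals that include both regions
double-count it by construction.

## GC landscape

GC content per window is `100·(G+C)/window_size`; the default is a true
sliding window (step 1, window 100) for content and non-overlapping
100-nt tiles for skew, both configurable — profiles read naturally as
continuous, skew as binned. A trailing partial window is kept with its
actual size as denominator (flag to drop). GC skew `(G−C)/(G+C)` is
undefined where G+C = 0 and is reported as missing, never as 0, because
0 would falsely assert balance.

## Motif models

**G4 / iM.** Both canonical motifs are four tracts separated by loops:
G4 uses tracts `G{3,}` (unbounded) with loops of 1–7 nt; iM uses tracts
`C{3,10}` with loops of 1–12 nt. Loops may contain any base, including
the tract base and N. Matching is leftmost and non-overlapping with
greedy quantifiers (a run of six Gs is one tract; a run of twelve Cs
contributes its first ten). This single-pass convention is what makes
totals well defined; an all-overlapping enumeration would count the
same G-rich patch many times. Only the canonical four-tract forms are
modelled — bulged, two-tetrad and long-loop G4 variants, and any
learned stability scoring of i-motif candidates, are out of scope;
detection is purely pattern-based.

**RLFS.** An R-loop forming sequence is three zones on one strand.
The initiation zone (RIZ) is a chain of G tracts: model m1 chains ≥3
tracts of ≥3 Gs, model m2 chains ≥2 tracts of ≥4 Gs, with inter-tract
gaps of 1–10 nt of any composition and ≥50 % G over the whole span.
Every maximal G run meeting the model's tract minimum anchors a chain
that extends tract-by-tract while the gap and G-fraction constraints
hold; one maximal RIZ is emitted per (anchor, model), and m1/m2 hits
are never merged — this per-anchor emission is what produces the
clusters of records sharing an origin but differing in length that are
characteristic of this model. The linker is 0–50 nt, unconstrained.
The elongation zone (REZ) is 100–2,000 nt with ≥40 % G over its full
extent; among candidate starts within linker range, the window with the
largest end wins, ties broken by the shortest linker (deterministic,
and favouring stable propagation). G-fraction thresholds use exact
integer arithmetic (`2·G ≥ len`, `5·G ≥ 2·len`), never floating-point
rounding. Row-for-row parity with any particular historical
implementation of this model is not guaranteed, because published
descriptions leave the enumeration order and overlap policy open; the
rules above are fixed and documented so results are reproducible.

## Quantification, bins, statistics

Motifs are assigned to the unique region containing their forward-axis
start, even when they extend across a boundary; for `-`-strand records
the forward-axis start (smaller coordinate) is used, matching how
coordinate-sorted interval files are conventionally read (configurable
at the record level since both conventions appear in practice).
Densities are reported per nt and per kb; proportions are per-class
percentages that sum to 100.

`make_bins` produces a fixed count of consecutive bins of width
`floor(L/n)`, the final bin absorbing the remainder (recorded in table
metadata, since it shifts the last boundary relative to even division).
Bin counts use motif starts, strands pooled by default. Co-occurrence
is the exclusive Venn partition of bins by class presence (count > 0),
with every cell reported including the all-absent one; by default the
R-loop side is anchored on initiation zones rather than whole RLFS
spans, since the RIZ grammar is the part that resembles the G4 motif
(whole-span anchoring is available and used for signal integration).
Pearson correlation is the standard product-moment coefficient with a
two-tailed p from `t = r·sqrt((n−2)/(1−r²))` (scipy); constant vectors
are an error, never r = 0.

## Signal integration

The contractual signal input is 4-column bedGraph (or any per-bin
table); bigWig conversion happens upstream. Uncovered positions carry
signal 0, consistent with coverage-track semantics. Per-bin means,
min–max normalization (error on constant input) and Pearson correlation
follow; normalization does not change r (affine invariance) and is
applied for parity with plotted tracks. Bin-wise directionality
classifies each adjacent-bin step by the signs of Δsignal and Δcounts;
steps where either Δ = 0 are excluded from the denominator and reported
as ties — any silent tie rule (counting ties as "same" or "opposite")
would bias the fraction, and the reported tie count preserves
auditability. With sparse count vectors many steps are ties, so the
fraction should always be read together with `n_steps_used`.

## Alignment

Global (end-to-end, end gaps penalized) alignment under match 2,
mismatch −3, gap open −5, gap extend −2, with a length-L gap costing
open + L·extend (a length-1 gap scores −7, the standard affine
convention). The implementation is a banded Gotoh dynamic program over
a diagonal parallelogram with one packed traceback byte per cell and
rolling score rows (numba-compiled). Correctness of banding is
certified, not assumed: any path leaving a band of half-width w must
contain ≥ w+1 insertion and ≥ w+1 deletion columns in at least two
separate gaps, so it scores at most
`match·min(n,m) + 2·open + 2·(w+1)·extend`; the band doubles until the
banded optimum meets this bound or the band covers the matrix. Memory
is O(n·w) bytes; two ~45 kb units at primate-like divergence align in
seconds to tens of seconds within ~1–2 GiB. Ties in the DP prefer
substitution, then gap-in-second-sequence, then gap-in-first, making
the traceback deterministic. Percent identity is identical columns
over a declared denominator; the default is alignment columns
(including gap columns), with shorter-sequence and
aligned-positions-excluding-gaps selectable and always recorded,
because printed identity values are meaningless without their
denominator.

## Synthetic loci

The generator's defaults encode the study conditions: nine regions with
the real human repeat lengths (promoter 2,000; 5′ETS 3,657; 18S 1,869;
ITS1 1,077; 5.8S 157; ITS2 1,167; 28S 5,070; 3′ETS 361; IGS 31,480 —
46,838 nt total) and the reported per-region GC levels (spacers
0.79–0.84, 18S 0.5607, 5.8S 0.5732, 28S 0.6923, promoter/IGS 0.45).
Background bases are i.i.d. with G and C equiprobable within the GC
mass. Thirteen motifs (5 G4, 4 iM, 4 RLFS, both strands) are planted at
fixed offsets spread over low- and high-GC regions, written over the
background with a 1-nt non-tract flank so greedy matching cannot extend
a plant outward; RLFS plants are built constructively (RIZ grammar
string + AT linker + 50 %-G REZ) so the scanner's three-zone logic is
exercised rather than a single pattern. A post-pass re-scans the
finished locus and reports every non-planted hit as spurious —
report-don't-scrub, because removing background matches would distort
the composition the generator is supposed to emulate. Recovery of a
planted G4/iM requires the exact interval and strand; recovery of a
planted RLFS requires the exact initiation zone (the elongation zone
legitimately extends into qualifying background, so its end is not
constrained). Plants overlapped by a same-class spurious hit are
excluded from recall, since the overlapping hit changes the leftmost
non-overlap structure by construction.

What the generator does **not** emulate: real ChIP-seq read noise and
coverage artifacts, sequence periodicity and repeat substructure of a
real IGS, CpG effects, or evolutionary divergence (conservation tests
use controlled substitutions instead). Passing tests on synthetic loci
therefore demonstrate algorithmic correctness and calibration, not
biological accuracy of any particular real-locus count.

The per-bin signal generator standardizes the count vector and mixes it
with seeded unit Gaussian noise as `r·z + sqrt(1−r²)·g`, so the
expected Pearson correlation equals the target (exact at |r| = 1 with
zero noise); an optional `noise_sd` adds further independent noise on
top of the calibrated mixture. At 100 bins the sampling spread of the
recovered r around −0.5 is ≈ 0.075 (Fisher-z), so recovery within
±0.15 is expected in ≳95 % of seeds.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated
data: oracle equivalence uses 200 random sequences per scanner class at
50–500 nt, alignment cross-checks use pairs up to 500 nt against a
full-matrix reference plus 5-kb controlled-divergence demonstrations,
and locus-scale analyses use the 46,838-nt default synthetic repeat —
sizes chosen so a full run takes well under a minute while still
exercising every code path at realistic scale. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`;
identical inputs and seeds give byte-identical outputs, including the
pipeline's CSV artifacts.

## Known limitations

* Real-locus values (motif totals, published correlations, cross-species
  identities) require the NCBI accessions and the public POLR1A
  coverage track as inputs; the corresponding checks fail loudly when
  those files are absent rather than silently passing.
* RLFS enumeration freedom (see above) means absolute RLFS counts can
  differ by a few records from other implementations of the same model;
  G4/iM counts and GC statistics carry no such freedom.
* The aligner's band certificate is conservative for highly divergent
  pairs (it widens toward the full matrix as identity falls), which is
  the correct but slower behaviour below ~50 % identity.
* Percent-identity denominator choice changes values by several points
  on gapped alignments; outputs always record the mode used.
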