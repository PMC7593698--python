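# Methods

## Phase-space embedding

The unit of analysis is the *activation-phase snapshot*: the vector of all
electrodes' activation phases at one instant. Phase is a sawtooth in
[−π, π) built by linear interpolation between consecutive local activation
times (LATs), with the activation instant as the moment of phase inversion
(φ = −π just after activation, → π just before the next). Between
activations tᵢ, tᵢ₊₁:

    φ(t) = −π + 2π (t − tᵢ) / (tᵢ₊₁ − tᵢ)

Before the first and after the last activation the ramp is extrapolated
with the adjacent inter-activation interval (the AF cycle length if the
electrode has a single activation) and clipped to [−π, π); this keeps the
recording's first and last cycles usable instead of discarding them.
Electrodes with no activations are flagged invalid; snapshots containing
an invalid electrode are excluded from the distance matrix (with an index
map retained so interval times refer back to real snapshots).

Snapshots are sampled at a configurable analysis rate, default **100 Hz**
(10–30 snapshots per cycle for AF cycle lengths of 100–300 ms). Computing
all pairwise distances at a raw acquisition rate of ~1 kHz would make the
quadratic distance matrix two orders of magnitude larger for no analytic
gain; the phase signal is piecewise linear, so the embedding is
rate-stable, and tests assert that a series sampled at rate r is an exact
row-subset of the series at 2r.

## AF cycle length

AFCL is the pooled median of all inter-activation intervals across
electrodes, with the interquartile range reported as dispersion. The
median is robust to the occasional missed or doubled annotation and needs
no distributional model. `afcl_samples = round(AFCL · rate / 1000)` must
be ≥ 2.

## Activation detection (optional input path)

When raw unipolar electrograms are supplied instead of LATs, a simplified
annotator marks activations at local maxima of negative slope. The
per-electrode threshold is the 0.95 quantile of the negative-slope
magnitudes (computed over all samples; if that quantile is zero because
deflections are very sparse, the quantile of the nonzero magnitudes is
used). A refractory period (default 50 ms, conservative for AFCL
≥ 100 ms) keeps the steeper of two conflicting candidates. Flat traces
yield an empty annotation list and a logged warning. This detector is a
deliberately simple stand-in for probabilistic annotators used with real
electrograms; it is adequate for synthetic deflections.

## Snapshot distance and recurrence plot

    δᵢⱼ = arccos( clamp(meanₖ cos(φᵢₖ − φⱼₖ), −1, 1) ) / 2π  ∈ [0, 0.5]

The cosine maps phase differences of 0 and ±2π to maximum similarity and
±π to maximum dissimilarity, making the measure symmetric and cyclic. The
full matrix is computed as two rank-K matrix products (cos·cosᵀ +
sin·sinᵀ)/K and stored at float32 (values of magnitude ≤ 0.5 need at most
~7 digits).

**Adaptive threshold.** δ_max is the empirical f-quantile of the eligible
pairwise distances with f = min(1, RR_max / afcl_samples); RR_max defaults
to 1, the recurrence rate per cycle a single always-repeating pattern
would produce. Pairs closer in time than half a cycle are trivially
similar and are excluded from the quantile by default (configurable via
`exclude_band`); the recurrence rate reported for calibration uses the
same pair set, counting unordered pairs. For very long recordings the
quantile is estimated from a seeded uniform subsample of ≤ 5×10⁶ pairs
(memory-bounded; sampling error is statistically negligible at that
size). Thresholding marks (i, j) recurrent iff δᵢⱼ ≤ δ_max.

**Erosion.** A repeating pattern draws diagonal lines in the plot; the
sensitive threshold also makes those lines thick (consecutive snapshots
fall within δ_max of each other — false nearest neighbours). Erosion
replaces every maximal run of consecutive recurrences in a row with the
single cell of minimum distance, does the same for columns, intersects
the two passes, re-symmetrises by AND with the transpose, and restores
the main diagonal. Runs are allowed to contain the main-diagonal cell:
its self-distance is 0, so the trivially similar band around the diagonal
collapses onto the diagonal itself rather than leaving satellite cells
beside it. Without this, every near-diagonal block would retain ~2
recurrences per row and pattern detection would fire on pure-noise
recordings. Erosion is idempotent and never increases the recurrence
count. Pass order (rows, then columns, then AND) is fixed; for a
symmetric input the row and column passes are transposes of each other,
so the result does not actually depend on the order.

## Repetitive-interval detection

At each diagonal position t, square blocks centred at (t, t) grow from 2
cycles in steps of afcl/2 samples up to the symmetric edge-clipped
maximum 2·min(t, N−t). The block recurrence rate per cycle is

    RR(d) = (off-diagonal recurrences in the d×d block) × afcl / d²

and D(t) is the largest d with RR ≥ RR_min (default 0.9). With erosion,
RR is nearly flat inside a fully repetitive region, so "largest duration
still above RR_min" is the stable reading of the block-growing rule; the
literal "duration at maximum RR" would be degenerate. Candidate
intervals sit at local maxima of D(t) (plateaus resolved at their
midpoint, rounded down, for determinism), spanning [t − D/2, t + D/2).
Greedy resolution by descending duration discards a candidate whose
overlap with an accepted interval exceeds 50% of the **shorter**
interval's duration (the overlap denominator is configurable in
principle but the shorter interval is the stricter, deterministic
choice).

A finite-block bias follows from the normalisation: the block's own
diagonal cells are excluded from the count but not from the d²
denominator, so a perfectly periodic block saturates at RR = 1 − afcl/d,
not 1. Consequently RR_min = 0.9 implies a minimum detectable pattern
length of ~10 cycles — consonant with reporting only clusters longer
than 10 cycles — and RR_min values ≥ 1 − 1/n_cycles cannot be satisfied
by any block of n_cycles. Sensitivity grids for RR_min should therefore
stay below that ceiling (e.g., 0.75–0.93 for 15-cycle segments).

## Clustering and pattern size

The interval similarity matrix holds the pairwise cross-recurrence rate:
recurrences in the rectangular block rows(a) × columns(b), excluding
main-diagonal cells, × afcl / (d_a·d_b); values are clipped to [0, 1]
(erosion can rarely leave > 1 recurrence per cycle in thick regions and
distances must stay non-negative). Distance 1 − similarity feeds
average-linkage agglomerative clustering (scipy), cut at 1 − RR_min —
the same threshold as detection. Complete linkage is available via
config. Clusters are ranked by combined duration; those with ≤ 10 cycles
combined are dropped from reporting.

Each cluster's representative snapshot is the per-electrode **circular
mean** (angle of the summed unit phasors; a zero resultant maps to phase
0) over the recurrences on one vertical line of the eroded plot inside
the cluster's longest interval — the interval-midpoint column, falling
back to the column with the most recurrences if the midpoint holds fewer
than two. The mean phase converts to an activation-time map via
τₖ = (φₖ + π)/2π · AFCL and aₖ = max τ − τₖ (earliest electrode = 0).
Note the map is cyclic: if the wave front is mid-array at the reference
instant, the map has a wrap line there; the direction field (below) is
local and unaffected away from that line.

The per-electrode recurrent phase distance δₖᵖ is the single-electrode
specialisation of the snapshot distance averaged over all unordered
pairs of recurrence snapshots (reference-free and symmetric; a
pairs-to-reference variant would depend on the arbitrary reference
column). Pattern size counts electrodes with δₖᵖ ≤ δ_max (adaptive mode)
or δₖᵖ·AFCL < Δt with Δt default 10 ms (fixed mode), each contributing
one spacing² unit cell, reported in cm². The adaptive comparison is
inclusive: on noise-free periodic inputs the distance distribution has
an atom at 0 and the quantile threshold can coincide with it; an
electrode exactly at threshold did recur and is counted.

Conduction direction per electrode is the normalised spatial gradient of
a local least-squares plane fit of activation time over neighbours
within 1.5 × spacing (≥ 3 non-collinear sites required), pointing from
early to late activation — the direction of wave-front travel.
Degenerate neighbourhoods or flat fits yield NaN. The gradient of the
average map is used rather than averaging per-cycle velocity vectors;
for the noise-free simulator fixtures the two coincide.

## Synthetic data

Wave kinematics are closed-form so ground truth is exact: planar fronts
arrive at t₀ + (r·u)/CV, focal/breakthrough at t₀ + |r − origin|/CV,
re-entry at a phase-of-rotation delay (angle/2π × period, plus a radial
delay), collisions as the earliest of two planar fronts. Per-cycle
Gaussian jitter and per-activation Gaussian noise are added from a
seeded generator; identical seeds give bit-identical output.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| array | 249 electrodes, 2.4 mm, circular | the reference high-density mapping array |
| cycle length | 150 ms | mid-range AF cycle length |
| conduction velocity | 0.5 mm/ms | slowed conduction of remodeled AF atria; gives the ~38 mm array ≈ half a cycle of phase span, so differently directed waves are distinguishable snapshots |
| analysis rate | 100 Hz | 15 snapshots/cycle at 150 ms |
| deflection template | one-cycle sine, 8 ms | biphasic unipolar morphology with the steepest negative slope at the annotated instant |
| electrogram SNR reference | deflection RMS | whole-record power is dominated by silent baseline and would overstate noise tolerance |

The AF-like sweep fixture (`af_like_schedule`) alternates a dominant
planar direction with randomly directed interlopers at 15 ms activation
noise and 8 ms cycle jitter. That noise level places the adaptive δ_max
(at RR_max = 1) inside 0.1–0.25, the operating range observed on real AF
recordings and the range the fixed-δ_max sensitivity grid is built on;
the adaptive-vs-fixed robustness contrast is a property of that regime.

What the simulator does **not** emulate: conduction heterogeneity and
curvature, wave-front fractionation and block, electrogram far-field and
fractionated morphology, 3-D transmural conduction, and drifting or
meandering sources. Passing tests therefore demonstrate correctness of
the analysis chain on idealised kinematic patterns, not clinical
performance on fibrillating tissue.

## Problem sizes and numerical choices

Test and acceptance fixtures use 60–120 cycle recordings (≈ 900–1800
snapshots at 100 Hz) on 49–249-electrode arrays; the threshold-calibration
check uses 3000 snapshots. Distances are float32; quantiles use linear
interpolation; `arccos` arguments are clamped to [−1, 1]; block counts use
an integral image (O(1) per block); circular-mean ties (zero resultant)
resolve to phase 0; candidate-interval ties break by earliest start. The
eroded recurrence rate of a finite periodic recording of N snapshots falls
short of 1 by ≈ (afcl − 1)/(N − 1) plus edge effects (≈ 0.974 at 60
cycles), within the ±10% band used for that check.

## Limitations

- The adaptive threshold intentionally over-admits on multi-pattern
  recordings (calibration assumes one always-repeating pattern), relying
  on erosion and the RR_min block constraint to reject false positives;
  at very low organisation the detected interval set is sensitive to
  RR_min.
- Intervals are axis-aligned square blocks: patterns that drift in rate
  (curved diagonal lines) are fragmented rather than tracked.
- The per-electrode distance map uses all recurrence pairs of one
  reference column; rare patterns whose recurrences cluster at interval
  edges may be summarised from few snapshots.
- The activation-time map inherits a cyclic wrap at the wave-front
  position of the reference snapshot.
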