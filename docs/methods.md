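# Methods

## Data model and assumptions

A mapped dendritic segment is a one-dimensional marked point pattern:
spine path positions `d_1 ≤ … ≤ d_N` (µm, origin at the segment start)
with a binary input mark per spine.  Segments between branch points
are analyzed independently; distances never cross segment boundaries,
and the null model below reshuffles marks within each segment.  The
null hypothesis throughout is *random assignment*: the `n` observed
inputs are a uniformly random `n`-subset of the `N` recorded spines.
Position ties (spines facing each other on the shaft) are allowed,
kept in file order, and flagged by the validator; unmapped stretches
inside a segment are not modeled.

## Ensembles and the specific ensemble likelihood

An *ensemble* is a maximal group of positive spines in which each
consecutive pair is within the nearest-neighbor criterion Δ_crit
(default 10 µm, closed comparison).  Its *type* is `(l_M, m, l_g)`:
window length `l_M` (the realized span for an observed ensemble),
input count `m ≥ 2`, and gap length `l_g = Δ_crit`.

The SEL is computed by the anchored window construction: for each
anchor spine `d_i`, the closed window `[d_i, d_i + l_M]` holds `M_i`
spines; the leading and trailing gap intervals hold `g_i` and `h_i`.
The number of assignments realizing the type at anchor `i` is
`C(M_i − 2, m − 2) · C(N − M_i − g_i − h_i, n − m)` — both window edge
spines carry an input (they delimit the ensemble), the remaining
`m − 2` ensemble inputs occupy interior window spines, the gaps are
input-free, and the other `n − m` inputs sit outside window and gaps.
Windows holding fewer than `m` spines contribute nothing, and gaps
truncated by the segment ends count only the spines that exist.
Summing over anchors and dividing by `C(N, n)` gives the
per-arrangement likelihood; the SEL sums it over all input counts from
`m` to `min(n, M_max)`, `M_max` being the largest window census for
that `l_M`.

**Gap boundary convention.**  The gap censuses use open intervals
`(d_i − l_g, d_i)` and `(d_i + l_M, d_i + l_M + l_g)`, so a spine is
never attributed to both the window and a gap; on the unit-lattice
worked example (Δ_crit = 2) this yields exactly one gap spine per side
and an outside count of 22.  A `closed` variant (far gap boundary
included) is exposed as a configuration switch; on continuous
positions the boundary set has measure zero, so the choice is
immaterial for real data.

**Exactness.**  All counts are arbitrary-precision integers; division
happens once at the end, and every likelihood is returned as a
`fractions.Fraction`.  Threshold comparisons (e.g. SEL ≤ 1%) are
therefore exact.

**The anchored sum is an inclusion count, not a probability.**  The
same assignment can realize windows at several anchors, so the SEL
upper-bounds the probability of the union of anchored realizations.
`brute_force_sel` enumerates all `C(N, n)` assignments (feasible up to
10^7) and evaluates that union event directly — some anchor window
with both edges positive, at least `m` positives inside and input-free
gaps.  Equality holds whenever realizations at distinct anchors cannot
co-occur, in particular whenever `n = m`; on lattices up to N = 12 the
two agree exactly except on instances where two disjoint realizations
genuinely co-occur, and there the SEL exceeds the exact probability by
construction (union-bound direction), by about 2% on the worked
example.  Note the window event does not re-check the internal spacing
of the `m` inputs — that is a property of the published counting
construction, which treats the window as the ensemble.  A related
consequence: for `n = m = 2` the second binomial factor is `C(·, 0)`,
so the SEL is independent of `l_g`; it coincides with the probability
that the two inputs are within Δ_crit only on unit lattices with
`l_g = 1`.

## Cluster classification

An ensemble is a cluster when SEL ≤ 1% (empirical threshold), it has
at least 3 inputs, and it does not encompass the whole segment
(`d_N − d_1 ≥ l_M ≥ d_N − d_1 − 2·l_g` with `m = n`); a segment whose
every input lies in one group is evidence about the segment, not about
a cluster within it.  Degenerate segments (N < 3 or n < 2) carry no
ensemble structure; their likelihood operations return 1 by convention
and they produce no cluster candidates.

## Overall cluster likelihood

The OCL of a called cluster is the likelihood that the segment shows
*any* ensemble type at least as unlikely as the cluster's own SEL.
Candidate window lengths are the distinct pairwise spine spans, capped
at `(m − 1)·l_g` for input count `m` (an ensemble of `m` inputs with
consecutive spacing ≤ `l_g` cannot span more).  For each candidate
length the δ-selector picks the smallest `m` whose SEL drops to or
below the starred SEL — so the `(m−1)` type at the same length is not
also below threshold, which would double-count its larger event.

A spine set realizes the type definition for every window length from
its own span upward; summing full SEL terms over all candidate lengths
would therefore count the same sets many times over (on null segments
such a sum exceeds 1).  Each set is instead attributed to the single
length it realizes *tightly* — the anchored terms restricted to
windows ending exactly on a spine.  The result is a union bound on the
probability that the segment carries any ensemble at least as unlikely
as the starred one: per-geometry Monte-Carlo checks on random-mark
segments show the OCL exceeding that probability by a factor of about
1.2–1.4, and an exhaustive small-instance oracle confirms the bound
direction.  On uniform lattices every interior window is tight and the
OCL reduces to plain SEL sums, which also guarantees OCL ≥ SEL(starred)
there; on continuous maps the tight anchors are a strict subset of the
anchored sum, so that inequality is not guaranteed in general (in
practice OCL exceeds the starred SEL by an order of magnitude, because
many other types qualify).

One caveat worth stating plainly: the OCL is a per-cluster tail
quantity evaluated at the *observed* SEL.  The fraction of null
segments that produce any cluster call at the 1% SEL threshold is a
different (larger) quantity — calling is a fixed-threshold event with
multiplicity over types, whereas the mean OCL over calls averages tail
probabilities at observed SELs well below the threshold; by the
probability-integral-transform argument even an exactly calibrated
tail quantity averages about half the call rate.  The package's
calibration guarantee is superuniformity — the rate of calls with
OCL ≤ u does not exceed u (tested) — not equality of the call rate
with the mean OCL.

## Segment-count test

Segments of span ≥ 20 µm are eligible.  Each cluster-bearing segment
contributes its smallest OCL; with values sorted ascending, the
probability of at least `c` cluster segments among `S` at bound
`OCL_max(c)` is the binomial tail `Σ_{x=c..S} C(S,x) p^x (1−p)^{S−x}`
(scipy.stats.binom), and the largest `c` with `P < 0.001` is reported.

## Nearest-neighbor analysis

Per positive spine, the distance to the nearest positive neighbor on
the same segment, pooled over segments; histogram in right-open 1 µm
bins over [0, 50) µm.  The null redraws, per segment and iteration, a
uniformly random subset of spine positions of the recorded positive
size (1000 iterations by default); segments with a single positive
relocate their mark but contribute no distance, keeping the null
comparable to the data.  Histograms are normalized per iteration and
then averaged.  The observed median is compared by a two-sided normal
z-test against the null mean and SD, with the empirical percentile
reported alongside.  Randomness flows from one master seed through
per-segment substreams (sorted key order), so input ordering cannot
change results.

## Slice-truncation correction

Radial axon density `A(r) = crossings / (4π r² δr)` from a Sholl-style
crossing profile, with presynaptic neuron density assumed uniform.
For a site at depth `D` in a slice of thickness `T`, the retained
shell volume is piecewise: complete (`4πr²δr`) below the near-face
distance, one cap removed (`2πr(r + d_near)δr`) between the near and
far face distances, two caps removed (`2πrTδr`) beyond; the published
case split assumes `D < T/2`, symmetrized here via
`d_near = min(D, T−D)` so any depth is valid, with the pieces
continuous at both boundaries.  The remaining fraction `F(D)` is the
density-weighted ratio of retained to complete shell volumes,
midpoint-quadrature over the profile's own bins with no extrapolation
beyond `r_max` (taken from the profile's last bin when not given).
`1 − F` estimates the fraction of inputs missed by slicing; the
published profile puts it between 30% and 50% depending on depth, a
number that requires that external profile as input and is therefore
reported, not unit-tested.  A rejection-sampling oracle (uniform
points in the sphere, slab fraction) reproduces `F` to ≲ 0.05% for
uniform density.

## Input classification from ΔG/R traces

Per trial: 50 frames at 10 Hz — shutter-closed offset frame, 5
baseline frames, 2 shuttered stimulus frames, 42 response frames.
Spine ROI intensities average the brightest 70% of pixels by mean red
intensity (fixed across frames); dendrite ROIs average all pixels.
The electrical offset is subtracted from both channels, ΔG is the
green deviation from the baseline mean, and ΔG/R divides by the mean
red intensity over open-shutter frames.  Baseline and response
sections are smoothed with a 3-point moving average *separately* —
they are discontinuous in time across the shuttered stimulus, and
smoothing across the gap would bleed the response onset into the
baseline noise estimate.  The peak is the smoothed maximum over the
2nd–4th post-stimulus points (frames 10–12); SDs are taken over the
smoothed baseline and the last five points.

A spine is input-positive if in at least one trial its peak exceeds
the paired dendritic peak plus three times the larger of the two SDs.
The SDs are taken from the spine trace (they bound the measurement
noise of the compared peak); a switch folds in the dendrite SDs, and
an optional secondary criterion requires the spine peak to precede the
dendritic peak (disabled by default — the primary rule is
threshold-only).  The classifier is invariant to a common gain on both
channels.  Manual re-verification of classifier output is out of
scope.

## Synthetic data

The generator emulates the mapped data's statistical structure: spine
positions as a homogeneous point process at 0.8 spines/µm on segments
of length U(40, 90) µm (matching a mapped mean of roughly 68 µm per
segment), background input probability 0.092, optional implanted
clusters of 7 inputs within a 12.5 µm window (the geometry of observed
clusters), and trace tables with release probability 0.5 per trial
(no published estimate exists; configurable), success amplitude 0.48,
dendritic amplitude 0.18 on every trial, Gaussian noise SD 0.05, 3
trials per spine.  Transients rise instantaneously at the first
response frame and decay exponentially with a 0.5 s time constant —
only the peak-window behavior matters to the classifier.  All
randomness derives from a single seed; identical configurations
regenerate bit-identical data.

What the generator does *not* emulate: biophysical calcium dynamics
(dye buffering, NMDA kinetics), spatially inhomogeneous spine
densities, correlated release across trials, imaging artifacts (focus
drift, bleaching), or heterogeneous per-cell input rates.  Passing
tests demonstrate correctness of the statistics under the stated point
process and noise model, not robustness to those real-data features.

## Simulation sizes and numerical choices

Calibration tests use 1000 random-mark segments (N = 50, n = 5, 60 µm)
for cluster-call behavior, 100 datasets of 15 segments with 300
reshuffles each for the z-test, 200 seeded simulations for implanted
cluster recovery (100-iteration nulls), ≥ 500 synthetic spines per
release probability for the classifier, and 2×10^6 Monte-Carlo points
for the slice geometry oracle.  Exhaustive oracles cover all lattice
instances with N ≤ 12, n ≤ 4.  Duplicate positions are flagged at
1e-9 µm; tight-window tests use the same absolute tolerance; the
binomial tail and normal p-values come from scipy.  Exhaustive
enumeration refuses instances beyond 10^7 assignments.

## Known limitations

- The anchored SEL is an upper bound, not an exact probability, when
  disjoint realizations can co-occur; the bias is conservative
  (clusters look less significant, never more).
- The OCL depends on a reading of the published "count each set once"
  restriction; the tight-window attribution implemented here is a
  calibrated union bound, but other readings are conceivable.
- No correction is applied for unmapped stretches inside segments, and
  segments are never concatenated across branch points.
- The trace classifier assumes the frame layout above; other
  acquisition protocols require a custom `FrameRoles`.
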