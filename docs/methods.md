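# Methods

## Model

A brain region's response to a continuous stimulus is modeled as a sequence
of `K` discrete event states, each expressed as a distinct spatial activity
pattern over the region's voxels. The event segmentation model is a
left-to-right hidden Markov chain: states must be traversed in order
0..K−1, the only transitions are "stay" and "advance by one", the sequence
starts in state 0 at the first timepoint and ends in state K−1 at the last,
so every event occupies at least one timepoint and a fit always yields
exactly K−1 boundaries (a boundary index is the first timepoint of the new
event; event intervals are half-open `[start, next_start)`).

Emissions are isotropic Gaussians over *spatially z-scored* activity
patterns: each timepoint's pattern is centered and scaled to unit variance
across voxels (population denominator), which makes the squared emission
distance an affine function of the spatial Pearson correlation. State means
are free parameters; a single emission variance is shared by all states and
re-estimated each M-step. Transition probabilities are fixed, not
re-estimated: the advance probability is `K/T` (expected event length
`T/K`), since boundary placement should be driven by the emissions and
fixed transitions keep EM stable on short runs (~56 timepoints). Whether
the upstream literature fits this model on spatially z-scored patterns or
raw per-voxel z-scored timecourses is ambiguous; spatial z-scoring is
adopted here as an explicit assumption so that the Gaussian emission
geometry matches the correlation geometry used by the similarity statistic.

### Fitting

EM with an exact forward–backward E-step in log space (the end-state
constraint is imposed through the backward initialization). Convergence:
absolute log-likelihood change below `tol = 1e-4`, at most `max_iter = 100`
iterations per initialization; the log-likelihood is non-decreasing across
EM iterations up to 1e-6 numerical slack. The shared variance is floored at
1e-6 so noise-free input cannot collapse the likelihood.

Because all monotone complete state paths contain exactly K−1 advances and
T−K stays, the transition term is identical for every segmentation and the
best hard labeling is the least-squares segmentation. Plain EM from a single
uniform partition of time can stall in a local optimum when the planted
event durations are very uneven, so the fit runs from two deterministic
initializations — the uniform partition, and a greedy top-down
least-squares binary splitting (O(K·T·V) with prefix sums) — and keeps the
run with the higher final log-likelihood. Fits are therefore deterministic
without seeds. On small instances (T ≤ 14, K ≤ 3) this matches exhaustive
search over all monotone segmentations in ≥ 499/500 random instances.

Labels are the monotone-path argmax of the posterior: a dynamic program
maximizes the summed per-timepoint log-posterior over valid left-to-right
complete paths, with ties broken toward the earlier state. Whenever the
plain per-timepoint argmax is itself a valid complete path the two coincide;
the constrained version additionally guarantees the label invariants
(monotone, all K states present) in every case.

## Within- vs. between-event similarity (WvB)

For a T×T matrix of spatial pattern correlations, every pair `(t, t+lag)`
with `lag = 5` TRs (chosen to step over BOLD autocorrelation) is *within*
one event iff no boundary `b` satisfies `t < b <= t+lag`, else *between* —
a pair spanning several boundaries is simply *between*. WvB is the mean
within-pair correlation minus the mean between-pair correlation, in
[−2, 2]. Pairs are at exactly the lag, not up to it. If either pair class
is empty (every fitted event shorter than the lag) the value is undefined,
propagates as missing, and is excluded from downstream averages with a
logged count.

An intrinsic resolution limit follows: events that do not outlast the lag
contribute no within pairs, so WvB cannot discriminate event counts whose
extra boundaries subdivide lag-scale segments. The synthetic validations of
timescale identification therefore plant events of at least 10 timepoints
(5 at the fastest timescale, where 56 timepoints cannot hold 10 longer
events).

### Cross-validation

Participants are split in half (5 random splits by default), stratified
within counterbalance group; the HMM is fit on the train half's
group-average timecourse and its boundaries are scored on the held-out
half's group average; the two directions, the counterbalance groups, and
the splits are averaged. Group averages are means of the per-participant
z-scored timecourses; spatial z-scoring is re-applied inside the HMM and is
implicit in the correlation, keeping the geometry consistent. The
individual-level variant trains on a half-group average and scores each
held-out participant's own timecourse, averaging each participant's value
over every split in which they were in the test half.

## Permutation nulls and filtering

**Segment-shuffle null (is WvB > 0?).** The fitted event durations are
reordered, giving boundaries with the real spacings at arbitrary positions;
orderings are deduplicated on the boundary vector they induce and the real
vector is excluded. All distinct orderings are enumerated when there are at
most `max_perm = 50`, otherwise 50 distinct ones are sampled. Null values
from all event counts (2–10) are pooled and a normal is fitted per
searchlight/clip/viewing; the one-tailed p for each event count is the
fitted upper-tail area above the real value. If every segment has equal
length there are no valid orderings and the searchlight is flagged.

**Reliable-searchlight filter.** A searchlight is kept for a clip iff every
viewing has at least one event count with WvB > 0 and p < 0.05 (one-tailed).
The source description of this threshold prints the inequality in the
opposite direction, which contradicts its own stated intent ("significantly
greater than the null"); it is implemented as p < 0.05 and the filter's
in/out counts are logged so the choice is auditable.

**Viewing-shuffle null (did structure change?).** The change statistic is
`Δ(K) = mean(WvB, viewings 2–6) − WvB(viewing 1)` at K = 2 (slow) and
K = 10 (fast). Each of 50 null datasets permutes the order of the six
viewings independently per participant (duplicate global permutations are
allowed — 50 draws is far below the permutation space) and the full
cross-validated pipeline is re-run; the two-tailed p is
`2·min(Φ(z), 1−Φ(z))` for the observed Δ against a normal fitted to the
null Δs. BH-FDR at q = 0.05 is applied per clip and timescale. Direction
labels: gaining slow or losing fast structure = *coarser*; losing slow or
gaining fast = *finer*; both = *mixed*.

**Conjunction.** On the intersection of each clip's reliable searchlights,
per-clip BH at alpha `0.05^(1/3)` (cube root, so the 3-clip conjunction is
controlled at q < 0.05; config-exposed) per timescale; a searchlight is
flagged only if significant in all three clips with the same sign of Δ.
Tests with undefined p (degenerate nulls) drop out of the BH family rather
than being imputed.

**Brain–behavior.** Per-participant Δ values at each flagged searchlight's
group-selected timescale are averaged across clips and regressed on average
recall with a participant-level percentile bootstrap of the OLS slope
(10,000 iterations; robustness comes from the resampling, with an optional
Huber-loss point estimate behind a flag, since "robust bootstrap
regression" admits several readings). Recall contrasts between clip
conditions use standard paired t-tests.

## Synthetic cohorts

The generator emulates the repeated-viewing design: ~30 participants, 2
counterbalance groups (round-robin), 3 clips × 6 viewings, 56 timepoints
per viewing (a 90 s clip at TR = 1.5 s minus 4 discarded volumes), 125
voxels per region. Clip-level event patterns are i.i.d. standard normal per
voxel, row-normalized; each participant gets a perturbed copy (additive
normal, scale `participant_sd`), stable across viewings. Segment durations
are uniform over compositions with a minimum length (the real stimulus's
segments were fixed by the editing; any fixed rule suffices for testing).
Viewings of one clip share the segment plan for a given event count —
repeated viewings of the same stimulus have the same stimulus-driven
boundaries — which is exactly what makes viewings exchangeable under the
no-change null; a flag redraws the plan per viewing to emulate an
unstable-order stimulus. Emission noise is i.i.d. Gaussian per voxel;
every matrix is z-scored per voxel across time (matching the real-data
preprocessing) to 1e-8.

A timescale change is planted by mapping viewing → true event count (e.g.
4 events on viewing 1, 2 events afterwards). Each participant carries an
effect weight `w ~ Uniform(effect_low, effect_high)`: changed viewings mix
`(1−w)` of the first-viewing structure with `w` of the changed structure,
so `w` is the planted per-participant change magnitude. Recall is
`intercept + slope·w + noise`, floored at zero and real-valued by default
(integer detail counts are behind a rounding flag to keep regression tests
smooth). Per-participant variation is pattern noise, not boundary jitter
(jitter is a flag, default off), so ground truth stays exact for recovery
tests.

Defaults `noise_sd = 0.4`, `participant_sd = 0.3` at 125 voxels were chosen
empirically — within-participant variability across identical viewings is
not documented for the real data — as the strongest noise at which
planted-structure regions reliably pass the reliability filter; the
validation suite uses 0.3–0.5. What the generator does *not* emulate:
3-D spatial autocorrelation, hemodynamic convolution, scanner drift, or
stimulus-locked boundary variability across participants. Passing tests
show the estimator and inference chain are correct and calibrated under
the model's own assumptions, not that real fMRI satisfies them.

## Searchlights

Spheres are closed Euclidean balls in voxel units (the target acquisition
is 2 mm isotropic, so anisotropy is ignored) of radius 5 on a stride-5
lattice starting at the grid origin (offset configurable; the exact centers
of the original searchlight set are not published). Searchlights need ≥ 20
in-mask voxels and, in real-data mode, valid data from ≥ 15 participants
(a participant is valid for a searchlight iff all member voxels are valid).
Voxel maps average each voxel over all searchlights containing it; NIfTI
affines pass through unchanged.

## Problem sizes in the validation suite

The test suite and acceptance script run the full machinery at reduced but
structurally faithful sizes chosen as the package's own validation budget:
6–12 participants, 30–56 timepoints, 30–125 voxels, 1–2 splits, 50
permutations / null datasets, 100 seeds for recovery and power checks, 200
simulated searchlights for type-I calibration. At these sizes the
false-positive rate of the viewing-shuffle test sits inside the exact
binomial 99% interval around 0.05 and its p-values pass a KS uniformity
test, planted coarsening/fine-tuning is recovered with the correct sign in
≥ 90% of seeds, and planted timescales are identified in ≥ 90% of cohorts.

## Numerical notes

- The forward–backward recursion runs through a numba-compiled kernel when
  numba is importable; a pure-numpy implementation is the reference and
  fallback, and a test pins the two to 1e-10 agreement.
- The percentile-bootstrap slope test is first-order accurate only: at
  n = 30 its measured size is ~6% at nominal 5% (mild liberality inherent
  to the method, not a bug); the permutation tests, whose exchangeability
  is exact, are calibrated to the exact binomial interval.
- Mixture-based participant effects interact with per-voxel temporal
  z-scoring: mean removal makes the first-viewing and changed-structure
  components non-orthogonal, and for mixture weights below ~0.5 the shared
  changed-structure correlation largely cancels. Planted-change studies
  therefore draw effect weights in [0.5, 1] (or exactly 1 for exact
  recovery tests).

## Known limitations

- The WvB statistic is blind to events shorter than the lag; at K = 10 and
  T ≲ 60 many fitted events are near that limit and fast-timescale values
  can be undefined on short runs (they propagate as missing).
- The EM fit is guaranteed only to a local optimum; the dual deterministic
  initialization empirically reaches the global segmentation optimum on
  small instances but carries no proof.
- One shared emission variance assumes homogeneous pattern noise across
  events.
- The pipeline compares viewing 1 against the mean of viewings 2–6 only; no
  trajectory modeling across viewings.
- `n_splits` is shared by the WvB and change stages; the per-participant
  behavior variant reuses the same split machinery.
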