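# eventscales

Multi-timescale neural event segmentation and change analysis for repeated
naturalistic viewing.

## The problem

When people watch a continuous stimulus (a movie clip), activity in a brain
region unfolds as a sequence of discrete *event states*, each expressed as a
stable spatial activity pattern. Different regions segment experience at
different granularities — a few long events (a slow timescale) or many short
ones (a fast timescale) — and, when the same clip is viewed repeatedly, a
region's event structure can become *finer* or *coarser* with familiarity.
`eventscales` quantifies event structure at multiple timescales
simultaneously, tests how its strength changes across repeated viewings, and
links those changes to memory — for researchers analyzing repeated-viewing
fMRI designs, and for method validation on fully synthetic cohorts with
known ground truth.

## The method

For a voxel × time matrix the package fits a left-to-right hidden Markov
model with `K` event states (`K = 2..10`): states advance in order with no
skips, the sequence starts in state 0 and ends in state `K−1`, and emissions
are isotropic Gaussians on spatially z-scored patterns with a single shared
variance. The strength of event structure at each `K` is the **within- vs.
between-event similarity (WvB)**: over all timepoint pairs `(t, t+5)` at a
fixed lag of 5 TRs,

```
WvB(K) = mean corr(within-event pairs) − mean corr(boundary-spanning pairs)
```

estimated with split-half cross-validation (boundaries fit on one half's
group-average timecourse, scored on the held-out half, both directions and
several stratified splits averaged). Significance comes from a
segment-shuffle permutation null (reordered event durations, pooled across
event counts, summarized by a fitted normal). Change with repetition is

```
Δ(K) = mean WvB over viewings 2–6 − WvB on viewing 1
```

at the slowest (`K=2`) and fastest (`K=10`) timescales, tested against a
viewing-shuffle permutation null with Benjamini–Hochberg FDR, combined
across clips by a sign-consistent conjunction at per-clip alpha
`0.05^(1/3)`, and related to recall scores by a participant-level bootstrap
regression.

## Worked example

```python
import numpy as np
from eventscales import (SyntheticConfig, simulate_cohort, split_participants,
                         fit_event_hmm, wvb_crossval)

cfg = SyntheticConfig(n_participants=6, n_groups=1, n_clips=1, n_viewings=1,
                      n_timepoints=56, n_voxels=125, true_event_counts=4,
                      min_segment_len=10, noise_sd=0.5, participant_sd=0.2,
                      seed=903)
ds, truth = simulate_cohort(cfg)
print("planted boundaries:", truth.boundaries[(0, 0)])

seg = fit_event_hmm(ds.data[:3, 0, 0].mean(axis=0), K=4)
print("fitted boundaries:", seg.boundaries)

splits = split_participants(np.arange(6), ds.groups, 2, np.random.default_rng(3))
for K in (2, 4, 8):
    v = wvb_crossval(ds.data[:, 0, 0], ds.groups, splits, K=K, lag=5)
    print(f"WvB at K={K}: {v:.3f}")
```

prints

```
planted boundaries: [10 21 46]
fitted boundaries: [10 21 46]
WvB at K=2: 1.079
WvB at K=4: 1.097
WvB at K=8: 0.685
```

The 4-event HMM recovers the planted boundaries exactly, and the
cross-validated WvB profile peaks at the planted event count: within-event
pattern correlations exceed boundary-spanning ones the most when the model's
timescale matches the region's true timescale.

The same analysis runs from the shell on a YAML config:

```bash
eventscales all --config cfg.yaml --out run1/
```

producing `wvb.tsv`, `reliable.json`, `change.tsv`, `conjunction.tsv`,
`behavior.tsv` and a `manifest.json` recording seeds and per-stage counts.
Real 4D NIfTI volumes plus a brain mask and metadata table are supported via
`mode: nifti` with spherical searchlights (radius 5, stride 5 voxels).

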