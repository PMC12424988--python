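"""Synthetic cohorts of event-structured neural timecourses with known ground truth.

Emulates the repeated-viewing design the analysis targets: ~30 participants in
2 counterbalance groups watch 3 clips 6 times each; each viewing yields a
voxel x time matrix (default 56 timepoints, i.e. a 90 s clip at TR = 1.5 s
with the first 4 volumes discarded) built from a sequence of discrete event
states, each with its own spatial pattern, plus Gaussian noise.  Every matrix
is z-scored per voxel across time, matching the preprocessing of the real
data.  A viewing-indexed map of true event counts lets a timescale change be
planted across repetitions (e.g. 10 events on the first viewing, 2 events
afterwards), and a per-participant effect weight links the magnitude of that
change to simulated recall scores so brain-behavior analyses can be validated
end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "SyntheticConfig",
    "SyntheticTruth",
    "CohortDataset",
    "make_event_patterns",
    "draw_segment_lengths",
    "boundaries_from_lengths",
    "simulate_timecourse",
    "simulate_cohort",
    "simulate_recall",
]

CONDITIONS = ("intact", "sfix", "srnd")


@dataclass
class SyntheticConfig:
    """Parameters of a simulated cohort.

    ``true_event_counts`` is either a single event count used for every
    viewing or a mapping from 1-based viewing index to the planted event
    count for that viewing, which is how a timescale change across
    repetitions is introduced.  ``effect_low``/``effect_high`` bound the
    per-participant effect weight w ~ Uniform(low, high): for viewings with a
    changed event count the participant's signal is (1 - w) x the
    first-viewing structure + w x the changed structure, so w is the planted
    per-participant change magnitude used by the behavior link.
    """

    n_participants: int = 30
    n_groups: int = 2
    n_clips: int = 3
    n_viewings: int = 6
    n_timepoints: int = 56
    n_voxels: int = 125
    true_event_counts: Mapping[int, int] | int = 4
    min_segment_len: int = 3
    noise_sd: float = 0.4
    participant_sd: float = 0.3
    effect_low: float = 1.0
    effect_high: float = 1.0
    boundary_jitter_sd: float = 0.0
    behavior_slope: float = -10.0
    behavior_noise_sd: float = 5.0
    recall_intercept: float = 22.0
    round_recall: bool = False
    seed: int = 0
    participant_effects: np.ndarray | None = None  # override the Uniform draw
    # Viewings of one clip share stimulus-driven boundaries, so by default the
    # segment plan is drawn once per distinct event count per clip; True
    # redraws it on every viewing (an unstable-order stimulus).
    redraw_boundaries_per_viewing: bool = False

    def event_counts_by_viewing(self) -> list[int]:
        if isinstance(self.true_event_counts, Mapping):
            return [int(self.true_event_counts[v]) for v in range(1, self.n_viewings + 1)]
        return [int(self.true_event_counts)] * self.n_viewings

    def validate(self) -> None:
        for name in (
            "n_participants",
            "n_groups",
            "n_clips",
            "n_viewings",
            "n_timepoints",
            "n_voxels",
            "min_segment_len",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2 for pattern correlations")
        if self.noise_sd < 0 or self.participant_sd < 0 or self.behavior_noise_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0.0 <= self.effect_low <= self.effect_high:
            raise ValueError("require 0 <= effect_low <= effect_high")
        for K in self.event_counts_by_viewing():
            if K < 1:
                raise ValueError("true event counts must be >= 1")
            if K * self.min_segment_len > self.n_timepoints:
                raise ValueError(
                    f"infeasible segment plan: K={K} events of >= "
                    f"{self.min_segment_len} timepoints do not fit in T={self.n_timepoints}"
                )


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests.

    boundaries[(clip, viewing)] are the planted boundary indices (viewing is
    0-based here); event_patterns[(clip, K)] is the K x V clip-level pattern
    matrix; participant_effects is the planted per-participant change weight;
    recall_true[(participant, clip)] the noiseless recall value.
    """

    boundaries: dict = field(default_factory=dict)
    event_patterns: dict = field(default_factory=dict)
    participant_effects: np.ndarray | None = None
    recall_true: np.ndarray | None = None


@dataclass
class CohortDataset:
    """In-memory cohort: data[(participant, clip, viewing)] -> V x T, plus metadata."""

    data: np.ndarray  # (n_participants, n_clips, n_viewings, V, T)
    groups: np.ndarray  # (n_participants,)
    config: SyntheticConfig

    @property
    def metadata(self) -> pd.DataFrame:
        rows = []
        for p in range(self.data.shape[0]):
            for c in range(self.data.shape[1]):
                for v in range(self.data.shape[2]):
                    rows.append(
                        {
                            "participant_id": f"sub-{p:02d}",
                            "clip": c,
                            "condition": CONDITIONS[c % len(CONDITIONS)],
                            "viewing": v + 1,
                            "group": int(self.groups[p]),
                        }
                    )
        return pd.DataFrame(rows)

    def viewing_stack(self, clip: int) -> np.ndarray:
        """(n_participants, n_viewings, V, T) array for one clip."""
        return self.data[:, clip]

    def to_hdf5(self, path, *, key: str = "cohort") -> None:
        import h5py

        with h5py.File(path, "a") as f:
            if key in f:
                del f[key]
            g = f.create_group(key)
            g.create_dataset("data", data=self.data)
            g.create_dataset("groups", data=self.groups)
            g.attrs["seed"] = self.config.seed

    @classmethod
    def from_hdf5(cls, path, *, key: str = "cohort", config: SyntheticConfig | None = None):
        import h5py

        with h5py.File(path, "r") as f:
            g = f[key]
            data = g["data"][...]
            groups = g["groups"][...]
            seed = int(g.attrs.get("seed", 0))
        cfg = config or SyntheticConfig(
            n_participants=data.shape[0],
            n_clips=data.shape[1],
            n_viewings=data.shape[2],
            n_voxels=data.shape[3],
            n_timepoints=data.shape[4],
            seed=seed,
        )
        return cls(data=data, groups=np.asarray(groups), config=cfg)


def make_event_patterns(K: int, V: int, rng: np.random.Generator) -> np.ndarray:
    """K independent spatial patterns, each centered and unit-variance across voxels.

    Rows are i.i.d. standard normal before normalization, so the expected
    pairwise row correlation is 0 (O(1/sqrt(V)) fluctuations).
    """
    if V < 2:
        raise ValueError("V must be >= 2 (pattern correlation undefined otherwise)")
    if K < 1:
        raise ValueError("K must be >= 1")
    P = rng.standard_normal((K, V))
    P = P - P.mean(axis=1, keepdims=True)
    sd = P.std(axis=1, keepdims=True)
    if np.any(sd == 0):  # essentially impossible for continuous draws
        raise ValueError("degenerate zero-variance pattern row")
    return P / sd


def draw_segment_lengths(
    K: int, T: int, min_len: int = 3, rng: np.random.Generator | None = None
) -> np.ndarray:
    """K segment lengths >= min_len summing to T, uniform over compositions.

    Uses the stars-and-bars bijection: a composition of T with K parts
    >= min_len corresponds to a choice of K-1 bar positions among
    T - K*min_len + K - 1 slots, sampled without replacement.
    """
    if rng is None:
        rng = np.random.default_rng()
    slack = T - K * min_len
    if slack < 0:
        raise ValueError(f"infeasible: {K} segments of >= {min_len} cannot sum to {T}")
    if K == 1:
        return np.array([T], dtype=int)
    bars = np.sort(rng.choice(slack + K - 1, size=K - 1, replace=False))
    padded = np.concatenate([[-1], bars, [slack + K - 1]])
    parts = np.diff(padded) - 1
    return (parts + min_len).astype(int)


def boundaries_from_lengths(lengths) -> np.ndarray:
    """Boundary indices (first timepoint of each new event) from segment lengths."""
    return np.cumsum(np.asarray(lengths, dtype=int))[:-1]


def simulate_timecourse(
    patterns: np.ndarray,
    lengths,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """V x T matrix: each timepoint's column is its event's pattern plus iid noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    patterns = np.asarray(patterns, dtype=float)
    lengths = np.asarray(lengths, dtype=int)
    if patterns.shape[0] != lengths.shape[0]:
        raise ValueError("number of patterns must equal number of segments")
    labels = np.repeat(np.arange(lengths.shape[0]), lengths)
    signal = patterns[labels].T  # (V, T)
    if noise_sd == 0:
        return signal.copy()
    return signal + noise_sd * rng.standard_normal(signal.shape)


def _zscore_temporal(x: np.ndarray) -> np.ndarray:
    """z-score each voxel's timecourse across time (the real-data preprocessing)."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError(
            "zero-variance voxel timecourse; increase noise_sd or event contrast"
        )
    return (x - mu) / sd


def _jitter_boundaries(
    lengths: np.ndarray, jitter_sd: float, T: int, min_len: int, rng
) -> np.ndarray:
    b = boundaries_from_lengths(lengths).astype(float)
    b += np.round(rng.normal(0.0, jitter_sd, size=b.shape))
    b = np.clip(np.sort(b), 1, T - 1).astype(int)
    # enforce at least one timepoint per event
    for i in range(1, b.size):
        b[i] = max(b[i], b[i - 1] + 1)
    b = b[b < T]
    edges = np.concatenate([[0], b, [T]])
    return np.diff(edges).astype(int)


def simulate_cohort(config: SyntheticConfig):
    """Simulate a full cohort and its ground truth.

    Clip-level event patterns are drawn once per (clip, event count), each
    participant gets a perturbed copy (additive normal, scale
    ``participant_sd``), and every emitted matrix is z-scored per voxel
    across time.  Counterbalance groups are assigned round-robin.

    Returns
    -------
    (CohortDataset, SyntheticTruth)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    P, C, W = config.n_participants, config.n_clips, config.n_viewings
    V, T = config.n_voxels, config.n_timepoints
    Ks = config.event_counts_by_viewing()
    groups = np.arange(P) % config.n_groups

    if config.participant_effects is not None:
        effects = np.asarray(config.participant_effects, dtype=float)
        if effects.shape != (P,):
            raise ValueError("participant_effects must have one entry per participant")
    else:
        effects = rng.uniform(config.effect_low, config.effect_high, size=P)

    truth = SyntheticTruth(participant_effects=effects)
    data = np.empty((P, C, W, V, T))

    for c in range(C):
        clip_patterns: dict[int, np.ndarray] = {}
        for K in sorted(set(Ks)):
            clip_patterns[K] = make_event_patterns(K, V, rng)
            truth.event_patterns[(c, K)] = clip_patterns[K]
        # per-participant perturbed copies, stable across viewings
        sub_patterns = {
            K: pat[None] + config.participant_sd * rng.standard_normal((P,) + pat.shape)
            for K, pat in clip_patterns.items()
        }
        lengths_by_viewing = []
        lengths_by_k: dict[int, np.ndarray] = {}
        for v in range(W):
            if config.redraw_boundaries_per_viewing or Ks[v] not in lengths_by_k:
                lengths = draw_segment_lengths(Ks[v], T, config.min_segment_len, rng)
                if config.boundary_jitter_sd > 0:
                    lengths = _jitter_boundaries(
                        lengths, config.boundary_jitter_sd, T, config.min_segment_len, rng
                    )
                lengths_by_k[Ks[v]] = lengths
            lengths = lengths_by_k[Ks[v]]
            lengths_by_viewing.append(lengths)
            truth.boundaries[(c, v)] = boundaries_from_lengths(lengths)
        base_lengths, base_K = lengths_by_viewing[0], Ks[0]
        for p in range(P):
            base_signal = None
            for v in range(W):
                K_v, lengths = Ks[v], lengths_by_viewing[v]
                sig = simulate_timecourse(sub_patterns[K_v][p], lengths, 0.0, rng)
                if v > 0 and K_v != base_K:
                    if base_signal is None:
                        base_signal = simulate_timecourse(
                            sub_patterns[base_K][p], base_lengths, 0.0, rng
                        )
                    w = effects[p]
                    sig = (1.0 - w) * base_signal + w * sig
                if config.noise_sd > 0:
                    sig = sig + config.noise_sd * rng.standard_normal(sig.shape)
                data[p, c, v] = _zscore_temporal(sig)

    truth.recall_true = (
        config.recall_intercept + config.behavior_slope * effects
    )[:, None].repeat(C, axis=1)
    dataset = CohortDataset(data=data, groups=groups, config=config)
    return dataset, truth


def simulate_recall(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Recall table (participant x clip): intercept + slope * effect + noise, floored at 0."""
    if truth.participant_effects is None:
        raise ValueError("truth.participant_effects must be populated")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    effects = truth.participant_effects
    P, C = effects.shape[0], config.n_clips
    values = (
        config.recall_intercept
        + config.behavior_slope * effects[:, None]
        + config.behavior_noise_sd * rng.standard_normal((P, C))
    )
    values = np.maximum(values, 0.0)
    if config.round_recall:
        values = np.round(values)
    rows = [
        {
            "participant_id": f"sub-{p:02d}",
            "clip": c,
            "condition": CONDITIONS[c % len(CONDITIONS)],
            "recall": values[p, c],
        }
        for p in range(P)
        for c in range(C)
    ]
    return pd.DataFrame(rows)


def stable_config(**overrides) -> SyntheticConfig:
    """Convenience: a cohort with the same planted event count on every viewing."""
    return replace(SyntheticConfig(), **overrides)
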