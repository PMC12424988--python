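"""End-to-end orchestration: simulate -> segment -> WvB -> filter -> change ->
conjunction -> behavior, with manifest, logging and TSV/JSON outputs.

Each stage reads its inputs from and writes its outputs to a run directory,
so stages are independently runnable (and re-runnable) from the CLI.  Every
number in the final report is recomputable from the emitted intermediate
tables; the manifest records the configuration, derived seeds and the counts
at every filtering step.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import inference, synthetic_data
from .inference import (
    bh_fdr,
    change_statistic,
    classify_direction,
    conjunction,
    filter_reliable_searchlights,
    fit_null_normal,
    paired_recall_test,
    split_participants,
    upper_tail_p,
    viewing_shuffle_null,
    wvb_crossval_with_null,
    wvb_per_participant,
)
from .synthetic_data import CONDITIONS, CohortDataset, SyntheticConfig, simulate_cohort, simulate_recall

__all__ = ["RunConfig", "run_full_pipeline", "summarize_directions"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Defaults follow the reference design: event counts 2-10, lag 5 TRs,
    5 participant splits, up to 50 segment-shuffle permutations per event
    count, 50 viewing-shuffle null datasets, BH-FDR at q = 0.05, per-clip
    conjunction alpha 0.05^(1/3), and 10,000 bootstrap iterations for the
    brain-behavior regression.
    """

    mode: str = "synthetic"
    event_counts: tuple = tuple(range(2, 11))
    lag: int = 5
    n_splits: int = 5
    max_perm: int = 50
    n_null_datasets: int = 50
    fdr_q: float = 0.05
    conjunction_alpha: float = 0.05 ** (1.0 / 3.0)
    n_boot: int = 10000
    seed: int = 0
    # synthetic-mode layout: how many simulated regions, and how many of them
    # carry a planted timescale change (the rest keep stable_event_count).
    n_searchlights: int = 6
    n_change: int = 3
    change_event_counts: dict | None = None
    stable_event_count: int = 4
    synthetic: dict = field(default_factory=dict)
    nifti: dict = field(default_factory=dict)

    def __post_init__(self):
        self.event_counts = tuple(int(k) for k in self.event_counts)
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if any(k < 2 for k in self.event_counts):
            raise ValueError("event counts must be >= 2")

    @property
    def slow_k(self) -> int:
        return min(self.event_counts)

    @property
    def fast_k(self) -> int:
        return max(self.event_counts)

    def change_map(self, n_viewings: int) -> dict:
        m = self.change_event_counts or {"first": self.fast_k, "rest": self.slow_k}
        if "first" in m or "rest" in m:
            return {
                v: int(m["first"] if v == 1 else m["rest"])
                for v in range(1, n_viewings + 1)
            }
        return {int(v): int(k) for v, k in m.items()}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["event_counts"] = list(self.event_counts)
        return d


# ---------------------------------------------------------------------------
# manifest helpers


def _manifest_path(run_dir) -> Path:
    return Path(run_dir) / "manifest.json"


def _update_manifest(run_dir, stage: str, info: dict) -> None:
    path = _manifest_path(run_dir)
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": {}}
    manifest["stages"][stage] = info
    path.write_text(json.dumps(manifest, indent=2, default=str))


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the run seed."""
    offsets = {"simulate": 1, "wvb": 2, "change": 3, "behavior": 4, "reliability": 5}
    return int((cfg.seed * 1000003 + offsets[stage] * 7919) % (2**31 - 1))


# ---------------------------------------------------------------------------
# synthetic inputs


def stage_simulate(cfg: RunConfig, run_dir) -> None:
    """Simulate per-searchlight cohorts sharing one participant-effect vector."""
    t0 = time.perf_counter()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    base = dict(cfg.synthetic)
    base.setdefault("seed", cfg.seed)
    probe = SyntheticConfig(**base)
    rng = np.random.default_rng(_stage_seed(cfg, "simulate"))
    effects = rng.uniform(probe.effect_low, probe.effect_high, probe.n_participants)
    sl_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_searchlights)
    change_map = cfg.change_map(probe.n_viewings)

    h5path = run_dir / "cohort.h5"
    if h5path.exists():
        h5path.unlink()
    planted = []
    recall = None
    for s in range(cfg.n_searchlights):
        kw = dict(base)
        kw["seed"] = int(sl_seeds[s])
        kw["participant_effects"] = effects
        if s < cfg.n_change:
            kw["true_event_counts"] = change_map
        else:
            kw["true_event_counts"] = cfg.stable_event_count
        scfg = SyntheticConfig(**kw)
        dataset, truth = simulate_cohort(scfg)
        dataset.to_hdf5(h5path, key=f"sl_{s:03d}")
        planted.append(
            {
                "searchlight_id": s,
                "planted_change": s < cfg.n_change,
                "event_counts": scfg.event_counts_by_viewing(),
            }
        )
        if recall is None:
            recall = simulate_recall(truth, scfg, rng)
            dataset.metadata.to_csv(run_dir / "metadata.tsv", sep="\t", index=False)
    recall.to_csv(run_dir / "recall.tsv", sep="\t", index=False)
    (run_dir / "truth.json").write_text(
        json.dumps(
            {"planted": planted, "participant_effects": effects.tolist()}, indent=2
        )
    )
    _update_manifest(
        run_dir,
        "simulate",
        {
            "n_searchlights": cfg.n_searchlights,
            "n_change": cfg.n_change,
            "seed": _stage_seed(cfg, "simulate"),
            "seconds": round(time.perf_counter() - t0, 2),
        },
    )


def load_cohorts(run_dir) -> dict:
    """searchlight id -> CohortDataset from a run directory's cohort.h5."""
    run_dir = Path(run_dir)
    out = {}
    with h5py.File(run_dir / "cohort.h5", "r") as f:
        keys = sorted(f.keys())
    for key in keys:
        sl = int(key.split("_")[1])
        out[sl] = CohortDataset.from_hdf5(run_dir / "cohort.h5", key=key)
    return out


def _load_nifti_cohorts(cfg: RunConfig, run_dir) -> dict:
    """Real-data mode: per-searchlight stacks from 4-D NIfTI volumes.

    Expects cfg.nifti with `data_table` (TSV: participant_id, clip, condition,
    viewing, group, path), `mask` (NIfTI path) and optional searchlight
    geometry parameters.  Returns {searchlight_id: (n_sub, n_clips,
    n_viewings, V, T) object-free arrays} plus writes searchlights.json.
    """
    from .searchlight_volume import (
        extract_searchlight_data,
        generate_searchlights,
        load_nifti,
    )

    run_dir = Path(run_dir)
    meta = pd.read_csv(cfg.nifti["data_table"], sep="\t")
    mask, _ = load_nifti(cfg.nifti["mask"])
    sls = generate_searchlights(
        mask > 0,
        radius=cfg.nifti.get("radius", 5.0),
        stride=cfg.nifti.get("stride", 5),
        min_voxels=cfg.nifti.get("min_voxels", 20),
    )
    (run_dir / "searchlights.json").write_text(sls.to_json())
    participants = sorted(meta["participant_id"].unique())
    clips = sorted(meta["clip"].unique())
    viewings = sorted(meta["viewing"].unique())
    groups = np.array(
        [
            int(meta.loc[meta["participant_id"] == p, "group"].iloc[0])
            for p in participants
        ]
    )
    stacks: dict[int, list] = {i: None for i in range(len(sls))}
    for pi, p in enumerate(participants):
        for ci, c in enumerate(clips):
            for vi, v in enumerate(viewings):
                row = meta[
                    (meta["participant_id"] == p)
                    & (meta["clip"] == c)
                    & (meta["viewing"] == v)
                ]
                vol, _ = load_nifti(row["path"].iloc[0])
                for si, mat in enumerate(extract_searchlight_data(vol, sls)):
                    if stacks[si] is None:
                        stacks[si] = np.empty(
                            (len(participants), len(clips), len(viewings)) + mat.shape
                        )
                    stacks[si][pi, ci, vi] = mat
    return {
        si: CohortDataset(
            data=stacks[si],
            groups=groups,
            config=SyntheticConfig(
                n_participants=len(participants),
                n_groups=int(groups.max()) + 1,
                n_clips=len(clips),
                n_viewings=len(viewings),
                n_voxels=stacks[si].shape[3],
                n_timepoints=stacks[si].shape[4],
            ),
        )
        for si in stacks
    }


def _get_cohorts(cfg: RunConfig, run_dir) -> dict:
    if cfg.mode == "synthetic":
        return load_cohorts(run_dir)
    if cfg.mode == "nifti":
        return _load_nifti_cohorts(cfg, run_dir)
    raise ValueError(f"unknown mode {cfg.mode!r}")


# ---------------------------------------------------------------------------
# WvB + null + filter


def stage_wvb(cfg: RunConfig, run_dir) -> pd.DataFrame:
    """Cross-validated WvB values, pooled permutation nulls and one-tailed p."""
    t0 = time.perf_counter()
    run_dir = Path(run_dir)
    cohorts = _get_cohorts(cfg, run_dir)
    rng = np.random.default_rng(_stage_seed(cfg, "wvb"))
    rows = []
    n_undefined_nulls = 0
    for sl in sorted(cohorts):
        ds = cohorts[sl]
        n = ds.data.shape[0]
        splits = split_participants(np.arange(n), ds.groups, cfg.n_splits, rng)
        for clip in range(ds.data.shape[1]):
            for v in range(ds.data.shape[2]):
                values, nulls, counts = wvb_crossval_with_null(
                    ds.data[:, clip, v],
                    ds.groups,
                    splits,
                    cfg.event_counts,
                    cfg.lag,
                    max_perm=cfg.max_perm,
                    rng=rng,
                    collect_counts=True,
                )
                try:
                    null = fit_null_normal(nulls, scope=(sl, clip, v))
                except ValueError:
                    null = None
                    n_undefined_nulls += 1
                for K in cfg.event_counts:
                    p = (
                        upper_tail_p(values[K], null)
                        if null is not None and np.isfinite(values[K])
                        else np.nan
                    )
                    rows.append(
                        {
                            "searchlight_id": sl,
                            "clip": clip,
                            "viewing": v + 1,
                            "K": K,
                            "value": values[K],
                            "n_within": counts[K][0],
                            "n_between": counts[K][1],
                            "p": p,
                            "null_mu": null.mu if null else np.nan,
                            "null_sigma": null.sigma if null else np.nan,
                            "n_null": null.n_values if null else 0,
                        }
                    )
    table = pd.DataFrame(rows)
    table.to_csv(run_dir / "wvb.tsv", sep="\t", index=False)
    _update_manifest(
        run_dir,
        "wvb",
        {
            "rows": len(table),
            "searchlights": len(cohorts),
            "degenerate_nulls": n_undefined_nulls,
            "seed": _stage_seed(cfg, "wvb"),
            "seconds": round(time.perf_counter() - t0, 2),
        },
    )
    return table


def stage_filter(cfg: RunConfig, run_dir) -> dict:
    """Keep searchlights with reliable event structure on every viewing."""
    t0 = time.perf_counter()
    run_dir = Path(run_dir)
    table = pd.read_csv(run_dir / "wvb.tsv", sep="\t")
    n_viewings = int(table["viewing"].max())
    retained = filter_reliable_searchlights(table, alpha=0.05, n_viewings=n_viewings)
    retained = {int(c): [int(s) for s in v] for c, v in retained.items()}
    (run_dir / "reliable.json").write_text(json.dumps(retained, indent=2))
    _update_manifest(
        run_dir,
        "filter",
        {
            "retained_per_clip": {c: len(v) for c, v in retained.items()},
            "total_searchlights": int(table["searchlight_id"].nunique()),
            "seconds": round(time.perf_counter() - t0, 2),
        },
    )
    return retained


# ---------------------------------------------------------------------------
# change + conjunction


def _make_change_stat(cfg: RunConfig, groups, splits):
    Ks = (cfg.slow_k, cfg.fast_k)

    def stat(clip_data):  # (n_sub, n_viewings, V, T) -> (delta_slow, delta_fast)
        per_view = []
        for v in range(clip_data.shape[1]):
            values, _ = wvb_crossval_with_null(
                clip_data[:, v], groups, splits, Ks, cfg.lag, max_perm=0, rng=None
            )
            per_view.append(values)
        return np.asarray(
            [change_statistic([pv[K] for pv in per_view]) for K in Ks]
        )

    return stat


def stage_change(cfg: RunConfig, run_dir) -> pd.DataFrame:
    """Delta (viewings 2-6 minus viewing 1) at the slow and fast timescales,
    viewing-shuffle p-values, BH-FDR q-values and direction labels."""
    t0 = time.perf_counter()
    run_dir = Path(run_dir)
    if cfg.n_null_datasets == 0:
        log.warning("change stage skipped: n_null_datasets = 0")
        _update_manifest(run_dir, "change", {"skipped": "n_null_datasets = 0"})
        return pd.DataFrame()
    cohorts = _get_cohorts(cfg, run_dir)
    retained = json.loads((run_dir / "reliable.json").read_text())
    rng = np.random.default_rng(_stage_seed(cfg, "change"))
    rows = []
    for clip_str, sls in sorted(retained.items()):
        clip = int(clip_str)
        for sl in sls:
            ds = cohorts[sl]
            n = ds.data.shape[0]
            splits = split_participants(np.arange(n), ds.groups, cfg.n_splits, rng)
            stat = _make_change_stat(cfg, ds.groups, splits)
            res = viewing_shuffle_null(
                ds.data[:, clip], stat, n_null=cfg.n_null_datasets, rng=rng
            )
            rows.append(
                {
                    "searchlight_id": sl,
                    "clip": clip,
                    "delta_slow": res.real[0],
                    "delta_fast": res.real[1],
                    "p_slow": res.p[0],
                    "p_fast": res.p[1],
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        for ts in ("slow", "fast"):
            table[f"q_{ts}"] = np.nan
        for clip, idx in table.groupby("clip").groups.items():
            for ts in ("slow", "fast"):
                p = table.loc[idx, f"p_{ts}"].to_numpy()
                ok = np.isfinite(p)
                if ok.any():
                    qv, _ = bh_fdr(p[ok], q=cfg.fdr_q)
                    table.loc[np.asarray(idx)[ok], f"q_{ts}"] = qv
        table["direction"] = [
            classify_direction(
                r.delta_slow,
                r.delta_fast,
                bool(r.q_slow < cfg.fdr_q),
                bool(r.q_fast < cfg.fdr_q),
            )
            for r in table.itertuples()
        ]
    table.to_csv(run_dir / "change.tsv", sep="\t", index=False)
    _update_manifest(
        run_dir,
        "change",
        {
            "rows": len(table),
            "n_null_datasets": cfg.n_null_datasets,
            "seed": _stage_seed(cfg, "change"),
            "seconds": round(time.perf_counter() - t0, 2),
        },
    )
    return table


def summarize_directions(change_table: pd.DataFrame, fdr_q: float = 0.05) -> pd.DataFrame:
    """Per clip: how many searchlights changed significantly, and which way.

    A searchlight counts as significant if either timescale survives FDR;
    proportions are NaN when nothing is significant.
    """
    rows = []
    for clip, t in change_table.groupby("clip"):
        sig = t[(t["q_slow"] < fdr_q) | (t["q_fast"] < fdr_q)]
        n_sig = len(sig)
        n_coarser = int((sig["direction"] == "coarser").sum())
        n_finer = int((sig["direction"] == "finer").sum())
        rows.append(
            {
                "clip": clip,
                "n_significant": n_sig,
                "n_coarser": n_coarser,
                "n_finer": n_finer,
                "proportion_coarser": n_coarser / n_sig if n_sig else np.nan,
            }
        )
    return pd.DataFrame(rows)


def stage_conjunction(cfg: RunConfig, run_dir) -> pd.DataFrame:
    """Searchlights changing in the same direction, significantly, in every clip."""
    t0 = time.perf_counter()
    run_dir = Path(run_dir)
    change = pd.read_csv(run_dir / "change.tsv", sep="\t")
    if change.empty:
        out = pd.DataFrame(columns=["searchlight_id", "timescale", "direction"])
    else:
        tables = {int(c): t for c, t in change.groupby("clip")}
        out = conjunction(tables, alpha_per_clip=cfg.conjunction_alpha)
    out.to_csv(run_dir / "conjunction.tsv", sep="\t", index=False)
    _update_manifest(
        run_dir,
        "conjunction",
        {
            "flagged": len(out),
            "alpha_per_clip": cfg.conjunction_alpha,
            "seconds": round(time.perf_counter() - t0, 2),
        },
    )
    return out


# ---------------------------------------------------------------------------
# behavior


def stage_behavior(cfg: RunConfig, run_dir) -> pd.DataFrame:
    """Bootstrap regression of recall on per-participant change values, plus
    pairwise paired t-tests of recall across clip conditions."""
    t0 = time.perf_counter()
    run_dir = Path(run_dir)
    recall = pd.read_csv(run_dir / "recall.tsv", sep="\t")
    conj = pd.read_csv(run_dir / "conjunction.tsv", sep="\t")
    cohorts = _get_cohorts(cfg, run_dir)
    rng = np.random.default_rng(_stage_seed(cfg, "behavior"))

    # recall contrasts between clip conditions
    wide = recall.pivot(index="participant_id", columns="clip", values="recall")
    contrast_rows = []
    clips = sorted(wide.columns)
    for i, a in enumerate(clips):
        for b in clips[i + 1:]:
            res = paired_recall_test(wide[a].to_numpy(), wide[b].to_numpy())
            contrast_rows.append(
                {
                    "clip_a": CONDITIONS[a % len(CONDITIONS)],
                    "clip_b": CONDITIONS[b % len(CONDITIONS)],
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                }
            )
    pd.DataFrame(contrast_rows).to_csv(run_dir / "recall_tests.tsv", sep="\t", index=False)

    rows = []
    recall_mean = wide.mean(axis=1).to_numpy()
    for rec in conj.itertuples():
        sl = int(rec.searchlight_id)
        K = cfg.slow_k if rec.timescale == "slow" else cfg.fast_k
        ds = cohorts[sl]
        n, n_clips, n_view = ds.data.shape[:3]
        splits = split_participants(np.arange(n), ds.groups, cfg.n_splits, rng)
        deltas = np.zeros(n)
        for clip in range(n_clips):
            per_view = np.stack(
                [
                    wvb_per_participant(
                        ds.data[:, clip, v], ds.groups, splits, K, cfg.lag
                    )
                    for v in range(n_view)
                ]
            )  # (n_view, n)
            deltas += per_view[1:].mean(axis=0) - per_view[0]
        deltas /= n_clips
        slope, r, p = inference.brain_behavior(
            deltas, recall_mean, n_boot=cfg.n_boot, rng=rng
        )
        rows.append(
            {
                "searchlight_id": sl,
                "timescale": rec.timescale,
                "direction": rec.direction,
                "slope": slope,
                "r": r,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        qv, _ = bh_fdr(np.maximum(table["p"].to_numpy(), np.finfo(float).tiny), q=cfg.fdr_q)
        table["q"] = qv
    table.to_csv(run_dir / "behavior.tsv", sep="\t", index=False)
    _update_manifest(
        run_dir,
        "behavior",
        {
            "n_searchlights": len(table),
            "n_boot": cfg.n_boot,
            "seed": _stage_seed(cfg, "behavior"),
            "seconds": round(time.perf_counter() - t0, 2),
        },
    )
    return table


# ---------------------------------------------------------------------------
# full run


STAGES = ("simulate", "wvb", "filter", "change", "conjunction", "behavior")


def run_full_pipeline(cfg: RunConfig, out_dir) -> Path:
    """Run every stage in order; halts with a stage-named error, preserving
    partial outputs.  Deterministic given cfg.seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (_manifest_path(out_dir)).write_text(
        json.dumps({"config": RunConfig.to_dict(cfg), "stages": {}}, indent=2)
    )
    stage_fns = {
        "simulate": stage_simulate,
        "wvb": stage_wvb,
        "filter": stage_filter,
        "change": stage_change,
        "conjunction": stage_conjunction,
        "behavior": stage_behavior,
    }
    for name in STAGES:
        if name == "simulate" and cfg.mode != "synthetic":
            continue
        try:
            stage_fns[name](cfg, out_dir)
        except Exception as e:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
    change = pd.read_csv(out_dir / "change.tsv", sep="\t") if (out_dir / "change.tsv").exists() else pd.DataFrame()
    if len(change):
        summarize_directions(change, cfg.fdr_q).to_csv(
            out_dir / "direction_summary.tsv", sep="\t", index=False
        )
    return out_dir
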