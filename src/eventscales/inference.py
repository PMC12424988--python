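"""Cross-validated WvB estimation, permutation nulls, and group statistics.

Implements the statistical machinery around the event HMM:

* split-half cross-validation of the within- vs. between-event similarity
  (boundaries fit on one half's group-average timecourse, scored on the
  held-out half's group average, both directions averaged over several
  stratified participant splits),
* a segment-shuffle null (reorder fitted event durations, score the induced
  boundaries on the test data) pooled across event counts into one fitted
  normal per searchlight/clip/viewing,
* the reliable-searchlight filter,
* the change statistic Delta = mean(viewings 2-6) - viewing 1 with a
  viewing-shuffle permutation null and Benjamini-Hochberg FDR,
* the cross-clip conjunction, split-cohort reliability, bootstrap
  brain-behavior regression, and paired recall t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from .event_hmm import fit_event_hmm
from .similarity import timepoint_corr_matrix, wvb_similarity

__all__ = [
    "NullDistribution",
    "ChangeResult",
    "ShuffleTestResult",
    "split_participants",
    "wvb_crossval",
    "wvb_crossval_with_null",
    "wvb_per_participant",
    "segment_shuffle_null",
    "count_distinct_orderings",
    "fit_null_normal",
    "upper_tail_p",
    "filter_reliable_searchlights",
    "change_statistic",
    "viewing_shuffle_null",
    "bh_fdr",
    "conjunction",
    "split_cohort_reliability",
    "brain_behavior",
    "paired_recall_test",
]

log = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Normal fitted to pooled permutation values (one per searchlight/clip/viewing)."""

    mu: float
    sigma: float
    n_values: int
    scope: tuple = ()


@dataclass
class ChangeResult:
    """Change in event-structure strength, repeated viewings minus first."""

    delta_slow: float
    delta_fast: float
    p_slow: float
    p_fast: float
    q_slow: float = np.nan
    q_fast: float = np.nan
    direction: str = "none"


@dataclass
class ShuffleTestResult:
    """Observed statistic vs. a permutation null summarized by a fitted normal."""

    real: np.ndarray
    null_values: np.ndarray  # (n_null, ...) same trailing shape as real
    mu: np.ndarray
    sigma: np.ndarray
    p: np.ndarray
    degenerate: np.ndarray


# ---------------------------------------------------------------------------
# participant splits and cross-validated WvB


def split_participants(ids, group_labels, n_splits: int, rng: np.random.Generator):
    """Random half-splits of participants, stratified within counterbalance group.

    Returns a list of ``n_splits`` pairs (half_a, half_b) of index arrays;
    both train->test directions of each pair are used downstream.
    """
    ids = np.asarray(ids)
    group_labels = np.asarray(group_labels)
    splits = []
    for g in np.unique(group_labels):
        if (group_labels == g).sum() < 2:
            raise ValueError(f"counterbalance group {g} has fewer than 2 participants")
    for _ in range(n_splits):
        half_a, half_b = [], []
        for g in np.unique(group_labels):
            members = ids[group_labels == g]
            perm = rng.permutation(members)
            half = members.size // 2
            half_a.append(perm[:half])
            half_b.append(perm[half:])
        splits.append((np.concatenate(half_a), np.concatenate(half_b)))
    return splits


def _half_pairs(split, group_labels):
    """Within-group (train, test) index pairs for both directions of one split."""
    a, b = split
    group_labels = np.asarray(group_labels)
    for g in np.unique(group_labels):
        ag = a[group_labels[a] == g]
        bg = b[group_labels[b] == g]
        if ag.size == 0 or bg.size == 0:
            raise ValueError(f"empty half for counterbalance group {g}")
        yield ag, bg
        yield bg, ag


def wvb_crossval(
    data: np.ndarray,
    group_labels,
    splits,
    K: int,
    lag: int = 5,
    hmm_kwargs: dict | None = None,
) -> float:
    """Cross-validated WvB value for one searchlight/clip/viewing.

    ``data`` is (n_participants, V, T).  Per split and direction the HMM is
    fit on the train half's group-average timecourse and its boundaries are
    scored on the held-out half's group average; values are averaged over
    directions, counterbalance groups and splits.  NaN if undefined in every
    piece.
    """
    values, _ = wvb_crossval_with_null(
        data, group_labels, splits, [K], lag, max_perm=0, rng=None, hmm_kwargs=hmm_kwargs
    )
    return values[K]


def wvb_crossval_with_null(
    data: np.ndarray,
    group_labels,
    splits,
    Ks,
    lag: int = 5,
    max_perm: int = 50,
    rng: np.random.Generator | None = None,
    hmm_kwargs: dict | None = None,
    collect_counts: bool = False,
):
    """Cross-validated WvB values for several event counts plus pooled null values.

    For every train/test piece and event count the fitted segment lengths are
    reshuffled (segment-shuffle null) and scored on the same test matrix;
    null values from all event counts are pooled, matching the single
    per-searchlight/clip/viewing null-distribution design.

    Returns
    -------
    values : dict K -> cross-validated value (NaN when undefined everywhere)
    nulls : 1-D array of pooled null WvB values
    counts (optional) : dict K -> (mean n_within, mean n_between)
    """
    data = np.asarray(data, dtype=float)
    hmm_kwargs = hmm_kwargs or {}
    per_k: dict[int, list[float]] = {K: [] for K in Ks}
    counts: dict[int, list] = {K: [] for K in Ks}
    nulls: list[float] = []
    n_undefined = 0
    for split in splits:
        for train, test in _half_pairs(split, group_labels):
            train_mean = data[train].mean(axis=0)
            test_mean = data[test].mean(axis=0)
            corr = timepoint_corr_matrix(test_mean)
            for K in Ks:
                seg = fit_event_hmm(train_mean, K, **hmm_kwargs)
                res = wvb_similarity(corr, seg.boundaries, lag, K=K)
                per_k[K].append(res.value if res.defined else np.nan)
                counts[K].append((res.n_within, res.n_between))
                if not res.defined:
                    n_undefined += 1
                if max_perm > 0:
                    nulls.extend(
                        segment_shuffle_null(
                            seg.segment_lengths(), corr, lag, max_perm, rng
                        )
                    )
    if n_undefined:
        log.debug("wvb_crossval: %d undefined WvB pieces excluded", n_undefined)
    values = {}
    for K in Ks:
        vals = np.asarray(per_k[K], dtype=float)
        values[K] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan
    out_nulls = np.asarray([v for v in nulls if np.isfinite(v)], dtype=float)
    if collect_counts:
        mean_counts = {
            K: tuple(np.mean(np.asarray(counts[K]), axis=0)) for K in Ks
        }
        return values, out_nulls, mean_counts
    return values, out_nulls


def wvb_per_participant(
    data: np.ndarray,
    group_labels,
    splits,
    K: int,
    lag: int = 5,
    hmm_kwargs: dict | None = None,
) -> np.ndarray:
    """Individual-level WvB: HMM trained on the group mean of one half, tested
    on each held-out participant's own timecourse.

    Each participant's value is averaged over every split in which they were
    in the test half.  Returns an array of length n_participants (NaN where
    never defined).
    """
    data = np.asarray(data, dtype=float)
    hmm_kwargs = hmm_kwargs or {}
    n = data.shape[0]
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for split in splits:
        for train, test in _half_pairs(split, group_labels):
            seg = fit_event_hmm(data[train].mean(axis=0), K, **hmm_kwargs)
            for p in test:
                res = wvb_similarity(
                    timepoint_corr_matrix(data[p]), seg.boundaries, lag, K=K
                )
                if res.defined:
                    acc[p] += res.value
                    cnt[p] += 1
    out = np.full(n, np.nan)
    mask = cnt > 0
    out[mask] = acc[mask] / cnt[mask]
    return out


# ---------------------------------------------------------------------------
# segment-shuffle null


def _distinct_permutations(items):
    """Yield distinct permutations of a multiset without materializing K!."""
    items = sorted(items)
    n = len(items)
    perm = []
    counts = {}
    for x in items:
        counts[x] = counts.get(x, 0) + 1
    keys = sorted(counts)

    def rec():
        if len(perm) == n:
            yield tuple(perm)
            return
        for k in keys:
            if counts[k] > 0:
                counts[k] -= 1
                perm.append(k)
                yield from rec()
                perm.pop()
                counts[k] += 1

    yield from rec()


def count_distinct_orderings(lengths) -> int:
    """Number of distinct orderings of the segment-length multiset."""
    lengths = list(lengths)
    n = factorial(len(lengths))
    for L in set(lengths):
        n //= factorial(lengths.count(L))
    return n


def segment_shuffle_null(
    lengths,
    test_corr: np.ndarray,
    lag: int,
    max_perm: int = 50,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null WvB values from reordered event segment lengths.

    Orderings are deduplicated on the boundary vector they induce and the
    real ordering's boundary vector is excluded, so the shuffled event
    sequence never matches the real one.  If the number of distinct null
    orderings is at most ``max_perm`` they are all enumerated, otherwise
    ``max_perm`` distinct ones are sampled.  Returns the (possibly empty)
    array of defined null values; an empty array signals that every ordering
    collapses onto the real boundaries (all segments equal length).
    """
    lengths = np.asarray(lengths, dtype=int)
    K = lengths.shape[0]
    if K < 2:
        raise ValueError("need at least 2 segments to shuffle")
    real = tuple(np.cumsum(lengths)[:-1])
    n_distinct = count_distinct_orderings(lengths)
    if n_distinct - 1 <= max_perm:
        candidates = {
            tuple(np.cumsum(p)[:-1]) for p in _distinct_permutations(lengths)
        }
        candidates.discard(real)
        boundary_vectors = sorted(candidates)
    else:
        if rng is None:
            rng = np.random.default_rng()
        seen: set = set()
        tries = 0
        while len(seen) < max_perm and tries < 100 * max_perm:
            b = tuple(np.cumsum(rng.permutation(lengths))[:-1])
            if b != real:
                seen.add(b)
            tries += 1
        boundary_vectors = sorted(seen)
    values = []
    for b in boundary_vectors:
        res = wvb_similarity(test_corr, np.asarray(b), lag)
        if res.defined:
            values.append(res.value)
    if not boundary_vectors:
        log.debug("segment_shuffle_null: no valid null orderings (equal lengths)")
    return np.asarray(values, dtype=float)


def fit_null_normal(values, scope: tuple = ()) -> NullDistribution:
    """Normal fit (sample mean, n-1 sd) to pooled permutation values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 null values to fit a normal")
    sigma = float(v.std(ddof=1))
    if sigma == 0:
        raise ValueError("null values have zero spread")
    return NullDistribution(mu=float(v.mean()), sigma=sigma, n_values=int(v.size), scope=scope)


def upper_tail_p(value: float, null: NullDistribution) -> float:
    """One-tailed p: area of the fitted normal above the observed value."""
    return float(stats.norm.sf((value - null.mu) / null.sigma))


# ---------------------------------------------------------------------------
# filtering and change statistics


def filter_reliable_searchlights(
    table: pd.DataFrame,
    alpha: float = 0.05,
    n_viewings: int = 6,
) -> dict:
    """Searchlights with reliable event structure on every viewing of a clip.

    ``table`` is long-format with columns searchlight_id, clip, viewing, K,
    value, p.  A searchlight is retained for a clip iff for *every* viewing
    there exists at least one event count with value > 0 and one-tailed
    p < alpha.  Searchlights missing a viewing are dropped with a logged
    reason.
    """
    retained: dict = {}
    for clip, tclip in table.groupby("clip"):
        keep = []
        for sl, tsl in tclip.groupby("searchlight_id"):
            viewings = tsl["viewing"].unique()
            if viewings.size < n_viewings:
                log.info(
                    "searchlight %s clip %s dropped: only %d/%d viewings present",
                    sl, clip, viewings.size, n_viewings,
                )
                continue
            ok = all(
                bool(((tv["value"] > 0) & (tv["p"] < alpha)).any())
                for _, tv in tsl.groupby("viewing")
            )
            if ok:
                keep.append(sl)
        retained[clip] = sorted(keep)
    return retained


def change_statistic(values_by_viewing) -> float:
    """Delta = mean(viewings 2..n) - viewing 1; NaN if any viewing is missing."""
    v = np.asarray(values_by_viewing, dtype=float)
    if v.size < 2 or not np.all(np.isfinite(v)):
        return np.nan
    return float(v[1:].mean() - v[0])


def viewing_shuffle_null(
    data: np.ndarray,
    stat_fn,
    n_null: int = 50,
    rng: np.random.Generator | None = None,
) -> ShuffleTestResult:
    """Permutation null for viewing-order effects.

    ``data`` is (n_participants, n_viewings, V, T).  Each null dataset
    independently permutes the viewing order per participant; ``stat_fn``
    (scalar- or vector-valued) is re-run on each.  The two-tailed p-value
    comes from a normal fitted to the null statistics:
    p = 2 * min(Phi(z), 1 - Phi(z)) with z = (real - mu) / sigma.
    """
    if rng is None:
        rng = np.random.default_rng()
    data = np.asarray(data, dtype=float)
    n_sub, n_view = data.shape[:2]
    real = np.atleast_1d(np.asarray(stat_fn(data), dtype=float))
    nulls = np.empty((n_null,) + real.shape)
    for i in range(n_null):
        perm = np.stack([data[s][rng.permutation(n_view)] for s in range(n_sub)])
        nulls[i] = np.atleast_1d(np.asarray(stat_fn(perm), dtype=float))
    mu = nulls.mean(axis=0)
    sigma = nulls.std(axis=0, ddof=1)
    degenerate = ~(sigma > 1e-12 * np.maximum(1.0, np.abs(mu)))
    if degenerate.any():
        log.warning("viewing_shuffle_null: degenerate null spread flagged")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (real - mu) / sigma
    p = 2.0 * np.minimum(stats.norm.cdf(z), stats.norm.sf(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[degenerate] = np.nan
    return ShuffleTestResult(
        real=real, null_values=nulls, mu=mu, sigma=sigma, p=p, degenerate=degenerate
    )


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR.

    Returns (q_values, reject): BH-adjusted p-values and the step-up
    rejection mask at level ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, q_values, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_values, reject


def classify_direction(
    delta_slow: float,
    delta_fast: float,
    sig_slow: bool,
    sig_fast: bool,
) -> str:
    """finer / coarser / mixed / none from significant slow- and fast-timescale changes.

    Gaining slow structure or losing fast structure = coarser; losing slow or
    gaining fast = finer; evidence in both directions = mixed.
    """
    coarser = (sig_slow and delta_slow > 0) or (sig_fast and delta_fast < 0)
    finer = (sig_slow and delta_slow < 0) or (sig_fast and delta_fast > 0)
    if coarser and finer:
        return "mixed"
    if coarser:
        return "coarser"
    if finer:
        return "finer"
    return "none"


def conjunction(
    change_tables: dict,
    alpha_per_clip: float = 0.05 ** (1.0 / 3.0),
    timescales=("slow", "fast"),
) -> pd.DataFrame:
    """Searchlights changing consistently (same sign, significant) in every clip.

    ``change_tables`` maps clip -> DataFrame with columns searchlight_id,
    delta_slow, delta_fast, p_slow, p_fast, restricted per clip to its
    reliable searchlights.  Per clip and timescale a BH correction at
    ``alpha_per_clip`` (default the cube root of 0.05, so the 3-clip
    conjunction is controlled at q < 0.05) defines significance on the
    intersection of retained searchlights; a searchlight is flagged iff it is
    significant in all clips with an identical sign of the change.  Returns a
    DataFrame with searchlight_id, timescale, direction (gain/loss).
    """
    clips = sorted(change_tables)
    if len(clips) < 2:
        raise ValueError("conjunction requires at least 2 clips")
    common = set(change_tables[clips[0]]["searchlight_id"])
    for c in clips[1:]:
        common &= set(change_tables[c]["searchlight_id"])
    common = sorted(common)
    rows = []
    if not common:
        return pd.DataFrame(columns=["searchlight_id", "timescale", "direction"])
    sig = {}
    delta = {}
    for c in clips:
        t = (
            change_tables[c]
            .set_index("searchlight_id")
            .loc[common]
        )
        for ts in timescales:
            p = t[f"p_{ts}"].to_numpy(dtype=float)
            finite = np.isfinite(p)
            rej = np.zeros(p.shape, dtype=bool)
            if finite.any():
                # undefined tests (degenerate nulls) drop out of the family
                _, rej[finite] = bh_fdr(p[finite], q=alpha_per_clip)
            sig[(c, ts)] = dict(zip(common, rej))
            delta[(c, ts)] = dict(zip(common, t[f"delta_{ts}"].to_numpy()))
    for ts in timescales:
        for sl in common:
            if not all(sig[(c, ts)][sl] for c in clips):
                continue
            signs = {np.sign(delta[(c, ts)][sl]) for c in clips}
            if len(signs) != 1 or 0 in signs:
                continue
            rows.append(
                {
                    "searchlight_id": sl,
                    "timescale": ts,
                    "direction": "gain" if signs.pop() > 0 else "loss",
                }
            )
    return pd.DataFrame(rows, columns=["searchlight_id", "timescale", "direction"])


# ---------------------------------------------------------------------------
# reliability, behavior, recall


def split_cohort_reliability(
    data_by_searchlight: dict,
    group_labels,
    Ks,
    lag: int = 5,
    n_splits: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Between-cohort reliability of the cross-validated WvB values.

    Participants are split into two disjoint cohorts (stratified by
    counterbalance group); the full cross-validated WvB procedure runs
    independently in each; the per-viewing Pearson correlation of the two
    value vectors (across searchlights x event counts) is returned.

    ``data_by_searchlight`` maps searchlight id -> (n_participants,
    n_viewings, V, T) arrays for one clip.
    """
    if rng is None:
        rng = np.random.default_rng()
    group_labels = np.asarray(group_labels)
    n = group_labels.shape[0]
    if n < 8:
        raise ValueError("split-cohort reliability needs at least 8 participants")
    ids = np.arange(n)
    (cohort_a, cohort_b) = split_participants(ids, group_labels, 1, rng)[0]
    any_sl = next(iter(data_by_searchlight.values()))
    n_view = any_sl.shape[1]
    vectors = {0: [], 1: []}
    for i, cohort in enumerate((cohort_a, cohort_b)):
        sub_groups = group_labels[cohort]
        splits = split_participants(np.arange(cohort.size), sub_groups, n_splits, rng)
        per_view = [[] for _ in range(n_view)]
        for sl in sorted(data_by_searchlight):
            sl_data = np.asarray(data_by_searchlight[sl])[cohort]
            for v in range(n_view):
                values, _ = wvb_crossval_with_null(
                    sl_data[:, v], sub_groups, splits, Ks, lag, max_perm=0, rng=None
                )
                per_view[v].extend(values[K] for K in Ks)
        vectors[i] = np.asarray(per_view)  # (n_view, n_sl * n_K)
    r = np.empty(n_view)
    for v in range(n_view):
        a, b = vectors[0][v], vectors[1][v]
        mask = np.isfinite(a) & np.isfinite(b)
        r[v] = np.corrcoef(a[mask], b[mask])[0, 1] if mask.sum() > 2 else np.nan
    return r


def brain_behavior(
    delta: np.ndarray,
    recall: np.ndarray,
    n_boot: int = 10000,
    rng: np.random.Generator | None = None,
    robust: bool = False,
):
    """Bootstrap linear regression of recall on per-participant change values.

    Participants are resampled with replacement ``n_boot`` times and an OLS
    line is fit to each resample; the two-tailed p-value is
    2 * min(fraction of bootstrap slopes <= 0, >= 0).  With ``robust=True``
    the point estimate uses a Huber-loss line (statsmodels RLM) instead of
    OLS; the bootstrap remains the source of the p-value either way.

    Returns (slope, pearson_r, p).
    """
    x = np.asarray(delta, dtype=float)
    y = np.asarray(recall, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("delta and recall must be 1-D and paired")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 paired participants")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in regression variable")
    if rng is None:
        rng = np.random.default_rng()

    if robust:
        import statsmodels.api as sm

        fit = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.HuberT()).fit()
        slope = float(fit.params[1])
    else:
        slope = float(np.polyfit(x, y, 1)[0])
    r = float(np.corrcoef(x, y)[0, 1])

    idx = rng.integers(0, n, size=(n_boot, n))
    xs, ys = x[idx], y[idx]
    xm = xs.mean(axis=1, keepdims=True)
    ym = ys.mean(axis=1, keepdims=True)
    var = ((xs - xm) ** 2).sum(axis=1)
    cov = ((xs - xm) * (ys - ym)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = cov / var
    slopes = slopes[np.isfinite(slopes)]
    frac_le = np.mean(slopes <= 0)
    frac_ge = np.mean(slopes >= 0)
    p = float(min(1.0, 2.0 * min(frac_le, frac_ge)))
    return slope, r, p


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float


def paired_recall_test(a, b, confidence: float = 0.95) -> PairedTestResult:
    """Paired t-test on per-participant differences with a CI of the mean difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and the same length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diff = a - b
    if np.allclose(diff, diff[0]):
        if diff[0] == 0:
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, ci_low=0.0, ci_high=0.0)
        raise ValueError("degenerate paired data: constant nonzero difference")
    res = stats.ttest_rel(a, b)
    ci = res.confidence_interval(confidence)
    return PairedTestResult(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )
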