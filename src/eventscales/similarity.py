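"""Timepoint pattern correlations and within- vs. between-event similarity.

The within- vs. between-event (WvB) similarity statistic quantifies how well
a set of event boundaries captures stable spatial activity patterns: pairs of
timepoints separated by a fixed lag (5 TRs in the reference design, chosen to
step over BOLD autocorrelation) are classified as *within* one event or
*between* events, and the statistic is the mean spatial correlation of the
within pairs minus the mean for the between pairs.  Values therefore lie in
[-2, 2], with positive values indicating event structure at that timescale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WvBResult", "timepoint_corr_matrix", "wvb_similarity"]


@dataclass
class WvBResult:
    """Within-minus-between mean correlation at a fixed lag.

    ``value`` is NaN and ``defined`` False when either pair class is empty
    (e.g. every fitted event is shorter than the lag).
    """

    value: float
    n_within: int
    n_between: int
    lag: int
    K: int | None = None
    searchlight_id: int | None = None
    clip: int | None = None
    viewing: int | None = None
    defined: bool = field(default=True)


def timepoint_corr_matrix(data: np.ndarray) -> np.ndarray:
    """T x T Pearson correlation matrix of spatial patterns across voxels.

    Entry (i, j) is the correlation, over voxels, between the activity
    patterns at timepoints i and j; the diagonal is exactly 1.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("expected a voxel x time matrix with at least 2 voxels")
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance spatial pattern at timepoint(s) {bad.tolist()}")
    corr = np.corrcoef(X.T)
    np.fill_diagonal(corr, 1.0)
    return corr


def wvb_similarity(
    corr: np.ndarray,
    boundaries,
    lag: int = 5,
    K: int | None = None,
    **ids,
) -> WvBResult:
    """Within- vs. between-event similarity from a correlation matrix.

    Every pair (t, t + lag) with t in [0, T - lag) is classified as *within*
    iff no boundary b satisfies t < b <= t + lag (boundaries mark the first
    timepoint of a new event), else *between*; a pair spanning several
    boundaries is still simply *between*.

    Parameters
    ----------
    corr : (T, T) symmetric correlation matrix.
    boundaries : ordered boundary indices in (0, T).
    lag : pair offset in timepoints, >= 1 and < T.
    """
    C = np.asarray(corr, dtype=float)
    T = C.shape[0]
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if lag >= T:
        raise ValueError(f"lag={lag} must be smaller than T={T}")
    b = np.asarray(boundaries, dtype=int)
    if b.size and (np.any(np.diff(b) <= 0) or b.min() <= 0 or b.max() >= T):
        raise ValueError("boundaries must be strictly increasing and lie in (0, T)")

    t = np.arange(T - lag)
    pair_corr = C[t, t + lag]
    if b.size:
        spans = (b[None, :] > t[:, None]) & (b[None, :] <= (t + lag)[:, None])
        between = spans.any(axis=1)
    else:
        between = np.zeros(T - lag, dtype=bool)
    within = ~between

    n_within = int(within.sum())
    n_between = int(between.sum())
    if n_within == 0 or n_between == 0:
        return WvBResult(np.nan, n_within, n_between, lag, K=K, defined=False, **ids)
    value = float(pair_corr[within].mean() - pair_corr[between].mean())
    return WvBResult(value, n_within, n_between, lag, K=K, defined=True, **ids)
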