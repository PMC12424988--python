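"""Left-to-right hidden Markov model for neural event segmentation.

A brain region's response to a continuous stimulus is modeled as a sequence
of ``K`` discrete event states, each expressed as a distinct spatial activity
pattern.  States must be traversed in order (0, 1, ..., K-1) with no skips:
the only allowed transitions are "stay" and "advance by one".  The sequence
is constrained to start in state 0 at the first timepoint and to end in state
K-1 at the last, so every event occupies at least one timepoint.

Emissions are isotropic Gaussians over spatially z-scored activity patterns
(state-specific mean, one shared variance re-estimated each M-step), which
makes the emission distance equivalent to spatial pattern correlation.
Fitting is EM with an exact forward-backward E-step in log space, run from
two deterministic initializations (a uniform partition of time and a greedy
top-down least-squares split); the run with the higher final log-likelihood
wins.  Fits are therefore reproducible without seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EventSegmentation",
    "zscore_spatial",
    "fit_event_hmm",
    "extract_boundaries",
]

_VAR_FLOOR = 1e-6  # keeps the shared emission variance from collapsing on noise-free input


@dataclass
class EventSegmentation:
    """A fitted K-event labeling of a voxel x time matrix.

    ``labels`` are 0-based, non-decreasing, start at 0 and end at K-1.
    ``boundaries`` holds the K-1 timepoint indices at which a new event
    starts (the boundary index is the first timepoint of the new event).
    """

    K: int
    labels: np.ndarray
    boundaries: np.ndarray
    event_patterns: np.ndarray
    log_lik: float
    n_iter: int
    converged: bool

    def segment_lengths(self) -> np.ndarray:
        """Event durations in timepoints (length K, sums to T)."""
        T = self.labels.shape[0]
        return np.diff(np.concatenate([[0], self.boundaries, [T]])).astype(int)

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"timepoint": np.arange(self.labels.shape[0]), "label": self.labels}
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "K": int(self.K),
                "log_lik": float(self.log_lik),
                "boundaries": [int(b) for b in self.boundaries],
                "n_iter": int(self.n_iter),
                "converged": bool(self.converged),
            }
        )


def zscore_spatial(data: np.ndarray) -> np.ndarray:
    """Center and scale each timepoint's spatial pattern (columns) to mean 0, sd 1.

    The standard deviation uses denominator V (population convention), so the
    dot product of two z-scored columns divided by V equals their Pearson
    correlation in the original data.

    Parameters
    ----------
    data : (V, T) array
        Voxel x time matrix with V >= 2.

    Raises
    ------
    ValueError
        If V < 2 or any timepoint has zero spatial variance (the offending
        timepoints are named in the message).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D voxel x time matrix")
    if X.shape[0] < 2:
        raise ValueError("spatial z-scoring requires at least 2 voxels")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance spatial pattern at timepoint(s) {bad.tolist()}")
    return (X - mu) / sd


def extract_boundaries(labels: np.ndarray) -> np.ndarray:
    """Timepoints at which the event label changes (first timepoint of each new event)."""
    lab = np.asarray(labels)
    if lab.size and np.any(np.diff(lab) < 0):
        raise ValueError("labels must be non-decreasing over time")
    return np.flatnonzero(np.diff(lab) != 0) + 1


def _forward_backward_numpy(logB: np.ndarray, log_stay: float, log_adv: float):
    """Exact posteriors for the constrained left-to-right chain.

    Parameters
    ----------
    logB : (K, T) array of emission log densities.

    Returns
    -------
    log_gamma : (K, T) log posterior state probabilities.
    log_lik : float, total data log likelihood under the start/end constraints.
    """
    K, T = logB.shape
    stay = np.full(K, log_stay)
    stay[K - 1] = 0.0  # final state absorbs
    neg_inf = -np.inf

    alpha = np.full((T, K), neg_inf)
    alpha[0, 0] = logB[0, 0]
    move = np.empty(K)
    with np.errstate(invalid="ignore"):
        for t in range(1, T):
            prev = alpha[t - 1]
            move[0] = neg_inf
            move[1:] = prev[:-1] + log_adv
            alpha[t] = logB[:, t] + np.logaddexp(prev + stay, move)

        beta = np.full((T, K), neg_inf)
        beta[T - 1, K - 1] = 0.0
        for t in range(T - 2, -1, -1):
            nxt = beta[t + 1] + logB[:, t + 1]
            move[K - 1] = neg_inf
            move[:-1] = nxt[1:] + log_adv
            beta[t] = np.logaddexp(nxt + stay, move)

    log_lik = alpha[T - 1, K - 1]
    log_gamma = (alpha + beta - log_lik).T
    return log_gamma, float(log_lik)


try:  # compiled recursion; the numpy version above stays the reference
    from numba import njit

    @njit(cache=False)
    def _fb_kernel(logB, log_stay, log_adv):  # pragma: no cover - numba path
        K, T = logB.shape
        neg_inf = -np.inf
        alpha = np.full((T, K), neg_inf)
        alpha[0, 0] = logB[0, 0]
        for t in range(1, T):
            for k in range(K):
                stay = log_stay if k < K - 1 else 0.0
                a = alpha[t - 1, k] + stay
                b = alpha[t - 1, k - 1] + log_adv if k > 0 else neg_inf
                if a == neg_inf:
                    m = b
                elif b == neg_inf:
                    m = a
                elif a > b:
                    m = a + np.log1p(np.exp(b - a))
                else:
                    m = b + np.log1p(np.exp(a - b))
                alpha[t, k] = logB[k, t] + m
        beta = np.full((T, K), neg_inf)
        beta[T - 1, K - 1] = 0.0
        for t in range(T - 2, -1, -1):
            for k in range(K):
                stay = log_stay if k < K - 1 else 0.0
                a = beta[t + 1, k] + logB[k, t + 1] + stay
                b = (
                    beta[t + 1, k + 1] + logB[k + 1, t + 1] + log_adv
                    if k < K - 1
                    else neg_inf
                )
                if a == neg_inf:
                    m = b
                elif b == neg_inf:
                    m = a
                elif a > b:
                    m = a + np.log1p(np.exp(b - a))
                else:
                    m = b + np.log1p(np.exp(a - b))
                beta[t, k] = m
        log_lik = alpha[T - 1, K - 1]
        return (alpha + beta - log_lik).T, log_lik

    def _forward_backward(logB, log_stay, log_adv):
        log_gamma, log_lik = _fb_kernel(
            np.ascontiguousarray(logB), float(log_stay), float(log_adv)
        )
        return log_gamma, float(log_lik)

except ImportError:  # pragma: no cover
    _forward_backward = _forward_backward_numpy


def _monotone_argmax_labels(log_gamma: np.ndarray) -> np.ndarray:
    """Monotone complete state path maximizing the summed log posterior.

    Dynamic program over paths that start in state 0, end in state K-1 and
    advance by at most one state per step.  Ties are broken toward the
    earlier state (the boundary is placed as late as possible), so the
    labeling is deterministic.  Whenever the per-timepoint posterior argmax
    is itself such a path, this returns exactly that argmax.
    """
    K, T = log_gamma.shape
    score = np.full((T, K), -np.inf)
    from_diag = np.zeros((T, K), dtype=bool)
    score[0, 0] = log_gamma[0, 0]
    for t in range(1, T):
        prev = score[t - 1]
        diag = np.concatenate([[-np.inf], prev[:-1]])
        take = diag >= prev  # tie -> predecessor k-1, i.e. earlier state before t
        score[t] = log_gamma[:, t] + np.where(take, diag, prev)
        from_diag[t] = take

    labels = np.empty(T, dtype=int)
    k = K - 1
    labels[T - 1] = k
    for t in range(T - 1, 0, -1):
        if from_diag[t, k]:
            k -= 1
        labels[t - 1] = k
    return labels


def _greedy_split_edges(Zt: np.ndarray, K: int) -> np.ndarray:
    """Segment edges from greedy top-down least-squares binary splitting.

    Repeatedly splits the segment (at the interior timepoint) that most
    reduces the total within-segment sum of squares; O(K*T*V) using prefix
    sums.  Serves as a second deterministic EM initialization that handles
    very uneven event durations, where a uniform partition can trap EM in a
    local optimum.
    """
    T, V = Zt.shape
    s = np.vstack([np.zeros(V), np.cumsum(Zt, axis=0)])
    sq = np.concatenate([[0.0], np.cumsum((Zt**2).sum(axis=1))])

    def cost(a, b):
        return sq[b] - sq[a] - ((s[b] - s[a]) ** 2).sum(axis=-1) / (b - a)

    edges = [0, T]
    for _ in range(K - 1):
        best = None
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a < 2:
                continue
            c = np.arange(a + 1, b)
            left = (sq[c] - sq[a]) - ((s[c] - s[a]) ** 2).sum(axis=1) / (c - a)
            right = (sq[b] - sq[c]) - ((s[b] - s[c]) ** 2).sum(axis=1) / (b - c)
            gain = cost(a, b) - (left + right)
            j = int(np.argmax(gain))
            if best is None or gain[j] > best[0]:
                best = (gain[j], int(c[j]))
        edges = sorted(edges + [best[1]])
    return np.asarray(edges)


def _em_run(Zt, V, T, K, edges, log_stay, log_adv, max_iter, tol):
    """One EM run from segment-edge initialized state means."""
    mu = np.stack([Zt[a:b].mean(axis=0) for a, b in zip(edges[:-1], edges[1:])])
    var = 1.0
    d2 = ((Zt[None, :, :] - mu[:, None, :]) ** 2).sum(axis=2)  # (K, T)
    log_lik = -np.inf
    converged = False
    n_iter = 0
    log_gamma = None
    for n_iter in range(1, max_iter + 1):
        logB = -0.5 * (V * np.log(2.0 * np.pi * var) + d2 / var)
        log_gamma, ll = _forward_backward(logB, log_stay, log_adv)
        if np.isfinite(ll) and abs(ll - log_lik) < tol:
            log_lik = ll
            converged = True
            break
        log_lik = ll
        gamma = np.exp(log_gamma)  # (K, T)
        w = gamma.sum(axis=1)
        mu = (gamma @ Zt) / w[:, None]
        d2 = ((Zt[None, :, :] - mu[:, None, :]) ** 2).sum(axis=2)
        var = max(float((gamma * d2).sum() / (T * V)), _VAR_FLOOR)
    return log_gamma, log_lik, mu, n_iter, converged


def fit_event_hmm(
    data: np.ndarray,
    K: int,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> EventSegmentation:
    """Fit the K-event left-to-right HMM to a voxel x time matrix.

    The data are spatially z-scored, then EM alternates an exact
    forward-backward E-step with M-step updates of the state mean patterns
    and the single shared isotropic variance.  Transition probabilities are
    fixed from the expected event length (advance probability K/T).  EM runs
    from two deterministic initializations — state means from a uniform
    partition of time into K contiguous blocks, and from a greedy top-down
    least-squares split — and the run with the higher final log-likelihood
    is returned, so fits are reproducible without seeds.

    Parameters
    ----------
    data : (V, T) array
    K : number of events, 2 <= K <= T.
    max_iter : EM iteration cap per initialization.
    tol : convergence threshold on the absolute log-likelihood change.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D voxel x time matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("data contain non-finite values")
    V, T = X.shape
    if not 2 <= K <= T:
        raise ValueError(f"event count K={K} must satisfy 2 <= K <= T={T}")

    Z = zscore_spatial(X)
    Zt = Z.T  # (T, V)

    p_adv = K / T
    with np.errstate(divide="ignore"):
        log_stay = np.log1p(-p_adv) if p_adv < 1.0 else -np.inf
        log_adv = np.log(p_adv)

    uniform = np.round(np.linspace(0, T, K + 1)).astype(int)
    inits = [uniform]
    greedy = _greedy_split_edges(Zt, K)
    if not np.array_equal(greedy, uniform):
        inits.append(greedy)

    best = None
    for edges in inits:
        run = _em_run(Zt, V, T, K, edges, log_stay, log_adv, max_iter, tol)
        if best is None or run[1] > best[1]:
            best = run
    log_gamma, log_lik, mu, n_iter, converged = best

    labels = _monotone_argmax_labels(log_gamma)
    boundaries = extract_boundaries(labels)
    return EventSegmentation(
        K=K,
        labels=labels,
        boundaries=boundaries,
        event_patterns=mu,
        log_lik=log_lik,
        n_iter=n_iter,
        converged=converged,
    )
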