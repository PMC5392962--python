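"""Fuzzy C-means clustering of gray values.

This is the segmentation core: FCM soft-partitions the pixel gray values of a
mammographic view into ``k`` clusters by alternating minimisation of

    J(U, V) = sum_ij  u_ij^m  (x_j - v_i)^2

subject to the memberships of each pixel summing to one, with the standard
update rules

    u_ij = 1 / sum_l ( |x_j - v_i| / |x_j - v_l| )^(2/(m-1))
    v_i  = sum_j u_ij^m x_j / sum_j u_ij^m .

The fuzzifier ``m`` controls softness (m -> 1 approaches hard k-means). The
implementation works on the 1-D value distribution, so identical gray values
share memberships; internally the unique values are clustered with counts as
weights, which leaves the optimisation exactly equivalent while keeping the
cost independent of image size for low-bit-depth data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InputError, ParameterError

__all__ = ["FCMResult", "fcm_cluster"]


@dataclass
class FCMResult:
    """Converged state of one FCM run.

    Attributes
    ----------
    centroids
        Cluster centres in strictly ascending gray-value order.
    memberships
        ``(n, k)`` array; row ``j`` holds pixel ``j``'s membership in each
        cluster (columns follow ``centroids``); each row sums to 1.
    hard_labels
        Per-pixel argmax cluster index.
    objective_trace
        Objective value at each iteration; non-increasing.
    m
        Fuzzifier used.
    converged
        True when the maximum centroid shift fell below the tolerance before
        ``max_iter`` was reached.
    n_iter
        Number of completed iterations.
    """

    centroids: np.ndarray
    memberships: np.ndarray
    hard_labels: np.ndarray
    objective_trace: np.ndarray
    m: float
    converged: bool
    n_iter: int

    def to_json_dict(self) -> dict:
        """Diagnostics summary (centroids, iterations, final objective)."""
        return {
            "centroids": [float(c) for c in self.centroids],
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "final_objective": float(self.objective_trace[-1]),
            "fuzzifier": float(self.m),
        }


def _memberships(x: np.ndarray, v: np.ndarray, m: float) -> np.ndarray:
    """Membership update; a value coinciding exactly with a centroid gets
    membership 1 for that cluster (0 for the rest)."""
    d2 = (x[:, None] - v[None, :]) ** 2
    zero = d2 == 0.0
    with np.errstate(divide="ignore"):
        p = d2 ** (-1.0 / (m - 1.0))
    u = np.empty_like(p)
    finite_rows = ~zero.any(axis=1)
    u[finite_rows] = p[finite_rows] / p[finite_rows].sum(axis=1, keepdims=True)
    if not finite_rows.all():
        rows = ~finite_rows
        u[rows] = 0.0
        # exactly one centroid can coincide (centroids kept distinct)
        u[rows] = zero[rows].astype(float)
    return u


def _objective(x: np.ndarray, w: np.ndarray, u: np.ndarray, v: np.ndarray,
               m: float) -> float:
    d2 = (x[:, None] - v[None, :]) ** 2
    return float((w[:, None] * u**m * d2).sum())


def _reseed_coincident(v: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Break exactly-coincident centroids by moving duplicates to the
    midpoint of the widest empty gap of the data range."""
    v = np.sort(v)
    lo, hi = float(x.min()), float(x.max())
    guard = 0
    while np.any(np.diff(v) == 0) and guard < len(v):
        i = int(np.flatnonzero(np.diff(v) == 0)[0])
        anchors = np.unique(np.concatenate(([lo], v, [hi])))
        gaps = np.diff(anchors)
        g = int(np.argmax(gaps))
        v[i] = anchors[g] + gaps[g] / 2.0
        v = np.sort(v)
        guard += 1
    return v


def _descend(x, w, v0, m, tol, max_iter):
    """One alternating-minimisation run from initial centroids ``v0``."""
    v = _reseed_coincident(np.array(v0, dtype=float), x)
    trace: list[float] = []
    converged = False
    n_iter = 0
    u = _memberships(x, v, m)
    for n_iter in range(1, max_iter + 1):
        # objective evaluated at (U_t, V_{t-1}); both half-steps only ever
        # decrease J, so the trace is non-increasing
        trace.append(_objective(x, w, u, v, m))
        um = (w[:, None]) * u**m
        denom = um.sum(axis=0)
        v_new = np.where(denom > 0, (um * x[:, None]).sum(axis=0)
                         / np.where(denom > 0, denom, 1.0), v)
        v_new = np.sort(v_new)
        if np.any(np.diff(v_new) == 0):
            v_new = _reseed_coincident(v_new, x)
            trace.clear()  # reseeding restarts the descent
        shift = float(np.max(np.abs(v_new - v)))
        v = v_new
        u = _memberships(x, v, m)
        if shift < tol:
            converged = True
            break
    trace.append(_objective(x, w, u, v, m))
    return v, u, np.asarray(trace), converged, n_iter


def fcm_cluster(
    values,
    k: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = None,
    init_jitter: float = 0.0,
    n_restarts: int = 1,
) -> FCMResult:
    """Cluster a 1-D set of gray values into ``k`` fuzzy clusters.

    Initialisation is deterministic: centroids start evenly spaced across
    the value range, which is robust to heavily imbalanced tissue classes.
    ``seed`` controls an optional uniform jitter of the initial centroids
    (``init_jitter`` > 0, in gray levels) and the extra random
    initialisations when ``n_restarts`` > 1, so repeated runs with the same
    arguments are bit-identical. Multiple restarts (the best final
    objective wins) are useful on tiny, irregular value sets where a single
    descent can stop in a local optimum; image-sized tissue histograms are
    well separated and use the default single start.

    Parameters
    ----------
    values
        Sequence/array of finite gray values (flattened).
    k
        Number of clusters, >= 2; requires at least ``k`` distinct values.
    m
        Fuzzifier, > 1.
    tol
        Convergence threshold on the maximum centroid shift.
    max_iter
        Iteration cap per start.
    seed, init_jitter
        Optional reproducible jitter of the initial centroids.
    n_restarts
        Number of initialisations (1 = the deterministic spread only).

    Returns
    -------
    FCMResult

    Raises
    ------
    InputError
        Non-finite values.
    ParameterError
        ``k < 2`` or ``m <= 1``.
    DegenerateInputError
        Fewer than ``k`` distinct values.
    """
    x_full = np.asarray(values, dtype=np.float64).ravel()
    if x_full.size == 0 or not np.all(np.isfinite(x_full)):
        raise InputError("values must be non-empty and finite")
    if k < 2:
        raise ParameterError("k must be >= 2")
    if not m > 1:
        raise ParameterError("fuzzifier m must be > 1")
    if tol <= 0 or max_iter < 1 or n_restarts < 1:
        raise ParameterError("tol > 0, max_iter >= 1, n_restarts >= 1")

    # weighted clustering of unique values: exactly equivalent objective
    x, inverse, w_int = np.unique(x_full, return_inverse=True,
                                  return_counts=True)
    if x.size < k:
        raise DegenerateInputError(
            f"need at least {k} distinct values, got {x.size}"
        )
    w = w_int.astype(np.float64)

    lo, hi = float(x.min()), float(x.max())
    v0 = lo + (np.arange(k) + 0.5) / k * (hi - lo)
    rng = np.random.default_rng(seed if seed is not None else 0)
    if init_jitter > 0 and seed is not None:
        v0 = v0 + rng.uniform(-init_jitter, init_jitter, size=k)

    best = None
    for start in range(n_restarts):
        vi = v0 if start == 0 else np.sort(rng.choice(x, size=k,
                                                      replace=False))
        run = _descend(x, w, vi, m, tol, max_iter)
        if best is None or run[2][-1] < best[2][-1]:
            best = run
    v, u, trace, converged, n_iter = best

    memberships = u[inverse]
    hard = np.argmax(memberships, axis=1)
    return FCMResult(
        centroids=v,
        memberships=memberships,
        hard_labels=hard,
        objective_trace=trace,
        m=m,
        converged=converged,
        n_iter=n_iter,
    )
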