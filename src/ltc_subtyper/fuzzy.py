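"""Fuzzy c-means clustering with Xie-Beni model selection and run consensus.

Standard Bezdek fuzzy c-means on the MCA coordinates: memberships
``u_ik ∈ [0, 1]`` with rows summing to 1, fuzzifier ``m > 1``, alternating
updates

    v_i = Σ_k u_ik^m x_k / Σ_k u_ik^m
    u_ik = 1 / Σ_j (d_ik / d_jk)^{2/(m−1)}

minimizing J_m = Σ_i Σ_k u_ik^m ‖x_k − v_i‖².  A point coinciding with a
center receives membership 1 on (the first of) its coincident centers.

Cluster-number selection combines the elbow curve of J_m with the Xie-Beni
index XB = J_m / (n · min_{i≠j} ‖v_i − v_j‖²); the chosen c minimizes XB
(ties broken toward the smaller c).

Because c-means solutions depend on the random start, the final partition
is a *consensus* over repeated runs (100 by default): the lowest-objective
run serves as the reference, each run's clusters are matched to it by a
maximum-weight one-to-one assignment on membership-column inner products,
and the aligned membership matrices are averaged and row-renormalized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, List

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

_ZERO = 1e-12


@dataclass
class FuzzyPartition:
    membership: np.ndarray  # (n, c), rows sum to 1
    centers: np.ndarray  # (c, d)
    objective: float  # J_m
    m: float
    seed: int
    n_iterations: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


@dataclass
class SelectionReport:
    candidates: List[int]
    objectives: List[float]  # elbow curve
    xie_beni_values: List[float]
    chosen_c: int


def _objective(u: np.ndarray, d2: np.ndarray, m: float) -> float:
    return float((u.T**m * d2).sum())


def _update_membership(d2: np.ndarray, m: float) -> np.ndarray:
    """u (n × c) from squared center distances d2 (c × n)."""
    c, n = d2.shape
    u = np.empty((n, c))
    zero_cols = d2.min(axis=0) < _ZERO
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))  # (c, n)
        u[:] = (inv / inv.sum(axis=0)).T
    if zero_cols.any():
        for k in np.flatnonzero(zero_cols):
            u[k] = 0.0
            u[k, int(np.argmin(d2[:, k]))] = 1.0
    return u


def fcm_fit(
    X,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> FuzzyPartition:
    """Fit fuzzy c-means from seeded random initial centers.

    Initial centers are ``c`` distinct data points sampled uniformly (the
    convention of standard c-means implementations); starting instead from
    uniformly random memberships places all initial centers at the grand
    mean, which is a degenerate stationary point of J_m that the updates
    cannot leave.  Iterates until the maximum absolute membership change
    drops below ``tol`` or ``max_iter`` is reached; the objective is
    checked to be nonincreasing across iterations.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not 1 <= c <= n:
        raise ValueError(f"need 1 <= c <= n; got c={c}, n={n}")
    if not m > 1:
        raise ValueError("fuzzifier m must be > 1")

    rng = np.random.default_rng(seed)
    centers = X[rng.choice(n, size=c, replace=False)]
    u = _update_membership(cdist(centers, X, metric="sqeuclidean"), m)

    prev_obj = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        um = u**m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = cdist(centers, X, metric="sqeuclidean")
        u_new = _update_membership(d2, m)
        obj = _objective(u_new, d2, m)
        # alternating minimization: J_m never increases (numerical slack)
        assert obj <= prev_obj + 1e-8 * max(1.0, abs(prev_obj)), (
            f"objective increased: {prev_obj} -> {obj}"
        )
        delta = float(np.abs(u_new - u).max())
        u = u_new
        prev_obj = obj
        if delta < tol:
            converged = True
            break

    um = u**m
    centers = (um.T @ X) / um.sum(axis=0)[:, None]
    d2 = cdist(centers, X, metric="sqeuclidean")
    obj = _objective(u, d2, m)
    return FuzzyPartition(
        membership=u,
        centers=centers,
        objective=obj,
        m=m,
        seed=seed,
        n_iterations=it,
        converged=converged,
    )


def xie_beni(X, partition: FuzzyPartition) -> float:
    """Xie-Beni validity index; +inf (with a warning) on coincident centers."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    v = partition.centers
    if v.shape[0] < 2:
        raise ValueError("Xie-Beni requires at least 2 clusters")
    d2 = cdist(v, X, metric="sqeuclidean")
    num = _objective(partition.membership, d2, partition.m)
    sep = cdist(v, v, metric="sqeuclidean")
    np.fill_diagonal(sep, np.inf)
    min_sep = float(sep.min())
    if min_sep < _ZERO:
        warnings.warn("coincident cluster centers: Xie-Beni index is infinite")
        return np.inf
    return num / (X.shape[0] * min_sep)


def select_c(
    X,
    c_candidates: Iterable[int] = range(2, 11),
    runs_per_c: int = 5,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> SelectionReport:
    """Elbow curve and Xie-Beni index over candidate cluster numbers.

    For each candidate c the best of ``runs_per_c`` seeded fits (lowest
    J_m) is evaluated; the chosen c minimizes the Xie-Beni index, with ties
    broken toward the smaller c.
    """
    candidates = sorted(int(c) for c in c_candidates)
    if not candidates or min(candidates) < 2:
        raise ValueError("c_candidates must all be >= 2")
    objectives, xbs = [], []
    for c in candidates:
        best = None
        for r in range(runs_per_c):
            fit = fcm_fit(X, c, m=m, tol=tol, max_iter=max_iter,
                          seed=seed + 1000 * c + r)
            if best is None or fit.objective < best.objective:
                best = fit
        objectives.append(best.objective)
        xbs.append(xie_beni(X, best))
    chosen = candidates[int(np.argmin(xbs))]  # argmin takes first on ties
    logger.info("select_c: chose c=%d (XB=%s)", chosen, dict(zip(candidates, xbs)))
    return SelectionReport(
        candidates=candidates,
        objectives=objectives,
        xie_beni_values=xbs,
        chosen_c=chosen,
    )


def _align_to_reference(u_ref: np.ndarray, u_run: np.ndarray) -> np.ndarray:
    """Permutation of run clusters maximizing Σ_i <u_ref[:,i], u_run[:,perm[i]]>."""
    overlap = u_ref.T @ u_run  # (c, c)
    _, cols = linear_sum_assignment(-overlap)
    return cols


def consensus_fcm(
    X,
    c: int,
    n_runs: int = 100,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> FuzzyPartition:
    """Average partition over repeated seeded runs after label alignment.

    Run seeds are ``seed + run_index``.  The lowest-objective run is the
    alignment reference; aligned memberships are averaged elementwise, rows
    renormalized, and consensus centers recomputed from the consensus
    memberships.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs = [
        fcm_fit(X, c, m=m, tol=tol, max_iter=max_iter, seed=seed + r)
        for r in range(n_runs)
    ]
    ref = min(runs, key=lambda p: p.objective)
    acc = np.zeros_like(ref.membership)
    for run in runs:
        perm = _align_to_reference(ref.membership, run.membership)
        acc += run.membership[:, perm]
    u = acc / n_runs
    u /= u.sum(axis=1, keepdims=True)
    um = u**m
    centers = (um.T @ X) / um.sum(axis=0)[:, None]
    d2 = cdist(centers, X, metric="sqeuclidean")
    return FuzzyPartition(
        membership=u,
        centers=centers,
        objective=_objective(u, d2, m),
        m=m,
        seed=seed,
        n_iterations=sum(r.n_iterations for r in runs),
        converged=all(r.converged for r in runs),
    )


def hard_assign(partition: FuzzyPartition) -> np.ndarray:
    """Per-row argmax labels in 1..c; exact ties go to the lowest index."""
    u = partition.membership
    labels = np.argmax(u, axis=1)  # first maximum on ties
    n_ties = int((np.isclose(u, u.max(axis=1, keepdims=True)).sum(axis=1) > 1).sum())
    if n_ties:
        logger.info("hard_assign: %d rows had tied memberships", n_ties)
    return labels + 1
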