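"""Model-based clustering of expression profiles by relocation iteration.

A dataset of N equal-length profiles is partitioned into K clusters, each
described by one damped-sinusoid-plus-trend parameter vector theta_k.  The
objective is the pooled residual cost

    f(C | Theta) = sum_k sum_{x in C_k} sum_i (x(t_i) - model_k(t_i))^2,

minimized by alternating two moves until the cost stops improving:

1. *Pooled estimation* — refit each cluster's parameters by the two-step
   estimator with per-profile normal-equation terms summed over the
   cluster's members (equivalently, least squares on the members' stacked
   design matrices).  A cluster of one profile reduces exactly to the
   single-profile fit.
2. *Relocation* — reassign every profile to the cluster whose fitted curve
   it is closest to in squared error.

Because the two-step estimator only approximates the least-squares optimum,
the estimation move is not guaranteed to lower the cost; an iteration whose
reassigned cost would exceed the previous one is rejected and the algorithm
stops there, which keeps the recorded cost trace non-increasing.

Clusters that turn up empty after a relocation are reseeded with the
profile currently worst-fit by its own cluster; clusters whose pooled
estimate is degenerate keep their previous parameters (or, lacking any, sit
out the assignment until reseeded).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .estimation import (
    MIN_PROFILE_LENGTH,
    RankDeficiencyError,
    SingularityError,
    TooShortProfileError,
    _lstsq_checked,
    _stencil_derivatives,
    resolve_stencil,
)
from .model import (
    DegenerateModelError,
    ModelParams,
    OdeParams,
    Profile,
    evaluate_model,
    ode_to_model,
    profiles_matrix,
    time_grid,
)

__all__ = [
    "ClusterModel",
    "RestartResult",
    "UnknownLabelError",
    "AllDegenerateError",
    "cluster_cost",
    "estimate_cluster_params",
    "assign_profiles",
    "relocate_iterate",
    "cluster_with_restarts",
]

logger = logging.getLogger(__name__)


class UnknownLabelError(ValueError):
    """A label refers to a cluster with no parameters, or is out of range."""


class AllDegenerateError(RuntimeError):
    """No cluster has usable (non-degenerate) model parameters."""


@dataclasses.dataclass(frozen=True)
class ClusterModel:
    """A K-way partition with per-cluster model parameters.

    ``labels`` holds a cluster index in 0..K-1 for each profile;
    ``cluster_params[k]`` is ``None`` for a cluster whose model is
    degenerate.  ``cost_trace`` records the pooled residual cost after each
    accepted iteration and is non-increasing by construction.
    ``stop_reason`` is one of ``stable`` (memberships repeated exactly: the
    partition is a fixed point of the update map), ``no_improvement``
    (relative cost gain below tolerance), ``cost_increase`` (the
    approximate estimation step would have raised the cost; the offending
    iteration was discarded), or ``max_iter``.
    """

    K: int
    labels: np.ndarray
    cluster_params: tuple[ModelParams | None, ...]
    cost: float
    n_iter: int
    converged: bool
    cost_trace: tuple[float, ...]
    stop_reason: str = "max_iter"

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)


@dataclasses.dataclass(frozen=True)
class RestartResult:
    """Outcome of repeated relocation-iteration runs from different starts."""

    best: ClusterModel
    runs: tuple[ClusterModel, ...]

    @property
    def label_sets(self) -> list[np.ndarray]:
        """Every run's final labels, in run order (for AARI)."""
        return [run.labels for run in self.runs]


# ---------------------------------------------------------------------------
# Pooled two-step estimation on a member matrix


def _pooled_step1(V: np.ndarray, delta: float, stencil: str = "central2") -> OdeParams:
    n, m = V.shape
    stencil = resolve_stencil(stencil, m)
    xd1, xd2, interior = _stencil_derivatives(V.T, delta, stencil)
    xd1, xd2 = xd1.T, xd2.T
    t_int = time_grid(m, delta)[interior]
    X = np.empty((n * t_int.size, 4))
    X[:, 0] = -xd1.ravel()
    X[:, 1] = -V[:, interior].ravel()
    X[:, 2] = np.tile(t_int, n)
    X[:, 3] = 1.0
    sol = _lstsq_checked(
        X, xd2.ravel(), RankDeficiencyError, "pooled Step-1 design", zero_rhs_ok=True
    )
    return OdeParams(*sol)


def _pooled_step2(
    V: np.ndarray, delta: float, alpha: float, omega: float, c: float, d: float
) -> tuple[float, float]:
    m = V.shape[1]
    t = time_grid(m, delta)
    # Summed normal equations across members collapse to a regression of the
    # member-averaged z on [cos, sin] because the design depends only on omega.
    z_mean = (np.exp(-alpha * t) * (V - c * t - d)).mean(axis=0)
    M = np.column_stack([np.cos(omega * t), np.sin(omega * t)])
    sol = _lstsq_checked(M, z_mean, SingularityError, "pooled sinusoid design")
    return float(sol[0]), float(sol[1])


def _estimate_matrix(V: np.ndarray, delta: float, stencil: str = "central2") -> ModelParams:
    if V.shape[1] < MIN_PROFILE_LENGTH:
        raise TooShortProfileError(
            f"cluster profiles have m={V.shape[1]} < {MIN_PROFILE_LENGTH} time points"
        )
    ode = _pooled_step1(V, delta, stencil)
    alpha, omega, c, d = ode_to_model(ode)  # may raise DegenerateModelError
    a, b = _pooled_step2(V, delta, alpha, omega, c, d)
    return ModelParams(alpha=alpha, omega=omega, a=a, b=b, c=c, d=d)


def estimate_cluster_params(
    profiles: Sequence[Profile], delta: float | None = None, stencil: str = "central2"
) -> ModelParams:
    """Pooled two-step fit of one cluster's model from its member profiles.

    Reduces exactly to :func:`cyclefit.estimation.fit_profile` parameters
    when the cluster has a single member, and is invariant to duplicating
    members.

    Raises
    ------
    DegenerateModelError
        If the pooled Step-1 estimate admits no oscillatory solution.
    """
    V, d_shared = profiles_matrix(profiles)
    if delta is not None and delta != d_shared:
        raise ValueError("delta disagrees with the profiles' sampling interval")
    return _estimate_matrix(V, d_shared, stencil)


# ---------------------------------------------------------------------------
# Cost and assignment


def _curves(
    cluster_params: Sequence[ModelParams | None], m: int, delta: float
) -> np.ndarray:
    """(K, m) fitted curves; rows for degenerate clusters are NaN."""
    K = len(cluster_params)
    curves = np.full((K, m), np.nan)
    for k, params in enumerate(cluster_params):
        if params is not None:
            curves[k] = evaluate_model(params, m, delta)
    return curves


def _cost_matrix(
    V: np.ndarray,
    delta: float,
    labels: np.ndarray,
    cluster_params: Sequence[ModelParams | None],
) -> float:
    K = len(cluster_params)
    if labels.min() < 0 or labels.max() >= K:
        raise UnknownLabelError("label outside 0..K-1")
    for k in np.unique(labels):
        if cluster_params[k] is None:
            raise UnknownLabelError(f"cluster {k} is referenced but has no parameters")
    curves = _curves(cluster_params, V.shape[1], delta)
    return float(np.sum((V - curves[labels]) ** 2))


def cluster_cost(
    profiles: Sequence[Profile],
    labels: Sequence[int],
    cluster_params: Sequence[ModelParams | None],
) -> float:
    """Pooled residual cost of a labelled partition under per-cluster models."""
    V, delta = profiles_matrix(profiles)
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != V.shape[0]:
        raise ValueError("labels and profiles have different lengths")
    return _cost_matrix(V, delta, labels, cluster_params)


def _assign_matrix(
    V: np.ndarray, delta: float, cluster_params: Sequence[ModelParams | None]
) -> np.ndarray:
    curves = _curves(cluster_params, V.shape[1], delta)
    if np.all(np.isnan(curves)):
        raise AllDegenerateError("no cluster has usable model parameters")
    costs = np.nansum((V[:, None, :] - curves[None, :, :]) ** 2, axis=2)
    costs[:, np.isnan(curves).any(axis=1)] = np.inf
    # argmin breaks exact ties toward the lowest cluster index
    return np.argmin(costs, axis=1)


def assign_profiles(
    profiles: Sequence[Profile], cluster_params: Sequence[ModelParams | None]
) -> np.ndarray:
    """Assign each profile to the cluster curve it is closest to.

    Degenerate clusters (``None`` parameters) are skipped; exact ties go to
    the lowest cluster index.

    Raises
    ------
    AllDegenerateError
        If every cluster is degenerate.
    """
    V, delta = profiles_matrix(profiles)
    return _assign_matrix(V, delta, cluster_params)


# ---------------------------------------------------------------------------
# Relocation iteration


def _member_residuals(
    V: np.ndarray,
    delta: float,
    labels: np.ndarray,
    cluster_params: Sequence[ModelParams | None] | None,
) -> np.ndarray:
    """Squared residual of each profile against its own cluster's model.

    Before any model exists (first iteration), the cluster mean profile
    stands in for the fitted curve.
    """
    N, m = V.shape
    resid = np.zeros(N)
    for k in np.unique(labels):
        members = labels == k
        if cluster_params is not None and cluster_params[k] is not None:
            curve = evaluate_model(cluster_params[k], m, delta)
        else:
            curve = V[members].mean(axis=0)
        resid[members] = np.sum((V[members] - curve) ** 2, axis=1)
    return resid


def _reseed_empty(
    V: np.ndarray,
    delta: float,
    labels: np.ndarray,
    K: int,
    cluster_params: Sequence[ModelParams | None] | None,
) -> np.ndarray:
    """Move the worst-fit profile from a multi-member cluster into each empty one."""
    labels = labels.copy()
    for k in range(K):
        if np.any(labels == k):
            continue
        resid = _member_residuals(V, delta, labels, cluster_params)
        sizes = np.bincount(labels, minlength=K)
        donors = np.flatnonzero(sizes[labels] >= 2)
        if donors.size == 0:
            continue  # nothing to split; leave the cluster empty
        mover = donors[np.argmax(resid[donors])]
        logger.debug("reseeding empty cluster %d with profile %d", k, mover)
        labels[mover] = k
    return labels


def relocate_iterate(
    profiles: Sequence[Profile],
    K: int,
    init: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 100,
    stencil: str = "central2",
) -> ClusterModel:
    """Alternate pooled estimation and relocation from an initial partition.

    Stops when cluster memberships repeat exactly, when the relative cost
    improvement falls below ``tol``, when an iteration fails to improve the
    cost (the approximate estimator makes this possible; the offending
    iteration is discarded), or after ``max_iter`` iterations.
    """
    V, delta = profiles_matrix(profiles)
    N = V.shape[0]
    if K < 1 or N < K:
        raise ValueError(f"need 1 <= K <= N, got K={K}, N={N}")
    labels = np.asarray(init, dtype=int)
    if labels.shape != (N,) or labels.min() < 0 or labels.max() >= K:
        raise ValueError("init must assign each profile a label in 0..K-1")

    params: list[ModelParams | None] = [None] * K
    cost: float | None = None
    trace: list[float] = []
    n_iter = 0
    converged = False
    stop_reason = "max_iter"

    for it in range(1, max_iter + 1):
        labels_work = _reseed_empty(V, delta, labels, K, params if any(params) else None)
        new_params: list[ModelParams | None] = []
        for k in range(K):
            members = V[labels_work == k]
            if members.shape[0] == 0:
                new_params.append(params[k])
                continue
            try:
                new_params.append(_estimate_matrix(members, delta, stencil))
            except (DegenerateModelError, RankDeficiencyError, SingularityError):
                if params[k] is not None:
                    logger.warning(
                        "cluster %d: degenerate pooled estimate at iteration %d; "
                        "keeping previous parameters",
                        k,
                        it,
                    )
                new_params.append(params[k])
        if all(p is None for p in new_params):
            raise AllDegenerateError("every cluster model is degenerate")

        new_labels = _assign_matrix(V, delta, new_params)
        new_cost = _cost_matrix(V, delta, new_labels, new_params)

        if cost is not None and new_cost > cost:
            # The approximate estimation step worsened the fit; discard this
            # iteration and stop at the previous (better) state.
            converged = True
            stop_reason = "cost_increase"
            break

        n_iter = it
        trace.append(new_cost)
        no_improvement = cost is not None and (cost - new_cost) <= tol * max(cost, 1e-300)
        unchanged = np.array_equal(new_labels, labels)
        labels, params, cost = new_labels, new_params, new_cost
        if unchanged or no_improvement:
            converged = True
            stop_reason = "stable" if unchanged else "no_improvement"
            break

    return ClusterModel(
        K=K,
        labels=labels,
        cluster_params=tuple(params),
        cost=float(cost),
        n_iter=n_iter,
        converged=converged,
        cost_trace=tuple(trace),
        stop_reason=stop_reason,
    )


def cluster_with_restarts(
    profiles: Sequence[Profile],
    K: int,
    n_restarts: int = 30,
    init_mode: Literal["random", "kmeans"] = "random",
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    stencil: str = "central2",
) -> RestartResult:
    """Run relocation iteration from many initial partitions; keep them all.

    ``random`` draws each profile's initial label uniformly from 0..K-1;
    ``kmeans`` seeds each restart with a (differently seeded) Euclidean
    k-means partition of the raw profile vectors.  Restart r derives its
    own RNG stream from ``seed``, so results are reproducible per
    (seed, r).  The lowest-cost run is returned as ``best``; every run's
    labels are retained so clustering stability (AARI) can be scored.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    V, _ = profiles_matrix(profiles)
    N = V.shape[0]
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    runs: list[ClusterModel] = []
    for child in children:
        rng = np.random.default_rng(child)
        if init_mode == "random":
            init = rng.integers(0, K, size=N)
        elif init_mode == "kmeans":
            km = KMeans(
                n_clusters=K,
                n_init=1,
                random_state=int(rng.integers(2**31)),
            )
            init = km.fit_predict(V)
        else:
            raise ValueError(f"unknown init_mode {init_mode!r}")
        runs.append(
            relocate_iterate(
                profiles, K, init, tol=tol, max_iter=max_iter, stencil=stencil
            )
        )
    best = min(runs, key=lambda run: run.cost)
    return RestartResult(best=best, runs=tuple(runs))


def kmeans_labels(
    profiles: Sequence[Profile] | Iterable[Profile],
    K: int,
    n_runs: int = 30,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Plain Euclidean k-means on raw profile vectors, one label set per run.

    Comparator for the model-based algorithm; each run uses a single
    k-means start with its own derived seed.
    """
    V, _ = profiles_matrix(profiles)
    children = np.random.SeedSequence(seed).spawn(n_runs)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        km = KMeans(n_clusters=K, n_init=1, random_state=int(rng.integers(2**31)))
        out.append(km.fit_predict(V))
    return out
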