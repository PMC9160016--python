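"""Reconstruction of 2-simplicial complexes from binary time series.

The reconstruction engine treats each node ``i`` in turn as the *target* and
models the number of times it leaves the susceptible state as a Poisson
superposition of channels: one channel per candidate neighbor ``j`` (with
weight ``P_{j->i} * P_j^i * Psi_j``), one per candidate triple partner pair
``{j, k}`` (weight ``P_{jk->i} * P_jk^i * Psi_j Psi_k``), and a noise floor
``eps_i``.  Here ``P_j^i`` and ``P_jk^i`` are conditional infection
frequencies counted directly from the data matrix, and ``Psi`` are the
observed 0/1 activity indicators at each time step.  The channel weights are
estimated by expectation maximization; because all channel intensities enter
the Poisson rate linearly, the M-step reduces to the familiar multiplicative
(Richardson–Lucy style) update and the log-likelihood is non-decreasing
across iterations.

The full pipeline (:func:`reconstruct`) uses a two-step strategy: a first EM
pass with pair channels only ranks candidate neighbors, a maximum-gap
truncation (:func:`gap_threshold`, applied twice) extracts an approximate
neighborhood, and a second EM pass restricted to those neighbors and their
pairs yields the final edge and triangle probabilities.  Edges are declared
where either directed probability is positive; triangles must win at least
two of their three directed above-threshold votes and must be closed by
predicted edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .complexes import SimplicialComplex2
from .dynamics import StateMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EMOptions",
    "CondEntry",
    "EmpiricalConditionals",
    "InferenceResult",
    "TruncationResult",
    "Reconstruction",
    "empirical_conditionals",
    "em_full",
    "em_first_step",
    "em_responsibilities",
    "gap_threshold",
    "approximate_neighbors",
    "reconstruct",
]


# --------------------------------------------------------------------------
# options and result containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EMOptions:
    """Knobs of the EM solver.

    ``tol`` bounds the per-parameter relative change declaring convergence
    (parameters below ``rel_floor`` are compared on the absolute scale, so a
    channel decaying toward zero does not stall the stopping rule until it is
    genuinely negligible).  ``n_restarts`` counts initializations: the first
    is all-ones, the rest are uniform on (0, 1]; the restart with the highest
    final log-likelihood wins.  ``eps_floor`` keeps the noise intensity
    positive so E-step denominators never vanish.  ``clip`` zeroes estimated
    probabilities below floating-point dust when assembling the complex.
    """

    tol: float = 1e-6
    max_iter: int = 500
    n_restarts: int = 3
    eps_floor: float = 1e-12
    rel_floor: float = 1e-8
    clip: float = 1e-9
    prune_floor: float = 1e-10
    guard_ratio: float = 0.5
    max_candidates: int = 30


@dataclass(frozen=True)
class CondEntry:
    """One empirical conditional: frequency ``p``, observation count
    (conditioning-event count) ``count``, and whether it is defined."""

    p: float
    count: int
    defined: bool = True


@dataclass
class EmpiricalConditionals:
    """Per-target conditional infection frequencies counted from the data.

    ``pair_cond[j]`` holds ``P_j^i``, the fraction of times the target was
    infected at ``t+1`` among times with target susceptible and ``j`` active
    at ``t``; ``triple_cond[(j, k)]`` holds the analogue conditioned on both
    ``j`` and ``k`` active.  Entries whose conditioning event never occurs
    are flagged undefined (``p = 0``, ``count = 0``), never NaN.
    """

    target: int
    pair_cond: Dict[int, CondEntry]
    triple_cond: Dict[Tuple[int, int], CondEntry]


@dataclass
class InferenceResult:
    """EM output for one target node: channel probabilities, noise level,
    log-likelihood trace of the winning restart, and bookkeeping."""

    target: int
    p_pair: Dict[int, float]
    p_triple: Dict[Tuple[int, int], float]
    epsilon: float
    loglik_trace: np.ndarray
    n_restarts_used: int
    n_iter: int = 0
    converged: bool = True


@dataclass(frozen=True)
class TruncationResult:
    """Outcome of the maximum-gap split of a descending value list.

    ``split_index`` is the 1-based count of values kept above the threshold;
    ``degenerate`` marks lists where no informative gap exists (fewer than
    two positive values, or all gap scores zero)."""

    sorted_values: np.ndarray
    split_index: int
    threshold: float
    degenerate: bool = False


@dataclass
class Reconstruction:
    """Full two-step reconstruction output.

    Iterable as ``(complex, node_results)`` for convenience."""

    complex: SimplicialComplex2
    node_results: Dict[int, InferenceResult]
    approximate_neighborhoods: Dict[int, Set[int]] = field(default_factory=dict)
    dropped_triangles: List[Tuple[int, int, int]] = field(default_factory=list)
    failed_nodes: List[int] = field(default_factory=list)

    def __iter__(self):
        return iter((self.complex, self.node_results))


# --------------------------------------------------------------------------
# empirical conditionals
# --------------------------------------------------------------------------


def _as_array(S) -> np.ndarray:
    values = S.values if isinstance(S, StateMatrix) else np.asarray(S)
    if isinstance(S, StateMatrix) and S.alphabet != "binary":
        raise ValueError("reconstruction requires a binary (0/1) state matrix")
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("state matrix must be T x N with T >= 2")
    if not np.isin(values, (0, 1)).all():
        raise ValueError("state matrix entries must be 0/1")
    return np.asarray(values, dtype=np.int8)


def empirical_conditionals(
    S,
    i: int,
    candidate_pairs: Optional[Iterable[Tuple[int, int]]] = None,
) -> EmpiricalConditionals:
    """Count the conditional infection frequencies for target node ``i``.

    Counts run over consecutive row pairs ``(t, t+1)`` restricted to rows
    with the target susceptible.  ``candidate_pairs`` limits the (otherwise
    quadratic) triple table to the given unordered source pairs.
    """
    A = _as_array(S)
    T, N = A.shape
    if not 0 <= i < N:
        raise ValueError(f"target {i} out of range for N={N}")
    mask = A[:-1, i] == 0
    Psi = A[:-1][mask].astype(np.float64)
    y = A[1:, i][mask].astype(np.float64)

    den = Psi.sum(axis=0)
    num = y @ Psi
    pair_cond: Dict[int, CondEntry] = {}
    for j in range(N):
        if j == i:
            continue
        if den[j] > 0:
            pair_cond[j] = CondEntry(p=float(num[j] / den[j]), count=int(den[j]))
        else:
            pair_cond[j] = CondEntry(p=0.0, count=0, defined=False)

    if candidate_pairs is None:
        pairs = [
            (j, k) for j, k in combinations(range(N), 2) if j != i and k != i
        ]
    else:
        pairs = []
        for j, k in candidate_pairs:
            if j == k or i in (j, k):
                raise ValueError(f"invalid source pair ({j}, {k}) for target {i}")
            pairs.append((j, k) if j < k else (k, j))
    triple_cond: Dict[Tuple[int, int], CondEntry] = {}
    for j, k in pairs:
        both = Psi[:, j] * Psi[:, k]
        d = both.sum()
        if d > 0:
            triple_cond[(j, k)] = CondEntry(p=float((y @ both) / d), count=int(d))
        else:
            triple_cond[(j, k)] = CondEntry(p=0.0, count=0, defined=False)
    return EmpiricalConditionals(target=i, pair_cond=pair_cond, triple_cond=triple_cond)


# --------------------------------------------------------------------------
# EM core
# --------------------------------------------------------------------------


@dataclass
class _EMRun:
    theta: np.ndarray
    epsilon: float
    trace: np.ndarray
    n_iter: int
    converged: bool


def _loglik(theta: np.ndarray, eps: np.ndarray, X1, d: np.ndarray, M: int) -> np.ndarray:
    """Poisson log-likelihood per restart column (constant terms dropped)."""
    D = X1 @ theta + eps
    with np.errstate(divide="ignore"):
        return np.log(D).sum(axis=0) - (theta * d[:, None]).sum(axis=0) - M * eps


_KKT_LEVEL = 1e-3


def _kkt_zero(
    theta: np.ndarray, eps: np.ndarray, X1: np.ndarray, d: np.ndarray, opts: EMOptions
) -> None:
    """Snap near-boundary channels whose MLE is exactly zero.

    The multiplicative update approaches the zero boundary only
    geometrically, so after finitely many iterations a channel that does not
    belong to the likelihood's support still carries positive dust.  The
    first-order condition decides: with the channel removed, if the partial
    derivative of the log-likelihood at zero weight,
    ``sum_events x_j / D_(-j) - d_j``, is non-positive, zero is optimal for
    that coordinate and the weight is set to exactly zero (in place).  Only
    small weights are tested; interactions between simultaneously removed
    dust channels are negligible at this scale.
    """
    for r in range(theta.shape[1]):
        th = theta[:, r]
        cand = np.flatnonzero((th > 0) & (th < _KKT_LEVEL))
        if cand.size == 0:
            continue
        D = X1 @ th + eps[r]
        Xc = X1[:, cand]
        D_minus = D[:, None] - Xc * th[cand][None, :]
        grad = (Xc / D_minus).sum(axis=0) - d[cand]
        th[cand[grad <= 0.0]] = 0.0


def _em_run(
    X: np.ndarray,
    y: np.ndarray,
    opts: EMOptions,
    rng: np.random.Generator,
) -> _EMRun:
    """Maximize the Poisson likelihood over channel weights and noise.

    ``X`` is the ``M x K`` matrix of channel intensities (conditional
    frequency times activity indicator) over the target-susceptible times;
    ``y`` the 0/1 outcome (target infected next).  Channels never active, or
    with undefined conditionals, must arrive as all-zero columns: they are
    frozen at zero and excluded from the iteration.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    M, K = X.shape
    d = X.sum(axis=0)
    active = d > 0
    theta_full = np.zeros(K, dtype=np.float64)

    events = y > 0
    n_ev = int(events.sum())
    if n_ev == 0:
        # every M-step numerator vanishes: one iteration lands on all zeros
        return _EMRun(
            theta=theta_full,
            epsilon=0.0,
            trace=np.array([-(d.sum() + 0.0)]),
            n_iter=1,
            converged=True,
        )

    X1 = np.ascontiguousarray(X[events][:, active])
    da = d[active]
    Ka = X1.shape[1]
    R = max(1, opts.n_restarts)

    theta = np.ones((Ka, R))
    eps = np.ones(R)
    if R > 1:
        theta[:, 1:] = 1.0 - rng.random((Ka, R - 1))  # uniform on (0, 1]
        eps[1:] = 1.0 - rng.random(R - 1)

    traces: List[List[float]] = [[] for _ in range(R)]
    conv_iter = np.full(R, -1, dtype=np.int64)
    for it in range(opts.max_iter):
        D = X1 @ theta + eps  # (n_ev, R)
        with np.errstate(divide="ignore"):
            ll = np.log(D).sum(axis=0) - (theta * da[:, None]).sum(axis=0) - M * eps
        for r in range(R):
            if conv_iter[r] < 0:
                traces[r].append(float(ll[r]))
        r_inv = 1.0 / D
        theta_new = theta * (X1.T @ r_inv) / da[:, None]
        eps_new = np.maximum(eps * r_inv.sum(axis=0) / M, opts.eps_floor)

        # a channel whose weight has decayed to negligibility is snapped to
        # the zero boundary; the multiplicative update then keeps it there,
        # so a slowly decaying channel cannot stall the stopping rule
        theta_new[theta_new < opts.prune_floor] = 0.0
        if it >= 50 and it % 25 == 0:
            _kkt_zero(theta_new, eps_new, X1, da, opts)

        rel_eps = np.abs(eps_new - eps) / np.maximum(eps, opts.rel_floor)
        if Ka:
            rel = np.abs(theta_new - theta) / np.maximum(theta, opts.rel_floor)
            delta = np.maximum(rel.max(axis=0), rel_eps)
        else:
            delta = rel_eps
        theta, eps = theta_new, eps_new
        newly = (delta < opts.tol) & (conv_iter < 0)
        conv_iter[newly] = it + 1
        if (conv_iter >= 0).all():
            break

    _kkt_zero(theta, eps, X1, da, opts)
    final_ll = _loglik(theta, eps, X1, da, M)
    for r in range(R):
        traces[r].append(float(final_ll[r]))
    best = int(np.argmax(final_ll))
    theta_full[active] = theta[:, best]
    n_iter = int(conv_iter[best]) if conv_iter[best] >= 0 else opts.max_iter
    return _EMRun(
        theta=theta_full,
        epsilon=float(eps[best]),
        trace=np.asarray(traces[best]),
        n_iter=n_iter,
        converged=bool(conv_iter[best] >= 0),
    )


def em_responsibilities(
    theta: np.ndarray, epsilon: float, X: np.ndarray
) -> np.ndarray:
    """E-step posterior attribution of events to channels (last column: noise).

    Rows are time steps; every row of the returned matrix sums to one, since
    all channels share the single Poisson-rate denominator.
    """
    X = np.asarray(X, dtype=np.float64)
    contrib = X * np.asarray(theta)[None, :]
    denom = contrib.sum(axis=1) + epsilon
    out = np.empty((X.shape[0], X.shape[1] + 1))
    out[:, :-1] = contrib / denom[:, None]
    out[:, -1] = epsilon / denom
    return out


# --------------------------------------------------------------------------
# public EM wrappers
# --------------------------------------------------------------------------


def _design_for_target(
    A: np.ndarray,
    i: int,
    pair_candidates: Sequence[int],
    triple_candidates: Sequence[Tuple[int, int]],
) -> Tuple[np.ndarray, np.ndarray]:
    """Build the (intensity matrix, outcome vector) pair for target ``i``."""
    mask = A[:-1, i] == 0
    Psi = A[:-1][mask].astype(np.float64)
    y = A[1:, i][mask].astype(np.float64)
    M = Psi.shape[0]

    cols: List[np.ndarray] = []
    if pair_candidates:
        P = Psi[:, list(pair_candidates)]
        den = P.sum(axis=0)
        num = y @ P
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(den > 0, num / np.maximum(den, 1.0), 0.0)
        cols.append(P * c[None, :])
    if triple_candidates:
        ja = np.array([j for j, _ in triple_candidates])
        ka = np.array([k for _, k in triple_candidates])
        PP = Psi[:, ja] * Psi[:, ka]
        den = PP.sum(axis=0)
        num = y @ PP
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(den > 0, num / np.maximum(den, 1.0), 0.0)
        cols.append(PP * c[None, :])
    X = np.hstack(cols) if cols else np.empty((M, 0))
    return X, y


def em_full(
    S,
    i: int,
    pair_candidates: Iterable[int],
    triple_candidates: Iterable[Tuple[int, int]] = (),
    opts: Optional[EMOptions] = None,
    rng: Optional[np.random.Generator] = None,
) -> InferenceResult:
    """Fit all channel probabilities for target ``i`` by EM.

    ``pair_candidates`` are candidate neighbors ``j``; ``triple_candidates``
    are unordered source pairs ``{j, k}``.  Channels whose conditional
    frequencies are undefined (conditioning event never observed) are frozen
    at zero.  Restarts use the all-ones initialization first, then uniform
    random ones; the restart with the highest final log-likelihood is
    returned.
    """
    opts = opts or EMOptions()
    rng = rng or np.random.default_rng(0)
    A = _as_array(S)
    N = A.shape[1]
    pairs = sorted(set(int(j) for j in pair_candidates))
    triples = sorted(
        set((j, k) if j < k else (k, j) for j, k in triple_candidates)
    )
    for j in pairs:
        if j == i or not 0 <= j < N:
            raise ValueError(f"invalid pair candidate {j} for target {i}")
    for j, k in triples:
        if i in (j, k) or j == k:
            raise ValueError(f"invalid triple candidate ({j}, {k}) for target {i}")

    X, y = _design_for_target(A, i, pairs, triples)
    run = _em_run(X, y, opts, rng)
    p_pair = {j: float(run.theta[a]) for a, j in enumerate(pairs)}
    off = len(pairs)
    p_triple = {jk: float(run.theta[off + a]) for a, jk in enumerate(triples)}
    return InferenceResult(
        target=i,
        p_pair=p_pair,
        p_triple=p_triple,
        epsilon=run.epsilon,
        loglik_trace=run.trace,
        n_restarts_used=opts.n_restarts,
        n_iter=run.n_iter,
        converged=run.converged,
    )


def em_first_step(
    S,
    i: int,
    opts: Optional[EMOptions] = None,
    rng: Optional[np.random.Generator] = None,
) -> InferenceResult:
    """First-pass EM ignoring three-body channels: all nodes ``j != i`` are
    pair candidates, no triples.  Used to rank approximate neighbors."""
    A = _as_array(S)
    N = A.shape[1]
    return em_full(A, i, [j for j in range(N) if j != i], (), opts=opts, rng=rng)


# --------------------------------------------------------------------------
# maximum-gap truncation
# --------------------------------------------------------------------------


def gap_threshold(values: Iterable[float]) -> TruncationResult:
    """Split a non-negative value list at its maximum ratio-weighted gap.

    Values are sorted in descending order; the split index ``l`` maximizes
    ``(P_l / P_{l+1}) * (P_l - P_{l+1})`` over positions with a positive
    successor, ties broken toward the smallest ``l``; the threshold is the
    midpoint of the winning gap.  Appending zeros never changes the result.
    With fewer than two positive values there is no gap to score and the
    degenerate result keeps every positive value (threshold 0).
    """
    vals = np.sort(np.asarray(list(values), dtype=np.float64))[::-1]
    if vals.size and vals[-1] < 0:
        raise ValueError("gap_threshold expects non-negative values")
    pos = vals[vals > 0]
    if pos.size < 2:
        return TruncationResult(
            sorted_values=vals,
            split_index=int(pos.size),
            threshold=0.0,
            degenerate=True,
        )
    upper, lower = pos[:-1], pos[1:]
    with np.errstate(over="ignore"):  # a gap onto a denormal scores inf
        scores = (upper / lower) * (upper - lower)
    l_star = int(np.argmax(scores)) + 1  # first max wins -> smallest l
    threshold = 0.5 * (pos[l_star - 1] + pos[l_star])
    return TruncationResult(
        sorted_values=vals,
        split_index=l_star,
        threshold=float(threshold),
        degenerate=bool(scores.max() == 0.0),
    )


def _guarded(threshold: float, positives: np.ndarray, guard_ratio: float) -> float:
    """Distrust a threshold that splits a cluster of comparable values.

    The maximum-gap score always proposes *some* split, even when the sorted
    values form one homogeneous cluster (as they do when the EM itself has
    already pushed every non-support channel to exactly zero).  If the
    largest discarded value is within ``1/guard_ratio`` of the smallest kept
    one the two are not separable on the multiplicative scale the gap score
    ranks, and the threshold is dropped (keep all positives)."""
    kept = positives[positives > threshold]
    below = positives[(positives > 0) & (positives <= threshold)]
    if kept.size and below.size and below.max() > guard_ratio * kept.min():
        return 0.0
    return threshold


def approximate_neighbors(
    first_step: InferenceResult, opts: Optional[EMOptions] = None
) -> Set[int]:
    """Approximate neighborhood from first-pass pair probabilities.

    A first maximum-gap threshold separates the dominant values; a second
    gap search on the values strictly below it yields a smaller, permissive
    threshold, so borderline true neighbors sitting just under the main gap
    are still retained.  A cut that would discard values comparable to the
    kept ones (a homogeneous cluster, typical once the EM has already zeroed
    every non-neighbor exactly) is distrusted and all positive values are
    kept instead.
    """
    opts = opts or EMOptions()
    items = sorted(first_step.p_pair.items(), key=lambda kv: -kv[1])
    vals = np.array([v for _, v in items], dtype=np.float64)
    if vals.size == 0 or vals.max() <= 0:
        return set()
    t1 = gap_threshold(vals)
    if t1.degenerate:
        return {j for j, v in items if v > 0}
    below = vals[vals < t1.threshold]
    t2 = gap_threshold(below)
    bar = 0.0 if t2.degenerate else t2.threshold
    bar = _guarded(bar, vals, opts.guard_ratio)
    return {j for j, v in items if v > bar}


# --------------------------------------------------------------------------
# two-step reconstruction
# --------------------------------------------------------------------------


def reconstruct(
    S,
    opts: Optional[EMOptions] = None,
    seed: int = 0,
) -> Reconstruction:
    """Reconstruct the full 2-simplicial complex from a binary state matrix.

    Per node: a first-step EM over all other columns ranks candidate
    neighbors; the maximum-gap truncation extracts the approximate
    neighborhood; a second EM restricted to those neighbors and all their
    unordered pairs yields the final probabilities.  An edge ``{i, j}`` is
    predicted when either directed probability is positive (after clipping
    numerical dust).  A triangle ``{i, j, k}`` is predicted when at least two
    of its three directed probabilities clear their per-target maximum-gap
    thresholds; predicted triangles not closed by predicted edges are
    dropped.

    Per-node EM failures are logged and leave that node's channels empty
    rather than aborting the run.
    """
    opts = opts or EMOptions()
    A = _as_array(S)
    T, N = A.shape
    rng = np.random.default_rng(seed)

    node_results: Dict[int, InferenceResult] = {}
    neighborhoods: Dict[int, Set[int]] = {}
    failed: List[int] = []
    for i in range(N):
        try:
            first = em_first_step(A, i, opts=opts, rng=rng)
            nbrs = approximate_neighbors(first, opts=opts)
            if len(nbrs) > opts.max_candidates:
                # keep the strongest-ranked candidates tractable; only binds
                # in heavily noisy regimes where the truncation cannot
                # separate a neighbor cluster
                nbrs = set(
                    sorted(nbrs, key=lambda j: -first.p_pair[j])[: opts.max_candidates]
                )
            neighborhoods[i] = nbrs
            cand = sorted(nbrs)
            triple_cand = list(combinations(cand, 2))
            node_results[i] = em_full(
                A, i, cand, triple_cand, opts=opts, rng=rng
            )
        except Exception:  # pragma: no cover - defensive
            logger.exception("EM failed for target node %d", i)
            failed.append(i)
            neighborhoods.setdefault(i, set())
            node_results[i] = InferenceResult(
                target=i,
                p_pair={},
                p_triple={},
                epsilon=0.0,
                loglik_trace=np.array([]),
                n_restarts_used=opts.n_restarts,
                converged=False,
            )

    clip = opts.clip
    # edges: OR rule on strict positivity of the directed probabilities
    edges: Set[Tuple[int, int]] = set()
    for i, res in node_results.items():
        for j, v in res.p_pair.items():
            if v > clip:
                edges.add((i, j) if i < j else (j, i))

    # triangles: per-target gap threshold and the 2-of-3 vote
    thresholds: Dict[int, float] = {}
    for i, res in node_results.items():
        vals = np.array([v for v in res.p_triple.values() if v > clip])
        if vals.size:
            thresholds[i] = _guarded(
                gap_threshold(vals).threshold, vals, opts.guard_ratio
            )
        else:
            thresholds[i] = 0.0
    votes: Dict[Tuple[int, int, int], int] = {}
    for i, res in node_results.items():
        for (j, k), v in res.p_triple.items():
            if v > clip and v >= thresholds[i]:
                t = tuple(sorted((i, j, k)))
                votes[t] = votes.get(t, 0) + 1
    triangles: Set[Tuple[int, int, int]] = set()
    dropped: List[Tuple[int, int, int]] = []
    for t, n_votes in votes.items():
        if n_votes < 2:
            continue
        u, v, w = t
        if {(u, v), (u, w), (v, w)} <= edges:
            triangles.add(t)
        else:
            dropped.append(t)
            logger.info("dropped open triangle %s (missing predicted edge)", t)

    predicted = SimplicialComplex2(
        n_nodes=N, edges=frozenset(edges), triangles=frozenset(triangles)
    )
    return Reconstruction(
        complex=predicted,
        node_results=node_results,
        approximate_neighborhoods=neighborhoods,
        dropped_triangles=dropped,
        failed_nodes=failed,
    )
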