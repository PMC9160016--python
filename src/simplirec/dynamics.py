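"""Forward simulators for binary dynamics on 2-simplicial complexes.

Two discrete-time processes are implemented, both recording the full state
of every node at every step into a ``T x N`` state matrix:

* :func:`simulate_contagion` -- SIS-type simplicial contagion: a susceptible
  node is infected through each edge to an infected neighbor with
  probability ``beta1`` and through each incident triangle whose two other
  members are both infected with probability ``beta2`` (synergistic
  reinforcement); infected nodes recover with probability ``mu``.
* :func:`simulate_ising` -- spin dynamics under a Hamiltonian
  ``H = -J1 sum_(i,j) S_i S_j - J2 sum_(i,j,k) S_i S_j S_k`` with heat-bath
  flip probability ``1 / (1 + exp(delta * dE))`` at inverse temperature
  ``delta``.

Updates are synchronous by default: every node draws its transition from the
time-``t`` configuration.  An asynchronous (single-spin Glauber) variant of
the Ising dynamics is available via ``update="asynchronous"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .complexes import SimplicialComplex2

__all__ = [
    "ContagionParams",
    "IsingParams",
    "StateMatrix",
    "simulate_contagion",
    "simulate_ising",
    "contagion_step",
]

ALPHABETS = {"binary": (0, 1), "spin": (-1, 1)}


@dataclass
class StateMatrix:
    """A ``T x N`` record of nodal states, one row per time step.

    ``alphabet`` is ``"binary"`` (0/1, contagion) or ``"spin"`` (-1/+1,
    Ising).  ``meta`` carries run diagnostics such as reseeding events.
    """

    values: np.ndarray
    alphabet: str = "binary"
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("state matrix must be two-dimensional (T x N)")
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = ALPHABETS[self.alphabet]
        if not np.isin(self.values, allowed).all():
            raise ValueError(f"entries outside alphabet {allowed}")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ContagionParams:
    """Simplicial-contagion parameters.

    The per-channel infection probabilities are ``beta1 = alpha / k1`` and
    ``beta2 = omega / k2`` where ``k1``, ``k2`` are the realized mean two- and
    three-body degrees of the simulated complex; set ``beta1``/``beta2``
    directly to bypass the rescaling.  ``mu`` is the recovery probability,
    ``rho0`` the initially infected fraction, ``T`` the number of recorded
    rows.
    """

    alpha: float = 0.8
    omega: float = 2.4
    mu: float = 1.0
    rho0: float = 0.2
    T: int = 10000
    seed: int = 0
    beta1: Optional[float] = None
    beta2: Optional[float] = None


@dataclass(frozen=True)
class IsingParams:
    """Simplicial Ising parameters: couplings ``J1`` (edges), ``J2``
    (triangles) and inverse temperature ``delta``."""

    J1: float = 1.0
    J2: float = 0.0
    delta: float = 1.0
    T: int = 10000
    seed: int = 0


def _resolve_betas(complex: SimplicialComplex2, params: ContagionParams) -> tuple:
    if params.beta1 is not None:
        beta1 = params.beta1
    else:
        k1 = complex.k1
        if k1 <= 0 and params.alpha > 0:
            raise ValueError("complex has no edges; pass beta1 explicitly")
        beta1 = params.alpha / k1 if k1 > 0 else 0.0
    if params.beta2 is not None:
        beta2 = params.beta2
    else:
        k2 = complex.k2
        beta2 = params.omega / k2 if k2 > 0 else 0.0
    if beta1 < 0 or beta2 < 0:
        raise ValueError(f"negative infection rate (beta1={beta1}, beta2={beta2})")
    if not 0.0 <= params.mu <= 1.0:
        raise ValueError(f"mu={params.mu} outside [0, 1]")
    # the rescaled rates alpha/k1, omega/k2 can exceed 1 for sparse
    # three-body degrees; a Bernoulli draw against such a rate is certain,
    # so the per-channel probability saturates at 1
    return min(beta1, 1.0), min(beta2, 1.0)


def _triangle_pressure(tri: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Per-node count of incident triangles whose two other members are
    active, given 0/1 state vector ``s``."""
    b = np.zeros(s.shape[0], dtype=np.int64)
    if tri.shape[0]:
        sv = s[tri]  # (n_tri, 3)
        np.add.at(b, tri[:, 0], sv[:, 1] * sv[:, 2])
        np.add.at(b, tri[:, 1], sv[:, 0] * sv[:, 2])
        np.add.at(b, tri[:, 2], sv[:, 0] * sv[:, 1])
    return b


def contagion_step(
    s: np.ndarray,
    adjacency: np.ndarray,
    triangles: np.ndarray,
    beta1: float,
    beta2: float,
    mu: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous update of the simplicial contagion.

    A susceptible node with ``a`` infected neighbors and ``b`` fully infected
    incident triangles is infected with probability
    ``1 - (1 - beta1)**a * (1 - beta2)**b`` (independent channels); an
    infected node recovers with probability ``mu``.  Infection and recovery
    are both evaluated from the time-``t`` snapshot, so a node infected at
    this step cannot recover within it.
    """
    s = np.asarray(s, dtype=np.int8)
    a = adjacency @ s
    b = _triangle_pressure(triangles, s)
    p_inf = 1.0 - (1.0 - beta1) ** a * (1.0 - beta2) ** b
    infect = (s == 0) & (rng.random(s.shape[0]) < p_inf)
    recover = (s == 1) & (rng.random(s.shape[0]) < mu)
    out = s.copy()
    out[recover] = 0
    out[infect] = 1
    return out


def simulate_contagion(
    complex: SimplicialComplex2,
    params: ContagionParams,
    reseed_on_extinction: bool = False,
) -> StateMatrix:
    """Simulate SIS-type simplicial contagion and record ``T`` rows.

    Row 0 contains ``floor(rho0 * N)`` infected nodes drawn uniformly.  With
    ``reseed_on_extinction`` the epidemic is re-initialized whenever the
    infected set empties (near-threshold parameters with ``mu = 1`` make
    extinction common); each reseeding step index is recorded in
    ``meta["reseed_steps"]``.  Without it an extinct epidemic simply leaves
    the remaining rows all-zero.
    """
    n = complex.n_nodes
    if n == 0 or params.T < 1:
        raise ValueError("empty complex or non-positive T")
    beta1, beta2 = _resolve_betas(complex, params)
    n0 = int(params.rho0 * n)
    if n0 < 1:
        raise ValueError(f"rho0={params.rho0} seeds no infected node at N={n}")
    rng = np.random.default_rng(params.seed)
    adj = complex.adjacency()
    tri = complex.triangle_array()

    def seed_state() -> np.ndarray:
        s = np.zeros(n, dtype=np.int8)
        s[rng.choice(n, size=n0, replace=False)] = 1
        return s

    rows = np.zeros((params.T, n), dtype=np.int8)
    reseeds: List[int] = []
    s = seed_state()
    rows[0] = s
    for t in range(1, params.T):
        if reseed_on_extinction and s.sum() == 0:
            # the extinct (all-zero) row stays in the record: re-seeded
            # infections then follow a row with no active channel at all,
            # so they cannot be mistaken for network-mediated transmission
            s = seed_state()
            reseeds.append(t)
        else:
            s = contagion_step(s, adj, tri, beta1, beta2, params.mu, rng)
        rows[t] = s
    meta = {
        "beta1": beta1,
        "beta2": beta2,
        "mu": params.mu,
        "reseed_steps": reseeds,
    }
    return StateMatrix(values=rows, alphabet="binary", meta=meta)


def _ising_delta_e(
    s: np.ndarray, adjacency: np.ndarray, tri: np.ndarray, J1: float, J2: float
) -> np.ndarray:
    """Energy change of flipping each spin, from the current configuration:
    ``dE_i = 2 J1 sum_{(i,j)} S_i S_j + 2 J2 sum_{(i,j,k)} S_i S_j S_k``."""
    pair = s * (adjacency @ s)
    tri_field = np.zeros(s.shape[0], dtype=np.float64)
    if tri.shape[0]:
        sv = s[tri]
        prod = sv[:, 0] * sv[:, 1] * sv[:, 2]
        np.add.at(tri_field, tri[:, 0], prod)
        np.add.at(tri_field, tri[:, 1], prod)
        np.add.at(tri_field, tri[:, 2], prod)
    return 2.0 * J1 * pair + 2.0 * J2 * tri_field


def simulate_ising(
    complex: SimplicialComplex2,
    params: IsingParams,
    update: str = "synchronous",
) -> StateMatrix:
    """Simulate simplicial Ising dynamics and record ``T`` rows of +-1 spins.

    Row 0 assigns each spin +-1 with equal probability.  Under the default
    synchronous update every node flips independently with probability
    ``1 / (1 + exp(delta * dE_i))`` computed from the time-``t``
    configuration.  ``update="asynchronous"`` instead performs ``N``
    sequential single-spin Glauber updates (uniformly chosen nodes) per
    recorded row.
    """
    if update not in ("synchronous", "asynchronous"):
        raise ValueError(f"unknown update scheme {update!r}")
    n = complex.n_nodes
    if n == 0 or params.T < 1:
        raise ValueError("empty complex or non-positive T")
    rng = np.random.default_rng(params.seed)
    adj = complex.adjacency().astype(np.float64)
    tri = complex.triangle_array()
    s = rng.choice(np.array([-1, 1], dtype=np.int8), size=n)
    rows = np.zeros((params.T, n), dtype=np.int8)
    rows[0] = s
    for t in range(1, params.T):
        if update == "synchronous":
            de = _ising_delta_e(s.astype(np.float64), adj, tri, params.J1, params.J2)
            flip = rng.random(n) < 1.0 / (1.0 + np.exp(params.delta * de))
            s = np.where(flip, -s, s).astype(np.int8)
        else:
            for i in rng.integers(0, n, size=n):
                de_i = _ising_delta_e(
                    s.astype(np.float64), adj, tri, params.J1, params.J2
                )[i]
                if rng.random() < 1.0 / (1.0 + np.exp(params.delta * de_i)):
                    s[i] = -s[i]
        rows[t] = s
    return StateMatrix(values=rows, alphabet="spin", meta={})
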