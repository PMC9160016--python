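"""File formats and the real-world contact-stream builder.

A complex is stored as three plain-text files sharing a prefix: an edge list
(two tab-separated 0-based columns, ``u < v``), a triangle list (three
columns, ``u < v < w``) and a one-line header recording the node count.
State matrices are stored either as headerless integer CSV (rows = time) or
as a compressed ``.npz`` container carrying the alphabet.  Contact-event
streams are 3-column TSV (``seconds  u  v``), the ordering used by
face-to-face proximity datasets recorded at 20-second resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .complexes import SimplicialComplex2
from .dynamics import StateMatrix
from .inference import InferenceResult

logger = logging.getLogger(__name__)

__all__ = [
    "ContactEventStream",
    "write_complex",
    "read_complex",
    "write_state_matrix",
    "read_state_matrix",
    "write_probability_tables",
    "write_results_table",
    "read_results_table",
    "read_contact_stream",
    "write_contact_stream",
    "build_complex_from_contacts",
]


def _paths(prefix) -> Tuple[Path, Path, Path]:
    p = Path(prefix)
    return (
        p.with_name(p.name + "_header.txt"),
        p.with_name(p.name + "_edges.tsv"),
        p.with_name(p.name + "_triangles.tsv"),
    )


def write_complex(complex: SimplicialComplex2, prefix) -> None:
    """Write a complex as ``<prefix>_header.txt`` / ``_edges.tsv`` /
    ``_triangles.tsv``."""
    header, edges, triangles = _paths(prefix)
    header.write_text(f"{complex.n_nodes}\n")
    with edges.open("w") as fh:
        for u, v in sorted(complex.edges):
            fh.write(f"{u}\t{v}\n")
    with triangles.open("w") as fh:
        for u, v, w in sorted(complex.triangles):
            fh.write(f"{u}\t{v}\t{w}\n")


def _parse_rows(path: Path, width: int) -> List[Tuple[int, ...]]:
    rows: List[Tuple[int, ...]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != width:
                raise ValueError(
                    f"{path}:{lineno}: expected {width} tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                rows.append(tuple(int(p) for p in parts))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field") from exc
    return rows


def read_complex(prefix, on_closure_violation: str = "error") -> SimplicialComplex2:
    """Load a complex written by :func:`write_complex`.

    ``on_closure_violation`` is ``"error"`` (strict: raise, naming the
    offending triple) or ``"drop"`` (discard open triangles with a warning).
    """
    if on_closure_violation not in ("error", "drop"):
        raise ValueError("on_closure_violation must be 'error' or 'drop'")
    header, edges_path, triangles_path = _paths(prefix)
    n_nodes = int(header.read_text().strip())
    edges = set()
    for lineno, (u, v) in enumerate(_parse_rows(edges_path, 2), start=1):
        if not 0 <= u < v < n_nodes:
            raise ValueError(
                f"{edges_path}:{lineno}: edge ({u}, {v}) out of range or unordered"
            )
        edges.add((u, v))
    triangles = set()
    for lineno, (u, v, w) in enumerate(_parse_rows(triangles_path, 3), start=1):
        if not 0 <= u < v < w < n_nodes:
            raise ValueError(
                f"{triangles_path}:{lineno}: triangle ({u}, {v}, {w}) "
                f"out of range or unordered"
            )
        missing = [e for e in combinations((u, v, w), 2) if e not in edges]
        if missing:
            if on_closure_violation == "error":
                raise ValueError(
                    f"{triangles_path}:{lineno}: triangle ({u}, {v}, {w}) "
                    f"violates closure (missing edge {missing[0]})"
                )
            logger.warning("dropping open triangle (%d, %d, %d)", u, v, w)
            continue
        triangles.add((u, v, w))
    return SimplicialComplex2(
        n_nodes=n_nodes, edges=frozenset(edges), triangles=frozenset(triangles)
    )


def write_state_matrix(S: StateMatrix, path) -> None:
    """Write a state matrix as headerless CSV (``.csv``) or compressed
    binary with alphabet metadata (``.npz``), chosen by extension."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, values=S.values, alphabet=np.array(S.alphabet))
    else:
        np.savetxt(path, S.values, fmt="%d", delimiter=",")


def read_state_matrix(path, alphabet: str = "binary") -> StateMatrix:
    """Read a state matrix written by :func:`write_state_matrix`.  For CSV
    input the alphabet is not stored in the file and must be supplied."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            return StateMatrix(
                values=data["values"], alphabet=str(data["alphabet"])
            )
    values = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    return StateMatrix(values=values, alphabet=alphabet)


def write_probability_tables(results: Dict[int, InferenceResult], prefix) -> None:
    """Write per-node channel probabilities as two TSV tables
    (``<prefix>_pair_probs.tsv``, ``<prefix>_triple_probs.tsv``)."""
    p = Path(prefix)
    pair_path = p.with_name(p.name + "_pair_probs.tsv")
    triple_path = p.with_name(p.name + "_triple_probs.tsv")
    with pair_path.open("w") as fh:
        fh.write("target\tsource\tprobability\n")
        for i in sorted(results):
            for j, v in sorted(results[i].p_pair.items()):
                fh.write(f"{i}\t{j}\t{v:.12g}\n")
    with triple_path.open("w") as fh:
        fh.write("target\tsource_j\tsource_k\tprobability\n")
        for i in sorted(results):
            for (j, k), v in sorted(results[i].p_triple.items()):
                fh.write(f"{i}\t{j}\t{k}\t{v:.12g}\n")


def write_results_table(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --------------------------------------------------------------------------
# contact streams
# --------------------------------------------------------------------------


@dataclass
class ContactEventStream:
    """Timestamped face-to-face contact events ``(seconds, u, v)``."""

    times: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.u = np.asarray(self.u, dtype=np.int64)
        self.v = np.asarray(self.v, dtype=np.int64)
        if not (self.times.shape == self.u.shape == self.v.shape):
            raise ValueError("times, u, v must have equal length")
        if (self.u == self.v).any():
            raise ValueError("self-contact records are not allowed")
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.u = self.u[order]
        self.v = self.v[order]

    def __len__(self) -> int:
        return self.times.size


def read_contact_stream(path) -> ContactEventStream:
    """Read a 3-column TSV contact stream (``seconds  u  v``)."""
    rows = _parse_rows(Path(path), 3)
    if not rows:
        raise ValueError(f"{path}: empty contact stream")
    arr = np.array(rows, dtype=np.int64)
    return ContactEventStream(times=arr[:, 0], u=arr[:, 1], v=arr[:, 2])


def write_contact_stream(stream: ContactEventStream, path) -> None:
    with Path(path).open("w") as fh:
        for t, u, v in zip(stream.times, stream.u, stream.v):
            fh.write(f"{t}\t{u}\t{v}\n")


def build_complex_from_contacts(
    stream: ContactEventStream,
    zeta: int,
    window_s: int = 300,
    keep_frac: float = 0.5,
) -> SimplicialComplex2:
    """Construct a 2-simplicial complex from a face-to-face contact stream.

    Edges are node pairs whose total contact count over the whole stream
    reaches the threshold ``zeta``.  Candidate triangles are node triples
    whose three pairwise contacts all occur within the same ``window_s``
    time window (windows are consecutive bins of the raw clock); their
    occurrences are counted over all windows, and the top ``keep_frac``
    fraction by total frequency is retained, keeping every triangle tied
    with the cutoff frequency.  Kept triangles lacking a surviving edge are
    dropped to enforce closure.
    """
    if len(stream) == 0:
        raise ValueError("empty contact stream")
    if zeta < 0 or window_s <= 0 or not 0.0 <= keep_frac <= 1.0:
        raise ValueError("invalid zeta, window_s or keep_frac")
    n_nodes = int(max(stream.u.max(), stream.v.max())) + 1

    # 1-2) pair weights over the whole stream, thresholded at zeta
    weights: Dict[Tuple[int, int], int] = {}
    lo = np.minimum(stream.u, stream.v)
    hi = np.maximum(stream.u, stream.v)
    for a, b in zip(lo, hi):
        weights[(int(a), int(b))] = weights.get((int(a), int(b)), 0) + 1
    edges = {pair for pair, w in weights.items() if w >= zeta}
    if not edges:
        logger.warning("threshold zeta=%d removed every edge", zeta)

    # 3) per-window triangle occurrences
    bins = stream.times // window_s
    tri_counts: Dict[Tuple[int, int, int], int] = {}
    for b in np.unique(bins):
        in_win = bins == b
        adj: Dict[int, set] = {}
        for a, c in zip(lo[in_win], hi[in_win]):
            adj.setdefault(int(a), set()).add(int(c))
            adj.setdefault(int(c), set()).add(int(a))
        for u in sorted(adj):
            nbrs = sorted(x for x in adj[u] if x > u)
            for v_, w_ in combinations(nbrs, 2):
                if w_ in adj[v_]:
                    t = (u, v_, w_)
                    tri_counts[t] = tri_counts.get(t, 0) + 1

    # 4) keep the top fraction by frequency, ties included
    ranked = sorted(tri_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    n_keep = int(keep_frac * len(ranked))
    if 0 < n_keep < len(ranked):
        cutoff = ranked[n_keep - 1][1]
        kept = [t for t, c in ranked if c >= cutoff]
    elif n_keep >= len(ranked):
        kept = [t for t, _ in ranked]
    else:
        kept = []

    # 5) closure: drop kept triangles lacking a surviving edge
    triangles = set()
    for u, v_, w_ in kept:
        if {(u, v_), (u, w_), (v_, w_)} <= edges:
            triangles.add((u, v_, w_))
        else:
            logger.info("dropping open contact triangle (%d, %d, %d)", u, v_, w_)
    return SimplicialComplex2(
        n_nodes=n_nodes, edges=frozenset(edges), triangles=frozenset(triangles)
    )
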