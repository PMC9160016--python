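"""Scoring reconstructions and robustness experiments.

Reconstruction accuracy is quantified by precision, recall and the F1 score
over all unordered node pairs (edges) or triples (triangles): a connection
present in the ground truth is a positive, every other pair/triple a
negative.  :func:`flip_states` implements the stochastic-perturbation
protocol (flip a fraction ``f`` of the active entries of the state matrix
and the same number of inactive ones, conserving the total activity), and
:func:`run_experiment` drives generate -> simulate -> (flip) -> reconstruct
-> score sweeps over a grid of series lengths or flip fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import comb
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .complexes import GeneratorParams, SimplicialComplex2, generate_ersc, generate_sfsc, generate_swsc
from .dynamics import ContagionParams, StateMatrix, simulate_contagion
from .inference import EMOptions, reconstruct

logger = logging.getLogger(__name__)

__all__ = [
    "ReconstructionMetrics",
    "ExperimentConfig",
    "score",
    "flip_states",
    "run_experiment",
    "summarize_results",
]

GENERATORS = {
    "ersc": generate_ersc,
    "sfsc": generate_sfsc,
    "swsc": generate_swsc,
}


@dataclass(frozen=True)
class ReconstructionMetrics:
    """Confusion counts and derived scores for one connection class."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float
    class_mode: str


def score(
    truth: SimplicialComplex2,
    predicted: SimplicialComplex2,
    class_mode: str = "edges",
) -> ReconstructionMetrics:
    """Score a predicted complex against the ground truth.

    ``class_mode`` selects edges (all unordered pairs as candidates) or
    triangles (all unordered triples).  Precision and recall are zero when
    their denominators vanish, except for the exact empty-vs-empty match,
    which is a perfect reconstruction (F1 = 1).
    """
    if truth.n_nodes != predicted.n_nodes:
        raise ValueError(
            f"node-count mismatch: truth {truth.n_nodes}, predicted {predicted.n_nodes}"
        )
    n = truth.n_nodes
    if class_mode == "edges":
        t, p = set(truth.edges), set(predicted.edges)
        universe = comb(n, 2)
    elif class_mode == "triangles":
        t, p = set(truth.triangles), set(predicted.triangles)
        universe = comb(n, 3)
    else:
        raise ValueError(f"unknown class_mode {class_mode!r}")
    tp = len(t & p)
    fp = len(p - t)
    fn = len(t - p)
    tn = universe - tp - fp - fn
    if not t and not p:
        precision = recall = f1 = 1.0
    else:
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return ReconstructionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        precision=precision, recall=recall, f1=f1, class_mode=class_mode,
    )


def flip_states(S: StateMatrix, f: float, seed: int = 0) -> StateMatrix:
    """Randomly flip a fraction ``f`` of the active (1) entries and the same
    number of inactive (0) entries, preserving the total number of ones.

    The flip count is ``floor(f * #ones)``, drawn uniformly over the whole
    matrix.  Raises if the matrix holds too few zero entries to match.
    """
    if isinstance(S, StateMatrix):
        if S.alphabet != "binary":
            raise ValueError("flip_states requires a binary state matrix")
        values = S.values
    else:
        values = np.asarray(S, dtype=np.int8)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"flip fraction f={f} outside [0, 1]")
    flat = values.ravel().copy()
    ones = np.flatnonzero(flat == 1)
    zeros = np.flatnonzero(flat == 0)
    n_flip = int(f * ones.size)
    if n_flip > zeros.size:
        raise ValueError(
            f"cannot flip {n_flip} susceptible entries: only {zeros.size} available"
        )
    rng = np.random.default_rng(seed)
    if n_flip:
        flat[rng.choice(ones, size=n_flip, replace=False)] = 0
        flat[rng.choice(zeros, size=n_flip, replace=False)] = 1
    out = flat.reshape(values.shape)
    meta = dict(S.meta) if isinstance(S, StateMatrix) else {}
    meta["flipped_fraction"] = f
    meta["flipped_count"] = n_flip
    return StateMatrix(values=out, alphabet="binary", meta=meta)


@dataclass(frozen=True)
class ExperimentConfig:
    """One sweep: a generator, contagion parameters, a grid over the series
    length ``T`` or the flip fraction ``f``, and a list of seeds."""

    generator: str
    generator_params: GeneratorParams
    contagion_params: ContagionParams
    grid_name: str  # "T" or "f"
    grid_values: Sequence[float]
    seeds: Sequence[int] = (0, 1, 2, 3, 4)
    flip_fraction: float = 0.0  # fixed f when sweeping T
    em_options: EMOptions = field(default_factory=EMOptions)
    reseed_on_extinction: bool = True


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run a full sweep and return a tidy results table.

    Each row holds one (grid value, seed, class mode) cell with its F1,
    precision and recall.  Per-cell failures are recorded in the ``error``
    column and do not stop the sweep.
    """
    if config.generator not in GENERATORS:
        raise ValueError(f"unknown generator {config.generator!r}")
    if config.grid_name not in ("T", "f"):
        raise ValueError("grid_name must be 'T' or 'f'")
    gen = GENERATORS[config.generator]
    rows: List[Dict] = []
    for value in config.grid_values:
        for seed in config.seeds:
            cell = {
                "grid_name": config.grid_name,
                "grid_value": value,
                "seed": seed,
            }
            try:
                gp = replace(config.generator_params, seed=seed)
                truth = gen(gp)
                cp = replace(config.contagion_params, seed=seed + 1)
                f = config.flip_fraction
                if config.grid_name == "T":
                    cp = replace(cp, T=int(value))
                else:
                    f = float(value)
                S = simulate_contagion(
                    truth, cp, reseed_on_extinction=config.reseed_on_extinction
                )
                if f > 0:
                    S = flip_states(S, f, seed=seed + 2)
                rec = reconstruct(S, opts=config.em_options, seed=seed + 3)
                for mode in ("edges", "triangles"):
                    m = score(truth, rec.complex, mode)
                    rows.append(
                        {
                            **cell,
                            "class_mode": mode,
                            "f1": m.f1,
                            "precision": m.precision,
                            "recall": m.recall,
                            "error": "",
                        }
                    )
            except Exception as exc:
                logger.exception(
                    "experiment cell failed (%s=%s, seed=%d)",
                    config.grid_name, value, seed,
                )
                rows.append(
                    {**cell, "class_mode": "", "f1": np.nan,
                     "precision": np.nan, "recall": np.nan, "error": str(exc)}
                )
    return pd.DataFrame(rows)


def summarize_results(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of the scores per grid point and class."""
    ok = results[results["error"] == ""]
    return (
        ok.groupby(["grid_name", "grid_value", "class_mode"])[["f1", "precision", "recall"]]
        .agg(["mean", "std"])
        .reset_index()
    )


def plot_f1(results: pd.DataFrame, ax=None):
    """Minimal F1-vs-grid plot (one line per connection class)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    summary = summarize_results(results)
    for mode, sub in summary.groupby("class_mode"):
        ax.errorbar(
            sub["grid_value"], sub[("f1", "mean")], yerr=sub[("f1", "std")],
            marker="o", label=mode,
        )
    ax.set_xlabel(summary["grid_name"].iloc[0] if len(summary) else "grid")
    ax.set_ylabel("F1")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax
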