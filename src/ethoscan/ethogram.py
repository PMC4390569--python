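"""Edge-weighted ethograms from condensed behavior sequences.

A first-order Markov view of courtship: for each male the 5x5 matrix of
transition counts between condensed categories A-E at successive scans is
normalized by the TOTAL number of transitions (sequence length - 1), so the
25 entries of every individual's matrix sum to 1. These joint transition
probabilities - not row-conditional ones - are the 25 phenotypes analyzed
downstream; a row-conditional view is available for inspection and
simulation. Scan sampling misses bouts shorter than the 30-s scan interval,
so observed transition frequencies are a lower bound; no imputation is done.

Cells never visited get probability 0 (no pseudocounts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .observations import CATEGORIES, ObservationTable

__all__ = [
    "TransitionMatrix",
    "count_transitions",
    "transition_probabilities",
    "line_mean_matrix",
    "transition_table",
    "line_mean_table",
    "phenotype_names",
    "to_graph",
    "export_dot",
    "export_graphml",
]

_IDX = {c: i for i, c in enumerate(CATEGORIES)}
K = len(CATEGORIES)


def phenotype_names() -> list[str]:
    """The 25 transition phenotype names 'A_A' ... 'E_E' (row-major)."""
    return [f"{a}_{b}" for a in CATEGORIES for b in CATEGORIES]


@dataclass
class TransitionMatrix:
    """Per-individual transition counts and joint probabilities."""

    counts: np.ndarray  # (5, 5) int
    n_transitions: int

    @property
    def probs(self) -> np.ndarray:
        """Joint transition probabilities; all 25 entries sum to 1."""
        if self.n_transitions < 1:
            raise ValueError("no transitions to normalize")
        return self.counts / float(self.n_transitions)

    def conditional(self, fallback_self_loop: bool = True) -> np.ndarray:
        """Row-stochastic view: P(next | current).

        Rows with zero observations get a self-loop when
        ``fallback_self_loop``, else raise.
        """
        out = np.zeros((K, K))
        rowsum = self.counts.sum(axis=1)
        for i in range(K):
            if rowsum[i] > 0:
                out[i] = self.counts[i] / rowsum[i]
            elif fallback_self_loop:
                out[i, i] = 1.0
            else:
                raise ValueError(f"state {CATEGORIES[i]} never observed")
        return out

    def flat(self) -> np.ndarray:
        """Row-major 25-vector of joint probabilities."""
        return self.probs.ravel()


def count_transitions(condensed_seq: Sequence[str]) -> TransitionMatrix:
    """Count successive-scan transitions in a condensed category sequence."""
    seq = list(condensed_seq)
    if len(seq) < 2:
        raise ValueError("need at least 2 observations to count transitions")
    counts = np.zeros((K, K), dtype=int)
    for a, b in zip(seq[:-1], seq[1:]):
        counts[_IDX[a], _IDX[b]] += 1
    return TransitionMatrix(counts=counts, n_transitions=len(seq) - 1)


def transition_probabilities(tm: TransitionMatrix) -> np.ndarray:
    """Joint probabilities (counts / total transitions); sums to 1."""
    return tm.probs


def line_mean_matrix(matrices: Iterable[TransitionMatrix]) -> np.ndarray:
    """Unweighted mean of individual joint-probability matrices.

    Each individual matrix sums to 1, so the line mean does too.
    """
    probs = [m.probs for m in matrices]
    if not probs:
        raise ValueError("line has no males")
    return np.mean(probs, axis=0)


def transition_table(obs: ObservationTable) -> pd.DataFrame:
    """Per-male wide table of the 25 joint transition probabilities.

    Index: (line, block, trial, arena, male); columns 'A_A'...'E_E'.
    """
    rows, index = [], []
    for m in obs:
        tm = count_transitions(m.condensed_seq)
        rows.append(tm.flat())
        index.append(m.key)
    idx = pd.MultiIndex.from_tuples(
        index, names=["line", "block", "trial", "arena", "male"]
    )
    return pd.DataFrame(rows, index=idx, columns=phenotype_names())


def line_mean_table(per_male: pd.DataFrame) -> pd.DataFrame:
    """Per-line means of the 25 transition phenotypes (lines x 25)."""
    return per_male.groupby(level="line").mean()


def to_graph(probs: np.ndarray, min_edge: float = 0.0) -> nx.DiGraph:
    """Directed graph over A-E with probability edge weights.

    Edges with weight < ``min_edge`` are omitted. Node and edge insertion
    order is deterministic (row-major over categories).
    """
    g = nx.DiGraph()
    g.add_nodes_from(CATEGORIES)
    for i, a in enumerate(CATEGORIES):
        for j, b in enumerate(CATEGORIES):
            w = float(probs[i, j])
            if w >= min_edge and w > 0.0:
                g.add_edge(a, b, weight=w)
    return g


def export_dot(
    probs: np.ndarray, path, min_edge: float = 0.0, scale: float = 10.0
) -> None:
    """Write a GraphViz DOT ethogram; edge penwidth = scale x probability."""
    lines = ["digraph ethogram {"]
    for c in CATEGORIES:
        lines.append(f'  {c} [shape=circle];')
    for i, a in enumerate(CATEGORIES):
        for j, b in enumerate(CATEGORIES):
            w = float(probs[i, j])
            if w >= min_edge and w > 0.0:
                lines.append(
                    f'  {a} -> {b} [weight={w:.6f}, '
                    f'penwidth={scale * w:.4f}, label="{w:.3f}"];'
                )
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def export_graphml(probs: np.ndarray, path, min_edge: float = 0.0) -> None:
    """Write the ethogram as GraphML via networkx."""
    nx.write_graphml(to_graph(probs, min_edge=min_edge), path)
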