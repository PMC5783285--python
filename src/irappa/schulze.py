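"""Schulze consensus over an ensemble of decoy rankings.

Each selected ranking model casts a ballot: a total order over one complex's
decoys. A complete preference digraph is built in which the weight of edge
(a, b) counts the ballots ranking a above b. The strength of a directed path
is its minimum edge weight; the strongest path between two decoys is the one
of maximal strength (a widest-path problem, solved by Floyd-Warshall-style
dynamic programming). Decoy a beats decoy b in the consensus when the
strongest path a -> b is stronger than the strongest path b -> a; the
pairwise relation is transitive, so a consensus total order follows.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = [
    "build_preference_graph",
    "consensus_ranking",
    "schulze_consensus",
    "strongest_paths",
]


def build_preference_graph(rankings: Sequence[np.ndarray]) -> np.ndarray:
    """Pairwise "ranked-higher" counts across the ensemble.

    ``rankings`` are permutations of the same decoy indices, best first.
    Returns the (n, n) integer matrix W with W[a, b] = number of rankings
    placing a above b; W[a, b] + W[b, a] equals the ensemble size for a != b.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    n = len(rankings[0])
    expected = list(range(n))
    W = np.zeros((n, n), dtype=int)
    for ranking in rankings:
        ranking = np.asarray(ranking, dtype=int)
        if sorted(ranking.tolist()) != expected:
            raise ValueError("rankings must be permutations of the same decoy set")
        pos = np.empty(n, dtype=int)
        pos[ranking] = np.arange(n)
        W += pos[:, None] < pos[None, :]
    return W


def strongest_paths(graph: np.ndarray) -> np.ndarray:
    """Strength of the strongest (widest) path between all ordered pairs.

    strength(a, b) = max over directed paths a -> b of the minimum edge
    weight along the path, computed by the O(n^3) Floyd-Warshall max-min
    relaxation. With n <= 500 decoys this is desk-scale.
    """
    W = np.asarray(graph, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("preference graph must be square")
    P = W.copy()
    np.fill_diagonal(P, np.inf)  # neutral for min() during relaxation
    n = P.shape[0]
    for k in range(n):
        np.maximum(P, np.minimum(P[:, k, None], P[None, k, :]), out=P)
    np.fill_diagonal(P, 0.0)
    return P


def consensus_ranking(
    strengths: np.ndarray,
    mean_ranks: Optional[np.ndarray] = None,
    initial_ranks: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Total order from the pairwise strongest-path comparisons.

    Decoy a precedes b whenever strength(a, b) > strength(b, a). Because the
    relation is transitive, sorting by the number of pairwise wins yields a
    total order that never contradicts a strict pairwise preference. Exact
    pairwise ties are broken by lower mean rank across the ensemble, then by
    the docking engine's initial rank.
    """
    P = np.asarray(strengths, dtype=float)
    n = P.shape[0]
    wins = (P > P.T).sum(axis=1)
    mean_ranks = np.zeros(n) if mean_ranks is None else np.asarray(mean_ranks, dtype=float)
    initial_ranks = (
        np.arange(n) if initial_ranks is None else np.asarray(initial_ranks, dtype=float)
    )
    return np.lexsort((initial_ranks, mean_ranks, -wins))


def schulze_consensus(
    rankings: Sequence[np.ndarray],
    initial_ranks: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Aggregate ensemble rankings into one consensus ranking (best first)."""
    W = build_preference_graph(rankings)
    P = strongest_paths(W)
    n = W.shape[0]
    pos_sum = np.zeros(n)
    for ranking in rankings:
        pos = np.empty(n, dtype=int)
        pos[np.asarray(ranking, dtype=int)] = np.arange(n)
        pos_sum += pos
    return consensus_ranking(P, mean_ranks=pos_sum / len(rankings), initial_ranks=initial_ranks)
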