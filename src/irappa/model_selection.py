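"""Cluster-rank scoring of ranking models and top-n ensemble selection.

A trained model is judged on held-out model-selection complexes. For one
complex, the decoys are clustered (single linkage, 3.5 A by default) and the
clusters are ordered by the ranking position of their best-ranked member.
With n_c clusters and r the rank of the first cluster whose top-ranked member
is near-native, the per-complex score is

    s_i = (log10(n_c) - log10(r)) / log10(n_c),

which runs from 1 (top cluster is topped by a near-native) down to 0 (only
the last cluster is), and is 0 when no cluster is topped by a near-native.
The logarithm makes a gain near the top of the list (rank 11 -> 1) worth far
more than the same gain far down it (rank 411 -> 401).

An ensemble member's total score is taken relative to the ensemble mean,
S = sum_i (s_i - s_bar_i), which favours models that do well on complexes
the rest of the ensemble finds hard; the top-n models by S form the final
ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .clustering import Clustering
from .decoyset_io import DecoySet
from .rsvm import RankingModel

__all__ = [
    "ClusterRanking",
    "ModelScore",
    "cluster_rank",
    "complex_score",
    "ensemble_relative_scores",
    "select_top_models",
]


@dataclass
class ClusterRanking:
    """Clusters of one complex ordered by their best-ranked member.

    ``cluster_order`` lists cluster ids best-first; ``r`` is the 1-based rank
    of the first cluster whose top-ranked member decoy is near-native
    (acceptable or better), or None when no cluster is topped by one.
    """

    n_c: int
    r: Optional[int]
    cluster_order: list[int]

    def __post_init__(self) -> None:
        if self.n_c < 1:
            raise ValueError("n_c must be >= 1")
        if self.r is not None and not 1 <= self.r <= self.n_c:
            raise ValueError(f"r must lie in 1..{self.n_c}, got {self.r}")


def cluster_rank(dset: DecoySet, ranking: np.ndarray, clustering: Clustering) -> ClusterRanking:
    """Order clusters by their best-ranked member and locate r.

    ``ranking`` is a permutation of decoy indices, best first, from one
    model's projection (or a consensus). Each cluster is represented by its
    best-ranked member; clusters are sorted by that member's position and r
    is the position of the first cluster whose representative is near-native.
    """
    ranking = np.asarray(ranking, dtype=int)
    positions = np.empty(dset.n_decoys, dtype=int)
    positions[ranking] = np.arange(dset.n_decoys)
    nn = dset.near_native_mask
    best_pos = []
    top_is_nn = []
    for cid in range(1, clustering.n_clusters + 1):
        members = clustering.members(cid)
        top = members[np.argmin(positions[members])]
        best_pos.append(positions[top])
        top_is_nn.append(bool(nn[top]))
    order = np.argsort(best_pos, kind="stable")
    cluster_order = [int(cid + 1) for cid in order]
    r = None
    for rank_1based, cid0 in enumerate(order, start=1):
        if top_is_nn[cid0]:
            r = rank_1based
            break
    return ClusterRanking(n_c=clustering.n_clusters, r=r, cluster_order=cluster_order)


def complex_score(cr: ClusterRanking) -> float:
    """Per-complex score s_i in [0, 1] from the cluster ranking.

    s_i = (log10(n_c) - log10(r)) / log10(n_c); 0 when r is absent. The
    single-cluster case (n_c = 1, where the formula degenerates to 0/0)
    scores 1 when that cluster's top decoy is near-native, else 0, consistent
    with the range endpoints.
    """
    if cr.r is None:
        return 0.0
    if cr.n_c == 1:
        return 1.0  # r == 1 is forced by the invariant
    return (math.log10(cr.n_c) - math.log10(cr.r)) / math.log10(cr.n_c)


@dataclass
class ModelScore:
    """One ensemble member's per-complex scores and relative total.

    ``s`` maps complex id to s_i; ``s_bar`` holds the ensemble means over
    the models scored on each complex; ``total`` is S = sum_i (s_i - s_bar_i)
    over this model's selection complexes.
    """

    s: dict[str, float]
    s_bar: dict[str, float]
    total: float


def ensemble_relative_scores(per_model_scores: Sequence[dict[str, float]]) -> list[ModelScore]:
    """Relative total score S for every model of an ensemble.

    ``per_model_scores[m]`` maps complex id to model m's s_i on its own
    model-selection set. The ensemble mean s_bar_i for a complex is taken
    over the models whose selection set contains it (they coincide for all
    models under protocol A; under protocol B selection sets differ).
    """
    if not per_model_scores:
        raise ValueError("ensemble must contain at least one model")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for scores in per_model_scores:
        for cid, s in scores.items():
            sums[cid] = sums.get(cid, 0.0) + s
            counts[cid] = counts.get(cid, 0) + 1
    s_bar = {cid: sums[cid] / counts[cid] for cid in sums}
    out = []
    for scores in per_model_scores:
        total = sum(s - s_bar[cid] for cid, s in scores.items())
        out.append(ModelScore(s=dict(scores), s_bar={c: s_bar[c] for c in scores}, total=total))
    return out


def select_top_models(
    models: Sequence[RankingModel],
    scores: Sequence[ModelScore],
    n: int,
) -> list[int]:
    """Indices of the n models with highest relative score S.

    Ties in S are broken by model creation index (ascending), making the
    selection deterministic. Returns indices into ``models`` in descending-S
    order.
    """
    if len(models) != len(scores):
        raise ValueError("models and scores differ in length")
    if not 1 <= n <= len(models):
        raise ValueError(f"n must lie in 1..{len(models)}, got {n}")
    order = sorted(range(len(models)), key=lambda m: (-scores[m].total, m))
    return order[:n]
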