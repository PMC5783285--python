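"""Ranking support vector machine over pairwise decoy-quality constraints.

For every ordered pair of decoys (i, j) of the same complex that fall in
different CAPRI categories, with i the better one, the model demands

    w . d_i  >=  w . d_j + 1 - xi_ij,     xi_ij >= 0,

and the weight vector solves

    argmin_w  1/2 ||w||^2 + c * sum(xi_ij)   subject to the above,

i.e. a soft-margin SVM on the difference vectors d_i - d_j with all-positive
labels and no intercept. Decoys are then ranked by descending projection
w . d. Pairs never span complexes: scores only matter relative to other
decoys of the same complex.

The optimizer here is dual coordinate descent with a duality-gap stopping
rule: the dual is max_a sum(a_p) - 1/2 ||sum_p a_p x_p||^2 with box
constraints 0 <= a_p <= c, and each coordinate update is the exact
one-dimensional maximizer. The problem is convex, so the gap bounds the
distance to the global optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .decoyset_io import DecoySet

__all__ = [
    "PairConstraintSet",
    "RankingModel",
    "build_pairs",
    "rank_by_projection",
    "swapped_pair_fraction",
    "train",
]

try:  # jitted inner loop; the pure-python fallback is ~100x slower but exact
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not args or not callable(args[0]) else args[0]


@dataclass(eq=False)
class PairConstraintSet:
    """Cross-category decoy pairs and their feature-difference vectors.

    ``pairs[p] = (complex_id, better_index, worse_index)`` (indices into that
    complex's decoy set, better strictly above worse in CAPRI category) and
    ``diffs[p] = d_better - d_worse``.
    """

    pairs: list[tuple[str, int, int]]
    diffs: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def complex_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for cid, _, _ in self.pairs:
            seen.setdefault(cid)
        return list(seen)


def build_pairs(sets: Sequence[DecoySet]) -> PairConstraintSet:
    """Enumerate all within-complex cross-category ordered pairs.

    A complex whose decoys all share one category contributes no pairs (not
    an error). No pair ever spans two complexes.
    """
    pairs: list[tuple[str, int, int]] = []
    blocks: list[np.ndarray] = []
    n_feat = sets[0].n_features if sets else 0
    for dset in sets:
        codes = dset.label_codes
        order = np.argsort(-codes, kind="stable")  # better categories first
        for a_pos, i in enumerate(order):
            for j in order[a_pos + 1 :]:
                if codes[i] > codes[j]:
                    pairs.append((dset.complex_id, int(i), int(j)))
                    blocks.append(dset.features[i] - dset.features[j])
    diffs = np.asarray(blocks, dtype=float) if blocks else np.empty((0, n_feat))
    return PairConstraintSet(pairs=pairs, diffs=diffs)


@dataclass(eq=False)
class RankingModel:
    """A trained weight vector with its regularization constant.

    ``objective_value`` is 1/2 ||w||^2 + c * sum(slacks) at the solution.
    """

    weights: np.ndarray
    c: float
    training_complex_ids: list[str] = field(default_factory=list)
    objective_value: float = float("nan")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValueError("model weights must be finite")

    def project(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.shape[-1] != self.weights.shape[0]:
            raise ValueError(
                f"feature dimension {features.shape[-1]} does not match "
                f"model dimension {self.weights.shape[0]}"
            )
        return features @ self.weights

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "weights": self.weights.tolist(),
                    "c": self.c,
                    "training_complex_ids": list(self.training_complex_ids),
                    "objective_value": self.objective_value,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RankingModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(doc["weights"], dtype=float),
            c=float(doc["c"]),
            training_complex_ids=list(doc["training_complex_ids"]),
            objective_value=float(doc["objective_value"]),
        )


@_njit(cache=False)
def _cd_epoch(X, sq_norms, alpha, w, c, order):  # pragma: no cover - jitted
    for p in order:
        s = sq_norms[p]
        if s <= 0.0:
            continue
        g = np.dot(X[p], w) - 1.0
        a_old = alpha[p]
        a_new = a_old - g / s
        if a_new < 0.0:
            a_new = 0.0
        elif a_new > c:
            a_new = c
        if a_new != a_old:
            delta = a_new - a_old
            alpha[p] = a_new
            for k in range(w.shape[0]):
                w[k] += delta * X[p, k]


def _objective(w: np.ndarray, X: np.ndarray, c: float) -> float:
    slacks = np.maximum(0.0, 1.0 - X @ w)
    return 0.5 * float(w @ w) + c * float(slacks.sum())


def train(
    pairs: PairConstraintSet,
    c: float,
    tolerance: float = 1e-4,
    max_epochs: int = 20000,
    shuffle_seed: int = 0,
) -> RankingModel:
    """Solve the soft-margin ranking problem for one value of ``c``.

    Dual coordinate descent over the pair constraints; stops when the
    relative duality gap (primal minus dual over max(1, |primal|)) drops
    below ``tolerance``, which certifies the returned objective is within
    that distance of the convex problem's global optimum. Raises if the
    budget of ``max_epochs`` passes is exhausted first.
    """
    if c <= 0:
        raise ValueError("regularization constant c must be positive")
    if pairs.n_pairs == 0:
        raise ValueError("cannot train on an empty pair set")
    X = np.ascontiguousarray(pairs.diffs, dtype=float)
    n_pairs, n_feat = X.shape
    sq_norms = np.einsum("ij,ij->i", X, X)
    alpha = np.zeros(n_pairs)
    w = np.zeros(n_feat)
    rng = np.random.default_rng(shuffle_seed)
    gap = np.inf
    for _ in range(max_epochs):
        order = rng.permutation(n_pairs)
        _cd_epoch(X, sq_norms, alpha, w, float(c), order)
        primal = _objective(w, X, c)
        dual = float(alpha.sum()) - 0.5 * float(w @ w)
        gap = primal - dual
        if gap <= tolerance * max(1.0, abs(primal)):
            return RankingModel(
                weights=w,
                c=float(c),
                training_complex_ids=pairs.complex_ids,
                objective_value=primal,
            )
    raise RuntimeError(
        f"ranking SVM did not converge: relative duality gap {gap:.3e} after "
        f"{max_epochs} epochs (n_pairs={n_pairs}, c={c})"
    )


def rank_by_projection(model: RankingModel, dset: DecoySet) -> np.ndarray:
    """Order decoys by descending projection onto the weight vector.

    Returns a permutation of decoy indices, best first. Projection ties are
    broken by ascending initial rank (the docking engine's prior), so an
    all-zero weight vector reproduces the engine's ordering.
    """
    scores = model.project(dset.features)
    keys = np.lexsort((dset.initial_ranks, -scores))
    return keys


def swapped_pair_fraction(ranking: np.ndarray, labels: Sequence) -> float:
    """Fraction of cross-category pairs ranked in the wrong order.

    Among all pairs of decoys in different CAPRI categories, the fraction
    where the worse-category decoy sits above the better one in ``ranking``
    (a permutation of decoy indices, best first). 0 is a perfect ranking, 1 a
    fully reversed one; NaN when no cross-category pair exists.
    """
    ranking = np.asarray(ranking, dtype=int)
    codes = np.array([int(lab) for lab in labels])
    if len(ranking) != len(codes):
        raise ValueError("ranking and labels differ in length")
    ordered = codes[ranking]  # category codes in ranked order, best-ranked first
    total = 0
    swapped = 0
    n = len(ordered)
    for a in range(n):
        for b in range(a + 1, n):
            if ordered[a] == ordered[b]:
                continue
            total += 1
            if ordered[a] < ordered[b]:  # worse category ranked above better
                swapped += 1
    if total == 0:
        return float("nan")
    return swapped / total
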