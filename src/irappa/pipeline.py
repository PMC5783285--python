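"""End-to-end training protocols, metaparameter search and evaluation.

Two validation protocols are supported, mirroring how the method is
benchmarked:

* **Protocol A** — the base benchmark complexes are randomly partitioned
  into training and model-selection sets (2:1), many times over (200 by
  default); an update set of new complexes is the fixed external test set.
* **Protocol B** — all complexes are partitioned into training,
  model-selection and test sets (2:1:1), 800 times by default, so each
  complex sits in roughly repeats/4 test sets; a complex is only ever ranked
  by models that saw it in neither training nor model selection
  (leave-many-out cross-validation).

For each repeat and each regularization constant c (50 log-spaced values in
[1e-4, 1e3] by default) a ranking SVM is trained and scored on its
model-selection set with the cluster-rank score. For every grid cell (c, n)
the top-n models by relative score S form an ensemble whose rankings are
Schulze-aggregated into a consensus per test complex. The (c, n) cell used
for a given complex is chosen by leave-one-out: the cell maximizing the
summed scores of the *other* test complexes. Evaluation reports top-1/10/100
retrieval rates (over complexes with a sampled near-native) and success
rates (over all complexes), plus a paired Wilcoxon signed-rank comparison of
best near-native ranks before and after re-ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import defaults
from .clustering import Clustering, ligand_rmsd_matrix, single_linkage
from .decoyset_io import DecoySet, FeatureSchema, fit_normalizer, impute_missing, normalize, truncate_to_top
from .model_selection import cluster_rank, complex_score, ensemble_relative_scores, select_top_models
from .rsvm import PairConstraintSet, RankingModel, build_pairs, rank_by_projection
from .rsvm import train as train_rsvm
from .schulze import schulze_consensus

__all__ = [
    "BenchmarkResult",
    "EvaluationReport",
    "MetaparameterGrid",
    "ModelBank",
    "SplitAssignment",
    "SplitPlan",
    "TrainedEntry",
    "WilcoxonResult",
    "cell_consensus",
    "compare_rankings",
    "evaluate",
    "grid_consensus_scores",
    "loo_metaparameters",
    "make_splits",
    "mode_average_cell",
    "run_benchmark",
    "train_grid",
]


# ---------------------------------------------------------------------------
# Splits and the metaparameter grid


@dataclass(frozen=True)
class SplitAssignment:
    training: tuple[str, ...]
    model_selection: tuple[str, ...]
    test: tuple[str, ...]


@dataclass
class SplitPlan:
    """Reproducible per-repeat role assignment of complexes."""

    protocol: str
    repeats: int
    assignments: list[SplitAssignment]
    seed: int


def _allocate(n: int, weights: Sequence[int]) -> list[int]:
    """Floor-allocate n items by integer ratio; remainders go to earlier roles."""
    total = sum(weights)
    sizes = [n * w // total for w in weights]
    remainder = n - sum(sizes)
    for i in range(remainder):
        sizes[i % len(sizes)] += 1
    return sizes


def make_splits(
    base_ids: Sequence[str],
    protocol: str = "B",
    repeats: Optional[int] = None,
    seed: int = 0,
    update_ids: Optional[Sequence[str]] = None,
) -> SplitPlan:
    """Draw the per-repeat training / model-selection / test partitions.

    Protocol A partitions ``base_ids`` 2:1 into training and model selection
    (200 repeats by default); ``update_ids`` is the fixed test set. Protocol
    B partitions ``base_ids`` 2:1:1 into all three roles (800 repeats by
    default). Sizes are floor-allocated by ratio with remainders given to
    training first. Identical seeds give identical plans.
    """
    protocol = protocol.upper()
    if protocol not in ("A", "B"):
        raise ValueError(f"unknown protocol {protocol!r}")
    base_ids = list(base_ids)
    if repeats is None:
        repeats = 200 if protocol == "A" else 800
    if protocol == "A":
        if not update_ids:
            raise ValueError("protocol A needs a non-empty update (test) set")
        sizes = _allocate(len(base_ids), (2, 1))
        if min(sizes) < 1:
            raise ValueError("too few complexes to fill training and selection roles")
    else:
        if update_ids:
            raise ValueError("protocol B partitions a single pool; update_ids must be empty")
        sizes = _allocate(len(base_ids), (2, 1, 1))
        if min(sizes) < 1:
            raise ValueError("too few complexes to fill all three roles")

    streams = np.random.SeedSequence(seed).spawn(repeats)
    assignments = []
    for rep in range(repeats):
        rng = np.random.default_rng(streams[rep])
        order = [base_ids[i] for i in rng.permutation(len(base_ids))]
        if protocol == "A":
            n_tr = sizes[0]
            assignments.append(
                SplitAssignment(
                    training=tuple(order[:n_tr]),
                    model_selection=tuple(order[n_tr:]),
                    test=tuple(update_ids),
                )
            )
        else:
            n_tr, n_sel, _ = sizes
            assignments.append(
                SplitAssignment(
                    training=tuple(order[:n_tr]),
                    model_selection=tuple(order[n_tr : n_tr + n_sel]),
                    test=tuple(order[n_tr + n_sel :]),
                )
            )
    return SplitPlan(protocol=protocol, repeats=repeats, assignments=assignments, seed=seed)


@dataclass(eq=False)
class MetaparameterGrid:
    """The (c, n) search grid: regularization constants x ensemble sizes."""

    c_values: np.ndarray
    n_values: np.ndarray

    @classmethod
    def default(cls) -> "MetaparameterGrid":
        """50 log-spaced c in [1e-4, 1e3] inclusive x n = 1..50."""
        c = np.logspace(
            np.log10(defaults.GRID_C_MIN), np.log10(defaults.GRID_C_MAX), defaults.GRID_N_C
        )
        c[0], c[-1] = defaults.GRID_C_MIN, defaults.GRID_C_MAX  # exact endpoints
        return cls(c_values=c, n_values=np.arange(1, defaults.GRID_N_MAX + 1))


# ---------------------------------------------------------------------------
# Grid training


@dataclass(eq=False)
class TrainedEntry:
    """One trained model: its split, c-index and selection-set scores."""

    model: RankingModel
    repeat: int
    c_index: int
    split: SplitAssignment
    selection_scores: dict[str, float]


@dataclass(eq=False)
class ModelBank:
    """All models of a grid run, indexed by (repeat, c_index)."""

    plan: SplitPlan
    c_values: np.ndarray
    entries: list[TrainedEntry]

    def entries_for_c(self, c_index: int) -> list[TrainedEntry]:
        return [e for e in self.entries if e.c_index == c_index]


def _score_on_selection(
    model: RankingModel,
    sets_by_id: dict[str, DecoySet],
    clusterings: dict[str, Clustering],
    complex_ids: Sequence[str],
) -> dict[str, float]:
    scores = {}
    for cid in complex_ids:
        dset = sets_by_id[cid]
        ranking = rank_by_projection(model, dset)
        scores[cid] = complex_score(cluster_rank(dset, ranking, clusterings[cid]))
    return scores


def train_grid(
    sets_by_id: dict[str, DecoySet],
    plan: SplitPlan,
    c_values: np.ndarray,
    clusterings: dict[str, Clustering],
    tolerance: float = 1e-3,
) -> ModelBank:
    """Train one model per (repeat, c) and score it on its selection set.

    Decoy sets must already be imputed and normalized; ``clusterings`` holds
    each complex's single-linkage partition at the scoring cutoff. Complexes
    whose decoys all share one CAPRI category contribute no pair constraints.
    """
    pair_cache: dict[str, PairConstraintSet] = {
        cid: build_pairs([dset]) for cid, dset in sets_by_id.items()
    }
    entries: list[TrainedEntry] = []
    for rep, split in enumerate(plan.assignments):
        train_ids = [cid for cid in split.training if pair_cache[cid].n_pairs > 0]
        if not train_ids:
            raise ValueError(f"repeat {rep}: no cross-category pairs in the training set")
        merged = PairConstraintSet(
            pairs=[p for cid in train_ids for p in pair_cache[cid].pairs],
            diffs=np.vstack([pair_cache[cid].diffs for cid in train_ids]),
        )
        for ci, c in enumerate(np.asarray(c_values, dtype=float)):
            model = train_rsvm(merged, c, tolerance=tolerance)
            scores = _score_on_selection(model, sets_by_id, clusterings, split.model_selection)
            entries.append(
                TrainedEntry(
                    model=model, repeat=rep, c_index=ci, split=split, selection_scores=scores
                )
            )
    return ModelBank(plan=plan, c_values=np.asarray(c_values, dtype=float), entries=entries)


# ---------------------------------------------------------------------------
# Cell consensus and leave-one-out metaparameter selection


def cell_consensus(
    bank: ModelBank,
    sets_by_id: dict[str, DecoySet],
    c_index: int,
    n: int,
) -> tuple[dict[str, np.ndarray], dict[str, list[int]]]:
    """Schulze consensus per test complex for one (c, n) grid cell.

    Under protocol A the top-n models (by relative score S over the whole
    c-ensemble) rank every test complex. Under protocol B each complex is
    ranked only by models whose test set contains it — i.e. models that saw
    it in neither training nor model selection — taking the top n of those by
    S (all of them when fewer than n exist). Returns the consensus ranking
    per complex plus, for audit, the bank indices of the models used.
    """
    pool = bank.entries_for_c(c_index)
    if not pool:
        raise ValueError(f"no models at c index {c_index}")
    scores = ensemble_relative_scores([e.selection_scores for e in pool])
    consensus: dict[str, np.ndarray] = {}
    used: dict[str, list[int]] = {}
    if bank.plan.protocol == "A":
        top = select_top_models([e.model for e in pool], scores, min(n, len(pool)))
        chosen = [pool[m] for m in top]
        test_ids = bank.plan.assignments[0].test
        for cid in test_ids:
            dset = sets_by_id[cid]
            rankings = [rank_by_projection(e.model, dset) for e in chosen]
            consensus[cid] = schulze_consensus(rankings, initial_ranks=dset.initial_ranks)
            used[cid] = [bank.entries.index(e) for e in chosen]
    else:
        for cid, dset in sets_by_id.items():
            eligible = [m for m, e in enumerate(pool) if cid in e.split.test]
            if not eligible:
                continue
            order = sorted(eligible, key=lambda m: (-scores[m].total, m))
            chosen = [pool[m] for m in order[: min(n, len(order))]]
            rankings = [rank_by_projection(e.model, dset) for e in chosen]
            consensus[cid] = schulze_consensus(rankings, initial_ranks=dset.initial_ranks)
            used[cid] = [bank.entries.index(e) for e in chosen]
    return consensus, used


def grid_consensus_scores(
    bank: ModelBank,
    sets_by_id: dict[str, DecoySet],
    clusterings: dict[str, Clustering],
    n_values: Sequence[int],
) -> dict[tuple[int, int], dict[str, float]]:
    """Per-complex cluster-rank score of the consensus in every grid cell.

    Keys are (c_index, n); values map complex id to the s_i of that cell's
    consensus ranking.
    """
    out: dict[tuple[int, int], dict[str, float]] = {}
    for ci in range(len(bank.c_values)):
        for n in n_values:
            consensus, _ = cell_consensus(bank, sets_by_id, ci, int(n))
            cell_scores = {}
            for cid, ranking in consensus.items():
                dset = sets_by_id[cid]
                cell_scores[cid] = complex_score(cluster_rank(dset, ranking, clusterings[cid]))
            out[(ci, int(n))] = cell_scores
    return out


def loo_metaparameters(
    cell_scores: dict[tuple[int, int], dict[str, float]],
) -> dict[str, tuple[int, int]]:
    """Leave-one-out (c, n) choice per test complex.

    For each complex, pick the cell maximizing the summed scores of the
    remaining complexes; ties break towards smaller c then smaller n. With a
    single complex the leave-one-out sum is empty everywhere, so the choice
    falls back to the global argmax (the complex's own score).
    """
    cells = sorted(cell_scores)
    complex_ids = sorted({cid for scores in cell_scores.values() for cid in scores})
    totals = {cell: sum(cell_scores[cell].values()) for cell in cells}
    choice = {}
    for cid in complex_ids:
        if len(complex_ids) == 1:
            values = dict(totals)
        else:
            values = {cell: totals[cell] - cell_scores[cell].get(cid, 0.0) for cell in cells}
        best = max(values.values())
        # ties break towards smaller c then smaller n (cells are sorted)
        choice[cid] = next(cell for cell in cells if values[cell] >= best - 1e-12)
    return choice


def mode_average_cell(choice: dict[str, tuple[int, int]]) -> tuple[int, int]:
    """Most frequent LOO cell (ties towards smaller c then n) — server mode."""
    counts: dict[tuple[int, int], int] = {}
    for cell in choice.values():
        counts[cell] = counts.get(cell, 0) + 1
    best = max(sorted(counts), key=lambda cell: counts[cell])
    return best


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvaluationReport:
    """Top-k retrieval/success rates and quality-upgrade counts.

    Retrieval rates are percentages over complexes with at least one sampled
    near-native; success rates share the numerator but divide by all
    complexes. ``upgrades[k] = (upgraded, downgraded)`` counts complexes,
    among those with a near-native within the top k both before and after
    re-ranking, whose top-ranked near-native moved to a higher (lower) CAPRI
    class.
    """

    ks: tuple[int, ...]
    n_complexes: int
    n_with_near_native: int
    best_rank_initial: dict[str, Optional[int]]
    best_rank_consensus: dict[str, Optional[int]]
    retrieval_rates: dict[int, float]
    success_rates: dict[int, float]
    baseline_retrieval_rates: dict[int, float]
    baseline_success_rates: dict[int, float]
    upgrades: dict[int, tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "ks": list(self.ks),
            "n_complexes": self.n_complexes,
            "n_with_near_native": self.n_with_near_native,
            "best_rank_initial": self.best_rank_initial,
            "best_rank_consensus": self.best_rank_consensus,
            "retrieval_rates": {str(k): v for k, v in self.retrieval_rates.items()},
            "success_rates": {str(k): v for k, v in self.success_rates.items()},
            "baseline_retrieval_rates": {
                str(k): v for k, v in self.baseline_retrieval_rates.items()
            },
            "baseline_success_rates": {
                str(k): v for k, v in self.baseline_success_rates.items()
            },
            "upgrades": {str(k): list(v) for k, v in self.upgrades.items()},
        }


def _best_near_native_rank(dset: DecoySet, ranking: np.ndarray) -> Optional[int]:
    positions = np.empty(dset.n_decoys, dtype=int)
    positions[np.asarray(ranking, dtype=int)] = np.arange(1, dset.n_decoys + 1)
    nn = dset.near_native_mask
    if not nn.any():
        return None
    return int(positions[nn].min())


def _top_near_native_class(dset: DecoySet, ranking: np.ndarray) -> int:
    positions = np.empty(dset.n_decoys, dtype=int)
    positions[np.asarray(ranking, dtype=int)] = np.arange(1, dset.n_decoys + 1)
    nn = np.flatnonzero(dset.near_native_mask)
    best = nn[np.argmin(positions[nn])]
    return int(dset.labels[best])


def _initial_ranking(dset: DecoySet) -> np.ndarray:
    return np.argsort(dset.initial_ranks, kind="stable")


def evaluate(
    sets: Sequence[DecoySet],
    consensus: dict[str, np.ndarray],
    ks: Sequence[int] = (1, 10, 100),
) -> EvaluationReport:
    """Score consensus rankings against the docking engine's initial order.

    Every complex in ``sets`` must have a consensus ranking. Rates are
    percentages; the retrieval denominator (complexes with a sampled
    near-native) is a subset of the success denominator, so retrieval >=
    success at every k.
    """
    ks = tuple(int(k) for k in ks)
    best_init: dict[str, Optional[int]] = {}
    best_cons: dict[str, Optional[int]] = {}
    upgrades = {k: [0, 0] for k in ks}
    n_with_nn = 0
    for dset in sets:
        cid = dset.complex_id
        if cid not in consensus:
            raise ValueError(f"no consensus ranking for complex {cid}")
        init_ranking = _initial_ranking(dset)
        best_init[cid] = _best_near_native_rank(dset, init_ranking)
        best_cons[cid] = _best_near_native_rank(dset, consensus[cid])
        if dset.has_near_native:
            n_with_nn += 1
            before_cls = _top_near_native_class(dset, init_ranking)
            after_cls = _top_near_native_class(dset, consensus[cid])
            for k in ks:
                if best_init[cid] <= k and best_cons[cid] <= k:
                    if after_cls > before_cls:
                        upgrades[k][0] += 1
                    elif after_cls < before_cls:
                        upgrades[k][1] += 1
    n_total = len(sets)

    def rates(best: dict[str, Optional[int]], denominator: int) -> dict[int, float]:
        out = {}
        for k in ks:
            hits = sum(1 for v in best.values() if v is not None and v <= k)
            out[k] = 100.0 * hits / denominator if denominator else float("nan")
        return out

    return EvaluationReport(
        ks=ks,
        n_complexes=n_total,
        n_with_near_native=n_with_nn,
        best_rank_initial=best_init,
        best_rank_consensus=best_cons,
        retrieval_rates=rates(best_cons, n_with_nn),
        success_rates=rates(best_cons, n_total),
        baseline_retrieval_rates=rates(best_init, n_with_nn),
        baseline_success_rates=rates(best_init, n_total),
        upgrades={k: (v[0], v[1]) for k, v in upgrades.items()},
    )


@dataclass
class WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank comparison of rank vectors."""

    defined: bool
    statistic: Optional[float]
    pvalue: Optional[float]
    n_nonzero: int
    direction: Optional[str]  # "after_better" | "before_better" | None


def compare_rankings(
    before: Sequence[float],
    after: Sequence[float],
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired per-complex best near-native ranks.

    Lower ranks are better, so "after_better" means the rank differences
    (after - before) lean negative. Zero differences are discarded (the
    standard convention); fewer than two non-zero pairs leaves the test
    undefined.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired vectors differ in length")
    diffs = after - before
    nonzero = diffs[diffs != 0]
    if len(nonzero) < 2:
        return WilcoxonResult(False, None, None, len(nonzero), None)
    stat, p = stats.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided")
    direction = "after_better" if nonzero.sum() < 0 else "before_better"
    return WilcoxonResult(True, float(stat), float(p), len(nonzero), direction)


# ---------------------------------------------------------------------------
# Driver


@dataclass
class BenchmarkResult:
    """Everything produced by one end-to-end run."""

    schema: FeatureSchema
    plan: SplitPlan
    bank: ModelBank
    cell_scores: dict[tuple[int, int], dict[str, float]]
    loo_choice: dict[str, tuple[int, int]]
    consensus: dict[str, np.ndarray]
    consensus_entries: dict[str, list[int]]
    report: EvaluationReport
    wilcoxon: WilcoxonResult


def prepare_sets(
    sets: Sequence[DecoySet],
    training_ids: Optional[Sequence[str]] = None,
    decoy_limit: int = defaults.DEFAULT_DECOY_LIMIT,
) -> tuple[dict[str, DecoySet], FeatureSchema]:
    """Truncate, impute and z-score a benchmark's decoy sets.

    The normalizer is fitted on the pooled training complexes (all of them by
    default, i.e. one parameter set per docking method) and applied
    everywhere with those fitted parameters.
    """
    truncated = [truncate_to_top(s, decoy_limit) for s in sets]
    imputed = impute_missing(truncated)
    schema = FeatureSchema(names=[f"f{j + 1}" for j in range(imputed[0].n_features)])
    fit_pool = (
        imputed
        if training_ids is None
        else [s for s in imputed if s.complex_id in set(training_ids)]
    )
    fitted = fit_normalizer(fit_pool, schema)
    sets_by_id = {s.complex_id: normalize(s, fitted) for s in imputed}
    return sets_by_id, fitted


def scoring_clusterings(
    sets_by_id: dict[str, DecoySet],
    cutoff: float = defaults.DEFAULT_SCORING_CUTOFF,
    distance_matrices: Optional[dict[str, np.ndarray]] = None,
) -> dict[str, Clustering]:
    """Single-linkage clustering of every complex at the scoring cutoff.

    Distance matrices are computed from coordinates when present, otherwise
    they must be supplied by the caller.
    """
    out = {}
    for cid, dset in sets_by_id.items():
        if distance_matrices is not None and cid in distance_matrices:
            matrix = distance_matrices[cid]
        else:
            matrix = ligand_rmsd_matrix(dset)
        out[cid] = single_linkage(matrix, cutoff)
    return out


def run_benchmark(
    sets: Sequence[DecoySet],
    protocol: str = "B",
    repeats: Optional[int] = None,
    c_values: Optional[np.ndarray] = None,
    n_values: Optional[Sequence[int]] = None,
    seed: int = 0,
    update_ids: Optional[Sequence[str]] = None,
    scoring_cutoff: float = defaults.DEFAULT_SCORING_CUTOFF,
    decoy_limit: int = defaults.DEFAULT_DECOY_LIMIT,
    tolerance: float = 1e-3,
    distance_matrices: Optional[dict[str, np.ndarray]] = None,
) -> BenchmarkResult:
    """Run a full protocol: splits, grid training, LOO selection, evaluation.

    ``sets`` holds every complex (base and, for protocol A, update/test
    complexes named in ``update_ids``). The default grid is the full 50x50
    one; pass reduced ``c_values``/``n_values`` for desk-scale runs. A
    complex that no eligible model can rank (possible under protocol B with
    very few repeats) falls back to the engine's initial ordering, with a
    warning.
    """
    grid = MetaparameterGrid.default()
    if c_values is None:
        c_values = grid.c_values
    if n_values is None:
        n_values = grid.n_values
    update_ids = list(update_ids) if update_ids else []
    base_ids = [s.complex_id for s in sets if s.complex_id not in set(update_ids)]

    sets_by_id, schema = prepare_sets(sets, training_ids=base_ids, decoy_limit=decoy_limit)
    clusterings = scoring_clusterings(sets_by_id, scoring_cutoff, distance_matrices)
    plan = make_splits(
        base_ids, protocol=protocol, repeats=repeats, seed=seed, update_ids=update_ids or None
    )
    bank = train_grid(sets_by_id, plan, np.asarray(c_values, dtype=float), clusterings, tolerance)
    cell_scores = grid_consensus_scores(bank, sets_by_id, clusterings, n_values)
    loo_choice = loo_metaparameters(cell_scores)

    cell_cache: dict[tuple[int, int], tuple[dict, dict]] = {}
    consensus: dict[str, np.ndarray] = {}
    used: dict[str, list[int]] = {}
    eval_ids = update_ids if plan.protocol == "A" else list(sets_by_id)
    for cid in eval_ids:
        cell = loo_choice.get(cid)
        if cell is None:
            warnings.warn(f"{cid}: no eligible models; falling back to the initial ordering")
            consensus[cid] = _initial_ranking(sets_by_id[cid])
            used[cid] = []
            continue
        if cell not in cell_cache:
            cell_cache[cell] = cell_consensus(bank, sets_by_id, cell[0], cell[1])
        consensus[cid] = cell_cache[cell][0][cid]
        used[cid] = cell_cache[cell][1][cid]

    eval_sets = [sets_by_id[cid] for cid in eval_ids]
    report = evaluate(eval_sets, consensus)
    paired = [
        (report.best_rank_initial[cid], report.best_rank_consensus[cid])
        for cid in eval_ids
        if report.best_rank_initial[cid] is not None
    ]
    if len(paired) >= 2:
        wilcoxon = compare_rankings([p[0] for p in paired], [p[1] for p in paired])
    else:
        wilcoxon = WilcoxonResult(False, None, None, 0, None)

    return BenchmarkResult(
        schema=schema,
        plan=plan,
        bank=bank,
        cell_scores=cell_scores,
        loo_choice=loo_choice,
        consensus=consensus,
        consensus_entries=used,
        report=report,
        wilcoxon=wilcoxon,
    )
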