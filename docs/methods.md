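# Methods

## Problem and data model

A docking engine produces, per complex, a list of candidate poses (decoys)
with an engine ordering (`initial_rank`). Each decoy carries a feature row —
by default 91 columns: 82 slots for externally computed physicochemical
descriptors (statistical potentials, energy terms, etc., supplied as input)
plus 9 cluster-size columns — and a CAPRI quality label, either given
directly or derived from fnat / ligand-RMSD / interface-RMSD with the
community thresholds (acceptable: fnat ≥ 0.1 and (L-RMSD ≤ 10 Å or
I-RMSD ≤ 4 Å); medium: fnat ≥ 0.3 and (≤ 5 or ≤ 2); high: fnat ≥ 0.5 and
(≤ 1 or ≤ 1)). The thresholds are a configuration dataclass so variants can
be swapped in. "Near-native" means acceptable or better throughout.

Decoy lists are truncated to the engine's top 500 poses before training:
the number of pairwise training constraints grows quadratically with decoys
per complex. A complex whose only near-natives fall outside the cut is
flagged (`has_near_native`) and excluded from retrieval denominators.

Missing descriptor cells (failed calculations) are imputed with the column
mean pooled over the decoy sets passed in; callers group by docking method
first, since descriptors behave differently per engine. Features are then
z-scored with mean/σ fitted once on the pooled training benchmark of one
docking method and applied unchanged to held-out or new decoys. Constant
columns get σ flagged and transform to zero rather than erroring, which
keeps degenerate fixtures usable.

## Geometry

Cluster-size features and scoring-time clusterings come from single-linkage
clustering of ligand Cα positions after least-squares (Kabsch)
superposition of each decoy's receptor onto a reference receptor (the first
decoy's receptor by default, standing in for the input structure).
Single linkage at cutoff t is exactly the connected components of the graph
with edges where RMSD ≤ t (inclusive at the cutoff; ids assigned by first
member index). Cluster sizes are computed at the nine cutoffs 3.0–7.0 Å in
0.5 Å steps; model scoring clusters at 3.5 Å. When coordinates are absent,
a precomputed distance matrix or clustering can be supplied instead.

## Ranking SVM

The optimizer solves the soft-margin pairwise ranking problem (see README
for the formulation) in the dual: maximize Σα_p − ½‖Σ α_p x_p‖² with
0 ≤ α_p ≤ c over the difference vectors x_p, by coordinate descent with
exact one-dimensional updates and a random coordinate order (fixed shuffle
seed, so training is deterministic). Convergence is certified by the duality
gap: iteration stops when (primal − dual)/max(1, |primal|) falls below the
tolerance, which bounds the distance of the reported objective from the
convex problem's global optimum. Defaults: tolerance 10⁻⁴, at most 20 000
passes, with an error (not a silent return) if the budget is exhausted.
Grid runs inside the pipeline use 10⁻³: coordinate descent has a slow tail
on the nearly rank-one pair Gram matrices that strongly collinear features
produce at large c, and rankings are insensitive to objective changes below
that level. Projection ties are broken by ascending `initial_rank`, so an
all-zero weight vector reproduces the engine's ordering. Within-category
pairs generate no constraints, there is no per-pair cost weighting, and all
cross-category pairs are used (no subsampling).

## Model scoring and selection

Per held-out complex, clusters at 3.5 Å are ordered by the ranking position
of their best member; r is the position of the first cluster whose top
member is near-native, and s_i = (log₁₀ n_c − log₁₀ r)/log₁₀ n_c, zero when
no cluster is topped by a near-native. Degenerate n_c = 1 (where the
formula is 0/0) scores 1 if that cluster's top decoy is near-native, else
0, consistent with the range endpoints. The relative total S = Σ(s_i − s̄_i)
uses, for each complex, the mean over the models whose selection set
contains it — under protocol A all models share one selection set; under
protocol B they differ, and this per-complex mean is the package's chosen
reading of an under-determined case. Ties in S break by model creation
index.

## Protocols, grid and evaluation

* Protocol A: base complexes split 2:1 into training/model-selection, 200
  repeats by default; a fixed update set is the external test set.
* Protocol B: all complexes split 2:1:1, 800 repeats by default, so each
  complex sits in ≈ repeats/4 test sets; a complex is only ever ranked by
  models whose test set contains it (never trained or selected on it), and
  the pipeline records the models behind every consensus so this purity is
  auditable.

Split sizes are floor-allocated by ratio with remainders given to training
first; the split plan derives from one integer seed via per-repeat
substreams (`numpy` SeedSequence spawning), so runs are reproducible.

The default metaparameter grid is 50 log-spaced c in [10⁻⁴, 10³] (endpoints
exact) × n = 1…50. For each grid cell the top-n models by S are
Schulze-aggregated per test complex, the consensus is scored with s_i, and
each complex's (c, n) is chosen by leave-one-out: the cell maximizing the
summed s_i of the other test complexes (ties toward smaller c, then smaller
n; a single-complex run falls back to the global argmax). The quantity
summed is the absolute per-complex score s_i of the consensus ranking — the
relative S would telescope to zero across a full ensemble and carries no
between-cell signal. A "server" mode instead retrains with the single
mode-average (c, n) pair, mirroring production deployments. Under protocol
B with very few repeats a complex may appear in no test set; the pipeline
then falls back to the engine ordering for it and warns.

Evaluation reports, at k = 1/10/100: retrieval rate (% of complexes with a
sampled near-native whose best near-native consensus rank ≤ k), success
rate (same numerator over all complexes), quality-upgrade counts (among
complexes with a near-native in the top k before and after, how many had
the top-ranked near-native move to a higher/lower CAPRI class), and a
two-sided Wilcoxon signed-rank test on paired best near-native ranks
(zero differences discarded; fewer than two non-zero pairs reported as
undefined).

## Schulze consensus

Strengths are computed as pure widest paths — max over directed paths of
the minimum edge weight — with the O(n³) Floyd–Warshall-style relaxation;
at n ≤ 500 decoys this is desk-scale and no sparse optimization is
attempted. Exact pairwise ties (equal opposing strengths) are broken by
lower mean rank across the ensemble, then by `initial_rank`. The emitted
total order sorts by pairwise win count, which can never contradict a
strict pairwise preference because the Schulze relation is transitive.
Ballots are always full rankings.

## Synthetic benchmarks

The generator emulates the statistical shape of a docking benchmark, not
its physics:

* latent quality per decoy, uniform in a fixed band per category
  (incorrect [0, 0.25), acceptable [0.25, 0.5), medium [0.5, 0.75),
  high [0.75, 1]);
* feature rows = quality · w*/‖w*‖ + isotropic Gaussian noise (σ = 0.1 by
  default). All feature columns, including the nine cluster-size slots,
  belong to this planted block; the slots are not derived from the
  generated coordinates, which exist to exercise the superposition/RMSD/
  clustering path independently;
* ligand Cα coordinates as Gaussian clouds (spread 0.5 Å per coordinate)
  around centres 20 Å apart on a line, so 3.5 Å single linkage recovers
  the planted clusters; each decoy additionally gets a random rigid
  transform of receptor+ligand so superposition is non-trivial;
* category fractions 0.94/0.03/0.02/0.01 and engine ordering = quality +
  Gaussian noise (σ = 3.0). The noise level was calibrated once, over 100
  synthetic complexes at the 200-decoy scale, so the simulated engine's
  top-1/top-10 retrieval (12% / 51%) lands in the band published docking
  engines occupy; it was not revisited afterwards.

What passing on this data shows: correct plumbing, correct optimization and
aggregation, and recoverability of a linear signal under noise. What it
does not show: performance on real decoys, where descriptors are noisy,
mutually correlated in structured ways, and only partially linear in
quality — headline success rates on real benchmarks require real decoys
plus externally computed descriptors and are explicitly out of scope.

A note on parameter-recovery checks: they compare the trained w with w* in
the *raw* feature space. Z-scoring rescales column j by 1/s_j, so the
planted direction's image under normalization is (u_j·s_j); as σ → 0 the
z-space optimum tends to sign(u_j), whose expected cosine with a Gaussian
u* is √(2/π) ≈ 0.8 regardless of fit quality — the comparison is only
meaningful pre-normalization. Per-column rescaling leaves rankings
unchanged in the noiseless limit, and the pipeline itself always trains on
z-scored features.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each property is non-trivial: oracle-equivalence
sweeps use ≤ 20-pair optimization instances, ≤ 6-node preference graphs and
≤ 25-point distance matrices; the end-to-end planted-signal run uses 20
complexes × 200 decoys (σ = 0.05) with 16 protocol-B repeats and a 3 × 3
(c, n) grid; the endpoint script uses a ten-cluster, ten-decoy set. The
full 50 × 50 grid with hundreds of repeats is exposed through the same API
and CLI and is simply a larger run of the identical code path.

## Known limitations

* Descriptor computation is out of scope; the 82 descriptor columns are
  opaque inputs.
* Interface-RMSD/fnat computation from structures is out of scope; labels
  or metrics are inputs.
* The coordinate path assumes atom-by-atom receptor correspondence across
  decoys (true for rigid-body docking output, Cα-only).
* Dual coordinate descent converges slowly at very large c on strongly
  collinear features; the iteration budget errs rather than returning an
  uncertified model.
* With unequal selection sets (protocol B), the relative score S depends on
  the package's choice of per-complex ensemble means documented above.
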