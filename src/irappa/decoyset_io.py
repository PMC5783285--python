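"""Decoy-set data model, TSV I/O, CAPRI labelling, imputation and z-scoring.

A :class:`DecoySet` holds everything known about one complex's docked poses:
the feature matrix (one row per decoy, one column per descriptor), CAPRI
quality labels, the docking engine's original ranks and, optionally, receptor
and ligand C-alpha coordinates. Feature tables are plain TSV with reserved
columns ``decoy_id``, ``initial_rank`` and either ``label`` or the raw quality
metrics ``fnat``, ``lrmsd``, ``irmsd`` from which labels are derived.

Missing feature cells (failed descriptor calculations) are carried as NaN
until :func:`impute_missing` replaces them with the column mean pooled over
the decoy sets of one docking method. Features are then z-scored with
parameters fitted on the training pool (:func:`fit_normalizer`) and applied
unchanged to held-out decoys (:func:`normalize`).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .defaults import CLUSTER_SIZE_CUTOFFS, N_DESCRIPTOR_SLOTS

__all__ = [
    "CapriCategory",
    "CapriThresholds",
    "DEFAULT_CAPRI_THRESHOLDS",
    "DecoySet",
    "DecoyTableError",
    "FeatureSchema",
    "capri_categorize",
    "default_schema",
    "fit_normalizer",
    "impute_missing",
    "normalize",
    "read_decoy_table",
    "truncate_to_top",
    "write_decoy_table",
]

RESERVED_COLUMNS = ("decoy_id", "initial_rank", "label", "fnat", "lrmsd", "irmsd")


class DecoyTableError(ValueError):
    """Raised for malformed decoy feature tables."""


class CapriCategory(enum.IntEnum):
    """CAPRI quality class of a docked pose, totally ordered.

    A pose is *near-native* when it is acceptable or better.
    """

    INCORRECT = 0
    ACCEPTABLE = 1
    MEDIUM = 2
    HIGH = 3

    @property
    def is_near_native(self) -> bool:
        return self >= CapriCategory.ACCEPTABLE

    @classmethod
    def from_name(cls, name: str) -> "CapriCategory":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise DecoyTableError(f"unknown CAPRI category {name!r}") from None


@dataclass(frozen=True)
class CapriThresholds:
    """Quality thresholds per CAPRI class.

    Each class requires ``fnat >= min_fnat`` and (``lrmsd <= max_lrmsd`` or
    ``irmsd <= max_irmsd``). Exposed as configuration so threshold variants
    can be swapped in; the defaults are the community-standard criteria.
    """

    acceptable: tuple[float, float, float] = (0.1, 10.0, 4.0)
    medium: tuple[float, float, float] = (0.3, 5.0, 2.0)
    high: tuple[float, float, float] = (0.5, 1.0, 1.0)


DEFAULT_CAPRI_THRESHOLDS = CapriThresholds()


def capri_categorize(
    fnat: float,
    lrmsd: float,
    irmsd: float,
    thresholds: CapriThresholds = DEFAULT_CAPRI_THRESHOLDS,
) -> CapriCategory:
    """Classify one pose from its fraction of native contacts and RMSDs.

    Returns the highest category whose criteria are met. ``fnat`` must lie in
    [0, 1]; both RMSDs (Angstrom) must be non-negative.
    """
    if not 0.0 <= fnat <= 1.0:
        raise ValueError(f"fnat must be in [0, 1], got {fnat}")
    if lrmsd < 0 or irmsd < 0:
        raise ValueError(f"RMSD values must be non-negative, got {lrmsd}, {irmsd}")
    for category, (min_fnat, max_l, max_i) in (
        (CapriCategory.HIGH, thresholds.high),
        (CapriCategory.MEDIUM, thresholds.medium),
        (CapriCategory.ACCEPTABLE, thresholds.acceptable),
    ):
        if fnat >= min_fnat and (lrmsd <= max_l or irmsd <= max_i):
            return category
    return CapriCategory.INCORRECT


@dataclass(eq=False)
class FeatureSchema:
    """Ordered feature-column names plus (optional) z-score parameters.

    The default schema is 91 columns wide: 82 placeholder slots for the
    externally computed physicochemical descriptors plus 9 cluster-size
    columns at single-linkage cutoffs 3.0-7.0 A. ``means``/``sigmas`` are
    fitted on a training pool by :func:`fit_normalizer`; constant columns
    (sigma = 0) are flagged and transform to zeros.
    """

    names: list[str]
    means: Optional[np.ndarray] = None
    sigmas: Optional[np.ndarray] = None

    @property
    def n_features(self) -> int:
        return len(self.names)

    @property
    def is_fitted(self) -> bool:
        return self.means is not None and self.sigmas is not None

    @property
    def constant_columns(self) -> np.ndarray:
        """Boolean mask of sigma = 0 columns (valid once fitted)."""
        if self.sigmas is None:
            raise ValueError("schema is not fitted")
        return self.sigmas == 0.0

    def to_json(self, path: str | Path) -> None:
        doc = {"names": list(self.names)}
        if self.is_fitted:
            doc["means"] = np.asarray(self.means).tolist()
            doc["sigmas"] = np.asarray(self.sigmas).tolist()
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        doc = json.loads(Path(path).read_text())
        means = np.asarray(doc["means"], dtype=float) if "means" in doc else None
        sigmas = np.asarray(doc["sigmas"], dtype=float) if "sigmas" in doc else None
        return cls(names=list(doc["names"]), means=means, sigmas=sigmas)


def default_schema(n_descriptors: int = N_DESCRIPTOR_SLOTS) -> FeatureSchema:
    """The 82 descriptor slots + 9 cluster-size columns (91 total)."""
    names = [f"desc_{i + 1:02d}" for i in range(n_descriptors)]
    names += [f"cluster_size_{cutoff:.1f}A" for cutoff in CLUSTER_SIZE_CUTOFFS]
    return FeatureSchema(names=names)


@dataclass(eq=False)
class DecoySet:
    """All decoys of one complex.

    ``features`` is ``(n_decoys, n_features)`` and may contain NaN before
    imputation. ``initial_ranks`` is the docking engine's own ordering, a
    permutation of ``1..n_decoys``. Coordinates, when present, are per-decoy
    C-alpha arrays of shape ``(n_decoys, n_atoms, 3)`` in Angstrom.
    """

    complex_id: str
    decoy_ids: list[str]
    features: np.ndarray
    labels: list[CapriCategory]
    initial_ranks: np.ndarray
    receptor_coords: Optional[np.ndarray] = None
    ligand_coords: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.initial_ranks = np.asarray(self.initial_ranks, dtype=int)
        n = len(self.decoy_ids)
        if n < 1:
            raise ValueError("a DecoySet needs at least one decoy")
        if len(set(self.decoy_ids)) != n:
            raise DecoyTableError(f"{self.complex_id}: duplicate decoy_id")
        if self.features.ndim != 2 or self.features.shape[0] != n:
            raise ValueError(f"{self.complex_id}: features must be ({n}, n_features)")
        if len(self.labels) != n or len(self.initial_ranks) != n:
            raise ValueError(f"{self.complex_id}: per-decoy containers differ in length")
        if sorted(self.initial_ranks.tolist()) != list(range(1, n + 1)):
            raise ValueError(f"{self.complex_id}: initial_ranks must be a permutation of 1..{n}")
        for coords in (self.receptor_coords, self.ligand_coords):
            if coords is not None and (coords.ndim != 3 or coords.shape[0] != n or coords.shape[2] != 3):
                raise ValueError(f"{self.complex_id}: coordinates must be (n_decoys, n_atoms, 3)")

    @property
    def n_decoys(self) -> int:
        return len(self.decoy_ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def label_codes(self) -> np.ndarray:
        return np.array([int(lab) for lab in self.labels], dtype=int)

    @property
    def near_native_mask(self) -> np.ndarray:
        return self.label_codes >= int(CapriCategory.ACCEPTABLE)

    @property
    def has_near_native(self) -> bool:
        """Whether the set contains at least one acceptable-or-better decoy."""
        return bool(self.near_native_mask.any())

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.features).any())

    def replace(self, **changes) -> "DecoySet":
        return dataclasses.replace(self, **changes)


def _parse_feature_cell(raw: object, row_id: str, column: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    text = str(raw).strip()
    if text == "" or text.lower() in ("na", "nan"):
        return math.nan
    try:
        return float(text)
    except ValueError:
        raise DecoyTableError(
            f"non-numeric feature cell at decoy {row_id!r}, column {column!r}: {raw!r}"
        ) from None


def read_decoy_table(
    path: str | Path,
    schema: Optional[FeatureSchema] = None,
    complex_id: Optional[str] = None,
    thresholds: CapriThresholds = DEFAULT_CAPRI_THRESHOLDS,
) -> DecoySet:
    """Read one complex's decoy feature table (TSV).

    The header must contain ``decoy_id``, ``initial_rank`` and either a
    ``label`` column or the three quality metrics ``fnat``/``lrmsd``/``irmsd``
    (labels are then derived with :func:`capri_categorize`; a ``label`` column
    wins if both are present). The remaining columns must match ``schema``
    order when a schema is given; otherwise they define the schema. Empty
    feature cells become NaN missing markers.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "decoy_id" not in frame.columns or "initial_rank" not in frame.columns:
        raise DecoyTableError(f"{path}: header must contain decoy_id and initial_rank")
    has_label = "label" in frame.columns
    has_metrics = all(c in frame.columns for c in ("fnat", "lrmsd", "irmsd"))
    if not has_label and not has_metrics:
        raise DecoyTableError(f"{path}: need a label column or fnat/lrmsd/irmsd columns")

    feature_names = [c for c in frame.columns if c not in RESERVED_COLUMNS]
    if schema is not None and feature_names != list(schema.names):
        raise DecoyTableError(
            f"{path}: feature columns do not match schema "
            f"(got {len(feature_names)}, expected {schema.n_features})"
        )

    decoy_ids = frame["decoy_id"].tolist()
    if len(set(decoy_ids)) != len(decoy_ids):
        dupes = sorted({d for d in decoy_ids if decoy_ids.count(d) > 1})
        raise DecoyTableError(f"{path}: repeated decoy_id {dupes[0]!r}")

    features = np.empty((len(decoy_ids), len(feature_names)))
    for j, name in enumerate(feature_names):
        col = frame[name].tolist()
        features[:, j] = [_parse_feature_cell(v, decoy_ids[i], name) for i, v in enumerate(col)]

    if has_label:
        labels = [CapriCategory.from_name(v) for v in frame["label"]]
    else:
        labels = [
            capri_categorize(float(f), float(l), float(i), thresholds)
            for f, l, i in zip(frame["fnat"], frame["lrmsd"], frame["irmsd"])
        ]
    try:
        initial_ranks = frame["initial_rank"].astype(int).to_numpy()
    except ValueError as exc:
        raise DecoyTableError(f"{path}: non-integer initial_rank ({exc})") from None

    return DecoySet(
        complex_id=complex_id if complex_id is not None else path.stem,
        decoy_ids=decoy_ids,
        features=features,
        labels=labels,
        initial_ranks=initial_ranks,
    )


def write_decoy_table(dset: DecoySet, path: str | Path, schema: Optional[FeatureSchema] = None) -> None:
    """Write a decoy set back to TSV (inverse of :func:`read_decoy_table`)."""
    names = list(schema.names) if schema is not None else [
        f"f{j + 1}" for j in range(dset.n_features)
    ]
    if len(names) != dset.n_features:
        raise ValueError("schema width does not match feature matrix")
    frame = pd.DataFrame({"decoy_id": dset.decoy_ids})
    frame["initial_rank"] = dset.initial_ranks
    frame["label"] = [lab.name.lower() for lab in dset.labels]
    for j, name in enumerate(names):
        col = dset.features[:, j]
        frame[name] = [("" if math.isnan(v) else repr(float(v))) for v in col]
    frame.to_csv(path, sep="\t", index=False)


def impute_missing(sets: Sequence[DecoySet]) -> list[DecoySet]:
    """Replace NaN feature cells by the column mean pooled over ``sets``.

    The pool should be the decoy sets of one docking method (imputation is
    per-method); callers group accordingly. A column with no observed value
    anywhere is an error. Non-missing cells are never altered.
    """
    if not sets:
        raise ValueError("impute_missing needs at least one decoy set")
    stacked = np.vstack([s.features for s in sets])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN handled below
        col_means = np.nanmean(stacked, axis=0)
    if np.isnan(col_means).any():
        bad = int(np.flatnonzero(np.isnan(col_means))[0])
        raise ValueError(f"feature column {bad} is entirely missing across the pool")
    out = []
    for s in sets:
        feats = s.features.copy()
        mask = np.isnan(feats)
        if mask.any():
            feats[mask] = np.broadcast_to(col_means, feats.shape)[mask]
        out.append(s.replace(features=feats))
    return out


def fit_normalizer(training_sets: Sequence[DecoySet], schema: FeatureSchema) -> FeatureSchema:
    """Fit per-column z-score parameters on the pooled training decoys.

    Imputation must already have been applied. Constant columns (sigma = 0)
    are flagged with a warning and later transform to zeros rather than
    erroring, which keeps degenerate fixtures usable.
    """
    if not training_sets:
        raise ValueError("fit_normalizer needs at least one training set")
    stacked = np.vstack([s.features for s in training_sets])
    if np.isnan(stacked).any():
        raise ValueError("normalizer fitting requires imputed (NaN-free) features")
    if stacked.shape[1] != schema.n_features:
        raise ValueError("feature width does not match schema")
    means = stacked.mean(axis=0)
    sigmas = stacked.std(axis=0)
    if (sigmas == 0.0).any():
        n_const = int((sigmas == 0.0).sum())
        warnings.warn(
            f"{n_const} constant feature column(s); z-scores set to 0 there",
            RuntimeWarning,
            stacklevel=2,
        )
    return FeatureSchema(names=list(schema.names), means=means, sigmas=sigmas)


def normalize(dset: DecoySet, schema: FeatureSchema) -> DecoySet:
    """Apply the schema's fitted z-score parameters to one decoy set.

    Held-out decoys are transformed with the training pool's mean and sigma,
    never their own. Constant columns map to zero.
    """
    if not schema.is_fitted:
        raise ValueError("schema has no fitted normalization parameters")
    if dset.n_features != schema.n_features:
        raise ValueError("feature width does not match schema")
    sigmas = np.where(schema.sigmas == 0.0, 1.0, schema.sigmas)
    z = (dset.features - schema.means) / sigmas
    z[:, schema.constant_columns] = 0.0
    return dset.replace(features=z)


def truncate_to_top(dset: DecoySet, limit: int) -> DecoySet:
    """Keep only decoys the docking engine ranked within ``limit``.

    Training cost grows quadratically with decoys per complex, hence the
    top-500 default upstream. Whether any near-native survives is reported by
    the returned set's ``has_near_native``; complexes where none does are
    excluded from retrieval statistics downstream.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    keep = np.flatnonzero(dset.initial_ranks <= limit)
    order = keep[np.argsort(dset.initial_ranks[keep])]
    return DecoySet(
        complex_id=dset.complex_id,
        decoy_ids=[dset.decoy_ids[i] for i in order],
        features=dset.features[order],
        labels=[dset.labels[i] for i in order],
        initial_ranks=dset.initial_ranks[order],
        receptor_coords=None if dset.receptor_coords is None else dset.receptor_coords[order],
        ligand_coords=None if dset.ligand_coords is None else dset.ligand_coords[order],
    )
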