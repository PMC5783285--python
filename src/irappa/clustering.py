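"""Receptor superposition, ligand-RMSD matrices and single-linkage clustering.

Docked poses of one complex share a receptor; after least-squares (Kabsch)
superposition of each decoy's receptor onto a reference, the ligand C-alpha
RMSD between every pair of decoys defines a distance matrix. Single-linkage
clustering of that matrix — connected components of the graph with an edge
wherever the distance is <= cutoff — yields pose clusters. Cluster sizes at
cutoffs 3.0-7.0 A (0.5 A steps) serve as nine extra descriptors, and the
3.5 A clustering is reused when scoring ranking models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.SVDSuperimposer import SVDSuperimposer
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .decoyset_io import DecoySet
from .defaults import CLUSTER_SIZE_CUTOFFS

__all__ = [
    "Clustering",
    "cluster_size_features",
    "ligand_rmsd_matrix",
    "load_ca_coordinates",
    "single_linkage",
    "superpose_receptor",
    "validate_distance_matrix",
    "write_ca_pdb",
]


def superpose_receptor(
    reference_receptor: np.ndarray,
    decoy_receptor: np.ndarray,
    decoy_ligand: np.ndarray,
) -> np.ndarray:
    """Transform a decoy's ligand into the reference receptor frame.

    Finds the rigid transform (rotation + translation, Kabsch least squares)
    that optimally superposes ``decoy_receptor`` onto ``reference_receptor``
    (atom-by-atom correspondence required, >= 3 atoms) and applies it to
    ``decoy_ligand``.
    """
    ref = np.asarray(reference_receptor, dtype=float)
    rec = np.asarray(decoy_receptor, dtype=float)
    lig = np.asarray(decoy_ligand, dtype=float)
    if ref.shape != rec.shape:
        raise ValueError(f"receptor arrays differ in shape: {ref.shape} vs {rec.shape}")
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise ValueError("receptors must be (n_atoms >= 3, 3) arrays")
    sup = SVDSuperimposer()
    sup.set(ref, rec)
    sup.run()
    rot, tran = sup.get_rotran()
    return lig @ rot + tran


def validate_distance_matrix(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Check symmetry, zero diagonal and non-negativity of an RMSD matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=atol):
        raise ValueError("distance matrix must have a zero diagonal")
    if (m < -atol).any():
        raise ValueError("distance matrix must be non-negative")
    return m


def ligand_rmsd_matrix(
    dset: DecoySet,
    reference_receptor: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Pairwise ligand C-alpha RMSD matrix after receptor superposition.

    Every decoy's receptor is superposed onto ``reference_receptor`` (the
    first decoy's receptor by default, standing in for the input receptor
    structure); entry (i, j) is then the plain coordinate RMSD between the
    transformed ligands of decoys i and j.
    """
    if dset.receptor_coords is None or dset.ligand_coords is None:
        raise ValueError(f"{dset.complex_id}: coordinates required for RMSD matrix")
    if reference_receptor is None:
        reference_receptor = dset.receptor_coords[0]
    ligs = np.stack(
        [
            superpose_receptor(reference_receptor, dset.receptor_coords[i], dset.ligand_coords[i])
            for i in range(dset.n_decoys)
        ]
    )
    # RMSD_ij = sqrt(mean_a |L_ia - L_ja|^2), via the Gram-matrix identity
    sq = np.einsum("iad,iad->i", ligs, ligs)
    cross = np.einsum("iad,jad->ij", ligs, ligs)
    d2 = (sq[:, None] + sq[None, :] - 2.0 * cross) / ligs.shape[1]
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


@dataclass(eq=False)
class Clustering:
    """Single-linkage partition at one cutoff.

    ``assignment`` maps decoy index to a cluster id in ``1..n_clusters``;
    two decoys share a cluster iff they are connected by a chain of pairwise
    distances <= cutoff. Ids are contiguous, assigned by order of each
    cluster's first member index.
    """

    cutoff: float
    assignment: np.ndarray
    n_clusters: int

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster_id)

    def sizes(self) -> np.ndarray:
        """Cluster size per decoy (size of the cluster each decoy belongs to)."""
        counts = np.bincount(self.assignment, minlength=self.n_clusters + 1)
        return counts[self.assignment]


def single_linkage(matrix: np.ndarray, cutoff: float) -> Clustering:
    """Single-linkage clustering: connected components of the <=cutoff graph.

    Distances exactly at the cutoff merge (inclusive convention, matching
    connected-component semantics).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    m = validate_distance_matrix(matrix)
    adj = csr_matrix(m <= cutoff)
    _, raw_labels = connected_components(adj, directed=False)
    # relabel contiguously, ordered by first member's decoy index
    assignment = np.zeros(m.shape[0], dtype=int)
    next_id = 0
    seen: dict[int, int] = {}
    for i, lab in enumerate(raw_labels):
        if lab not in seen:
            next_id += 1
            seen[lab] = next_id
        assignment[i] = seen[lab]
    return Clustering(cutoff=float(cutoff), assignment=assignment, n_clusters=next_id)


def cluster_size_features(
    dset: DecoySet,
    cutoffs: Sequence[float] = CLUSTER_SIZE_CUTOFFS,
    matrix: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-decoy cluster sizes at each cutoff, as feature columns.

    Returns an ``(n_decoys, len(cutoffs))`` array, one column per cutoff in
    the given order (3.0-7.0 A by default). A precomputed distance matrix may
    be supplied when coordinates are absent.
    """
    if matrix is None:
        matrix = ligand_rmsd_matrix(dset)
    else:
        matrix = validate_distance_matrix(matrix)
    cols = [single_linkage(matrix, c).sizes() for c in cutoffs]
    return np.column_stack(cols).astype(float)


def load_ca_coordinates(
    path: str | Path,
    receptor_chains: Sequence[str],
    ligand_chains: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Read receptor and ligand C-alpha coordinates from one decoy PDB file.

    Chain identifiers designate which chains belong to the receptor and which
    to the ligand. Returns two ``(n_atoms, 3)`` arrays.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("decoy", str(path))
    model = next(structure.get_models())
    rec, lig = [], []
    for chain in model:
        target = None
        if chain.id in receptor_chains:
            target = rec
        elif chain.id in ligand_chains:
            target = lig
        if target is None:
            continue
        for residue in chain:
            if "CA" in residue:
                target.append(residue["CA"].get_coord())
    if not rec or not lig:
        raise ValueError(f"{path}: no C-alpha atoms for receptor or ligand chains")
    return np.asarray(rec, dtype=float), np.asarray(lig, dtype=float)


def write_ca_pdb(
    path: str | Path,
    receptor: np.ndarray,
    ligand: np.ndarray,
    receptor_chain: str = "A",
    ligand_chain: str = "B",
) -> None:
    """Write C-alpha-only coordinates as a minimal PDB file (ATOM records)."""
    lines = []
    serial = 1
    for chain, coords in ((receptor_chain, receptor), (ligand_chain, ligand)):
        for resseq, (x, y, z) in enumerate(np.asarray(coords, dtype=float), start=1):
            lines.append(
                f"ATOM  {serial:5d}  CA  GLY {chain}{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
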