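"""Similarity, clustering and common-substructure analysis of the
fittest designed ligands.

Pools of top candidates from independent evolutionary runs tend to
converge on shared chemical features; this module makes those features
visible: pairwise Tanimoto similarity over hashed path fingerprints,
average-linkage hierarchical clustering with a distance cut, the
maximum common substructure of each cluster, and min-max normalized
relative fitness for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFMCS
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .fragments import LigandGraph

__all__ = [
    "ClusterReport",
    "fingerprint",
    "similarity_matrix",
    "cluster",
    "mcs_per_cluster",
    "normalized_fitness",
    "analyze_fittest",
]

FP_SIZE = 2048
FP_MAX_PATH = 7


def _as_mol(obj) -> Chem.Mol:
    if isinstance(obj, Chem.Mol):
        return obj
    if isinstance(obj, LigandGraph):
        return obj.to_mol()
    mol = Chem.MolFromSmiles(str(obj))
    if mol is None:
        raise ValueError(f"unparseable SMILES {obj!r}")
    return mol


def fingerprint(mol_or_smiles) -> DataStructs.ExplicitBitVect:
    """Hashed path-based binary fingerprint (2048 bits, paths up to 7)."""
    return Chem.RDKFingerprint(_as_mol(mol_or_smiles), maxPath=FP_MAX_PATH, fpSize=FP_SIZE)


def similarity_matrix(ligands: Sequence) -> np.ndarray:
    """Pairwise Tanimoto similarity; symmetric with unit diagonal."""
    if len(ligands) < 2:
        raise ValueError("need at least two ligands for a similarity matrix")
    fps = [fingerprint(l) for l in ligands]
    n = len(fps)
    out = np.eye(n)
    for i in range(n):
        if i + 1 < n:
            row = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
            out[i, i + 1 :] = row
            out[i + 1 :, i] = row
    return out


def cluster(
    matrix: np.ndarray, cut: float = 0.6
) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage agglomerative clustering on distance 1 - similarity.

    Returns (flat cluster labels at the ``cut`` distance threshold,
    scipy linkage matrix).  Inputs should be supplied in a fixed key
    order; scipy's linkage is deterministic given the matrix.
    """
    matrix = np.asarray(matrix, float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    dist = 1.0 - matrix
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    return labels, Z


@dataclass(frozen=True)
class MCSResult:
    smarts: str
    num_atoms: int
    num_bonds: int
    timed_out: bool


def mcs_per_cluster(
    clusters: Mapping[int, Sequence],
    timeout_s: int = 10,
) -> dict[int, MCSResult]:
    """Largest connected common substructure per cluster.

    Atoms match by element, bonds by order, ring bonds only to ring
    bonds.  A singleton cluster's MCS is the molecule itself.  The
    search is capped at ``timeout_s`` per cluster; on timeout the
    best-so-far pattern is returned and flagged.
    """
    out: dict[int, MCSResult] = {}
    for label, members in clusters.items():
        mols = [_as_mol(m) for m in members]
        if not mols:
            raise ValueError(f"cluster {label} is empty")
        if len(mols) == 1:
            m = mols[0]
            out[label] = MCSResult(
                smarts=Chem.MolToSmarts(m),
                num_atoms=m.GetNumAtoms(),
                num_bonds=m.GetNumBonds(),
                timed_out=False,
            )
            continue
        res = rdFMCS.FindMCS(
            mols,
            atomCompare=rdFMCS.AtomCompare.CompareElements,
            bondCompare=rdFMCS.BondCompare.CompareOrder,
            ringMatchesRingOnly=True,
            timeout=timeout_s,
        )
        out[label] = MCSResult(
            smarts=res.smartsString,
            num_atoms=res.numAtoms,
            num_bonds=res.numBonds,
            timed_out=res.canceled,
        )
    return out


def normalized_fitness(values: Sequence[float]) -> np.ndarray:
    """Min-max scaling to [0, 1]; the best candidate maps to 1."""
    v = np.asarray(values, float)
    span = v.max() - v.min()
    if span == 0:
        return np.ones_like(v)
    return (v - v.min()) / span


@dataclass
class ClusterReport:
    keys: list[str]
    similarity: np.ndarray
    linkage: np.ndarray
    labels: np.ndarray
    mcs: dict[int, MCSResult]
    relative_fitness: np.ndarray
    cut: float

    def members(self, label: int) -> list[str]:
        return [k for k, l in zip(self.keys, self.labels) if l == label]

    def verify_mcs(self, mols: Mapping[str, Chem.Mol]) -> bool:
        """Every reported MCS must embed in every cluster member."""
        for label, res in self.mcs.items():
            patt = Chem.MolFromSmarts(res.smarts)
            if patt is None:
                return False
            for key in self.members(label):
                if not mols[key].HasSubstructMatch(patt):
                    return False
        return True


def analyze_fittest(
    candidates: Sequence[tuple[str, object, float]],
    cut: float = 0.6,
    mcs_timeout_s: int = 10,
) -> ClusterReport:
    """Full fittest-set analysis.

    ``candidates``: (key, molecule-or-smiles-or-LigandGraph, fitness)
    triples.  Input is sorted by key first so the report is independent
    of the supplied order.
    """
    ordered = sorted(candidates, key=lambda t: t[0])
    keys = [k for k, _m, _f in ordered]
    mols = {k: _as_mol(m) for k, m, _f in ordered}
    fits = [f for _k, _m, f in ordered]
    sim = similarity_matrix([mols[k] for k in keys])
    labels, Z = cluster(sim, cut=cut)
    groups: dict[int, list[Chem.Mol]] = {}
    for k, l in zip(keys, labels):
        groups.setdefault(int(l), []).append(mols[k])
    mcs = mcs_per_cluster(groups, timeout_s=mcs_timeout_s)
    return ClusterReport(
        keys=keys,
        similarity=sim,
        linkage=Z,
        labels=labels,
        mcs=mcs,
        relative_fitness=normalized_fitness(fits),
        cut=cut,
    )
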