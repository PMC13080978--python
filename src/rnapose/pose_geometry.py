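"""Scaffold symmetry handling and symmetry-corrected pose distances.

Docked poses of a congeneric series are compared on the atoms of their
common scaffold.  A symmetric scaffold (the two-fold diamidine-like core of
the series) makes the naive atom-by-atom RMSD overestimate the distance
between poses whose arms are swapped, so the RMSD is minimised over all
element- and bond-preserving permutations of the scaffold atoms (the
coloured-graph automorphisms).  Distances are computed **in the receptor
frame, without superposition**: docked poses share the receptor coordinate
system, and superposing them would erase exactly the binding-site placement
the clustering is meant to resolve.  A superposed variant is available
behind a flag for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .clustering import DistanceMatrix
from .io_formats import LigandPose

logger = logging.getLogger(__name__)

AUTOMORPHISM_CAP = 10_000


@dataclass
class SymmetryGroup:
    """Enumerated scaffold automorphisms (always containing the identity).

    Each permutation ``p`` maps scaffold position k to position p[k]; applying
    ``coords[p]`` re-orders a pose's scaffold coordinates by the symmetry.
    """

    permutations: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        if not self.permutations:
            raise ValueError("symmetry group must not be empty")
        n = len(self.permutations[0])
        ident = tuple(range(n))
        if ident not in self.permutations:
            raise ValueError("symmetry group must contain the identity")

    def __len__(self) -> int:
        return len(self.permutations)


@dataclass
class PoseDistanceMatrix:
    matrix: DistanceMatrix
    pose_keys: list[tuple[str, str]]       # (ligand_id, pose_id) per row


def scaffold_automorphisms(
    bonds: Sequence[tuple[int, int]], elements: Sequence[str]
) -> SymmetryGroup:
    """All element-preserving automorphisms of the scaffold bond graph.

    Enumerated deterministically (VF2 on the element-coloured graph, results
    sorted); more than 10,000 automorphisms aborts with a hint to supply a
    manual permutation list.
    """
    g = nx.Graph()
    for i, e in enumerate(elements):
        g.add_node(i, element=e)
    g.add_edges_from((int(i), int(j)) for i, j in bonds)
    if g.number_of_nodes() and not nx.is_connected(g):
        raise ValueError("scaffold bond graph must be connected")
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"])
    perms: set[tuple[int, ...]] = set()
    n = len(elements)
    for mapping in matcher.isomorphisms_iter():
        perms.add(tuple(mapping[i] for i in range(n)))
        if len(perms) > AUTOMORPHISM_CAP:
            raise ValueError(
                f"more than {AUTOMORPHISM_CAP} scaffold automorphisms; "
                "supply an explicit permutation list instead")
    return SymmetryGroup(sorted(perms))


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def min_symmetry_rmsd(
    pose_a: LigandPose,
    pose_b: LigandPose,
    group: SymmetryGroup,
    superpose: bool = False,
) -> float:
    """Minimum scaffold RMSD over the symmetry group, in the receptor frame.

    The RMSD is evaluated atom-by-atom between pose A's scaffold and every
    symmetry-permuted copy of pose B's scaffold, and the minimum is kept.
    With ``superpose=True`` each permuted comparison is preceded by an
    optimal rigid superposition (sensitivity analysis only).
    """
    xa = pose_a.scaffold_coords()
    xb = pose_b.scaffold_coords()
    if xa.shape != xb.shape:
        raise ValueError("scaffold size mismatch between poses")
    best = np.inf
    for perm in group.permutations:
        xb_p = xb[list(perm)]
        if superpose:
            ca, cb = xa.mean(axis=0), xb_p.mean(axis=0)
            rot, _ = Rotation.align_vectors(xa - ca, xb_p - cb)
            val = _rmsd(xa - ca, rot.apply(xb_p - cb))
        else:
            val = _rmsd(xa, xb_p)
        best = min(best, val)
    return best


def pose_distance_matrix(
    poses: Sequence[LigandPose], group: SymmetryGroup
) -> PoseDistanceMatrix:
    """Symmetric matrix of ``min_symmetry_rmsd`` over all pose pairs.

    The scaffold is common to the whole congeneric series, so distances are
    defined across ligands; substituent atoms never enter the matrix.  The
    computation is vectorised: in-frame RMSD equals the Euclidean distance of
    flattened scaffold coordinates divided by sqrt(m), so each permutation
    contributes one ``cdist`` call and the elementwise minimum is kept.
    """
    if not poses:
        raise ValueError("no poses")
    m = len(poses[0].scaffold_atoms)
    coords = np.array([p.scaffold_coords() for p in poses])       # (n, m, 3)
    if any(len(p.scaffold_atoms) != m for p in poses):
        raise ValueError("inconsistent scaffold sizes")
    flat = coords.reshape(len(poses), 3 * m)
    best = None
    for perm in group.permutations:
        flat_p = coords[:, list(perm), :].reshape(len(poses), 3 * m)
        d = cdist(flat, flat_p) / np.sqrt(m)
        best = d if best is None else np.minimum(best, d)
    # numerical symmetrisation: the group is closed under inversion, so the
    # matrix is symmetric up to floating-point noise
    best = np.minimum(best, best.T)
    np.fill_diagonal(best, 0.0)
    dm = DistanceMatrix(best, metric_tag="pose_min_rmsd")
    keys = [(p.ligand_id, p.pose_id) for p in poses]
    return PoseDistanceMatrix(dm, keys)


def pose_coordinate_pca(poses: Sequence[LigandPose], n_components: int = 2):
    """PCA on flattened scaffold coordinates (3·m features per pose).

    Returns ``(scores, explained_variance_ratio, tags)`` where tags is a list
    of (ligand_id, program_tag, conformation_tag) per pose, for binding-mode
    maps coloured by docking program or receptor conformation.
    """
    from .trends import fit_pca   # local import to avoid a cycle

    if len(poses) < 2:
        raise ValueError("need at least two poses for PCA")
    feats = np.array([p.scaffold_coords().ravel() for p in poses])
    model = fit_pca(feats, n_components=min(n_components, feats.shape[0] - 1,
                                            feats.shape[1]))
    tags = [(p.ligand_id, p.program_tag, p.conformation_tag) for p in poses]
    return model.scores, model.explained_variance_ratio, tags
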