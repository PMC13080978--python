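"""Geometric RNA-ligand interaction typing and distance-binned fingerprints.

Seven noncovalent interaction categories are detected between a docked
ligand pose and an RNA conformation: hydrogen bonds, halogen bonds,
lipophilic contacts, cation-anion pairs, pi-stacking, pi-cation and
pi-anion.  Interaction *centers* are assigned deterministically from
elements, bonds, formal charges and (for RNA) a built-in per-nucleotide
dictionary of donors, acceptors, phosphate anions and aromatic rings.  Each
detected interaction carries a characteristic distance; per pose these are
histogrammed per category from 2 to 8 Å in 80 bins, and the flattened
7 x 80 bin populations are the fingerprint features for the downstream PCA.

The geometric rule table (cutoffs and angular criteria) is a documented
package choice; every cutoff is overridable through :class:`RuleTable`.
When a molecule carries no explicit hydrogens the hydrogen-bond angular
criterion is skipped and distance-only detection applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io_formats import LigandPose, RnaModel

logger = logging.getLogger(__name__)

CATEGORY_ORDER: tuple[str, ...] = (
    "hydrogen_bond", "halogen_bond", "lipophilic", "cation_anion",
    "pi_stacking", "pi_cation", "pi_anion",
)
CATEGORY_INDEX = {c: i for i, c in enumerate(CATEGORY_ORDER)}

HALOGENS = {"Cl", "Br", "I"}

# Per-nucleotide typing dictionary (heavy-atom names).
BASE_DONORS = {"A": ("N6",), "U": ("N3",), "G": ("N1", "N2"), "C": ("N4",)}
BASE_ACCEPTORS = {"A": ("N1", "N3", "N7"), "U": ("O2", "O4"),
                  "G": ("O6", "N3", "N7"), "C": ("O2", "N3")}
SUGAR_DONORS = ("O2'",)
SUGAR_ACCEPTORS = ("O2'", "O4'")
PHOSPHATE_ANIONS = ("OP1", "OP2", "O1P", "O2P")          # non-bridging oxygens
PHOSPHATE_NAMES = {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P"}
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
PURINE_RING5 = ("C4", "C5", "N7", "C8", "N9")
PURINES = {"A", "G"}
BASE_CARBONS = ("C2", "C4", "C5", "C6", "C8")


@dataclass
class RuleTable:
    """Geometric cutoffs of the seven categories (Å and degrees)."""

    hbond_max: float = 3.9
    hbond_angle_min: float = 100.0          # D-H...A angle at the hydrogen
    halogen_max: float = 4.0
    halogen_angle_min: float = 140.0        # C-X...A angle at the halogen
    lipophilic_core: float = 4.5            # classic lipophilic distance
    lipophilic_max: float = 8.0             # detection records the full range
    cation_anion_max: float = 5.5
    pi_stack_max: float = 5.5
    pi_stack_planar_max: float = 30.0
    pi_stack_tshape_min: float = 60.0
    pi_stack_offset_max: float = 2.5
    pi_cation_max: float = 6.0
    pi_cation_angle_max: float = 40.0       # centroid->charge vs ring normal
    pi_anion_max: float = 5.5


@dataclass
class FingerprintConfig:
    d_min: float = 2.0
    d_max: float = 8.0
    n_bins: int = 80

    def __post_init__(self) -> None:
        if self.d_max <= self.d_min:
            raise ValueError("d_max must exceed d_min")
        if self.n_bins < 1:
            raise ValueError("n_bins must be at least 1")

    @property
    def bin_width(self) -> float:
        return (self.d_max - self.d_min) / self.n_bins

    def bin_edges(self) -> np.ndarray:
        return self.d_min + self.bin_width * np.arange(self.n_bins + 1)


@dataclass
class Ring:
    members: tuple          # atom labels
    centroid: np.ndarray
    normal: np.ndarray      # unit length


@dataclass
class InteractionCenters:
    """Typed interaction centers of one molecule.

    Positions are (n, 3) arrays; ``labels`` identify the participants — for
    RNA a (residue_index, moiety, atom_name) triple, for ligands the atom
    index (or an index tuple for group centroids).
    """

    donor_pos: np.ndarray
    donor_labels: list
    donor_h: list            # per donor: (k, 3) array of H positions (may be empty)
    acceptor_pos: np.ndarray
    acceptor_labels: list
    halogen_x_pos: np.ndarray
    halogen_c_pos: np.ndarray
    halogen_labels: list
    cation_pos: np.ndarray
    cation_labels: list
    anion_pos: np.ndarray
    anion_labels: list
    hydrophobic_pos: np.ndarray
    hydrophobic_labels: list
    rings: list[Ring]
    has_explicit_h: bool


@dataclass
class Interaction:
    category: str
    distance: float
    ligand_participant: object
    rna_residue: int
    rna_moiety: str
    core: bool = True        # False for lipophilic contacts beyond the core cutoff


def _empty() -> np.ndarray:
    return np.zeros((0, 3))


def _stack(rows: list) -> np.ndarray:
    return np.array(rows, dtype=float) if rows else _empty()


def _plane_normal(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit normal of the best-fit plane and the max out-of-plane residual."""
    c = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - c)
    normal = vt[-1]
    resid = float(np.abs((points - c) @ normal).max()) if len(points) > 3 else 0.0
    return normal / np.linalg.norm(normal), resid


# ---------------------------------------------------------------------------
# Center assignment
# ---------------------------------------------------------------------------

def assign_rna_centers(model: RnaModel) -> InteractionCenters:
    """Type the interaction centers of an RNA conformation.

    Donors/acceptors come from the per-nucleotide dictionary (base edges plus
    the sugar 2'-hydroxyl); the non-bridging phosphate oxygens are anion
    centers and hydrogen-bond acceptors; base carbons are the lipophilic
    partners; base rings supply the aromatic systems.  RNA inputs typically
    carry no hydrogens, so donor geometry is distance-only.
    """
    donors, donor_labels = [], []
    acceptors, acceptor_labels = [], []
    anions, anion_labels = [], []
    hydro, hydro_labels = [], []
    rings: list[Ring] = []
    for res in model.residues:
        base = res.name
        for name in BASE_DONORS.get(base, ()):
            if res.has_atom(name):
                donors.append(res.atom_position(name))
                donor_labels.append((res.index, "base", name))
        for name in BASE_ACCEPTORS.get(base, ()):
            if res.has_atom(name):
                acceptors.append(res.atom_position(name))
                acceptor_labels.append((res.index, "base", name))
        for name in SUGAR_DONORS:
            if res.has_atom(name):
                donors.append(res.atom_position(name))
                donor_labels.append((res.index, "sugar", name))
        for name in SUGAR_ACCEPTORS:
            if res.has_atom(name):
                acceptors.append(res.atom_position(name))
                acceptor_labels.append((res.index, "sugar", name))
        for name in PHOSPHATE_ANIONS:
            if res.has_atom(name):
                pos = res.atom_position(name)
                anions.append(pos)
                anion_labels.append((res.index, "phosphate", name))
                acceptors.append(pos)
                acceptor_labels.append((res.index, "phosphate", name))
        for name in BASE_CARBONS:
            if res.has_atom(name):
                hydro.append(res.atom_position(name))
                hydro_labels.append((res.index, "base", name))
        ring_defs = [PYRIMIDINE_RING]
        if base in PURINES:
            ring_defs.append(PURINE_RING5)
        for ring_names in ring_defs:
            present = [n for n in ring_names if res.has_atom(n)]
            if len(present) < 3:
                continue
            pts = np.array([res.atom_position(n) for n in present])
            normal, resid = _plane_normal(pts)
            if resid > 0.35:
                logger.warning("residue %d: non-planar ring skipped", res.index)
                continue
            rings.append(Ring(tuple((res.index, "base", n) for n in present),
                              pts.mean(axis=0), normal))
    return InteractionCenters(
        donor_pos=_stack(donors), donor_labels=donor_labels,
        donor_h=[np.zeros((0, 3))] * len(donors),
        acceptor_pos=_stack(acceptors), acceptor_labels=acceptor_labels,
        halogen_x_pos=_empty(), halogen_c_pos=_empty(), halogen_labels=[],
        cation_pos=_empty(), cation_labels=[],
        anion_pos=_stack(anions), anion_labels=anion_labels,
        hydrophobic_pos=_stack(hydro), hydrophobic_labels=hydro_labels,
        rings=rings, has_explicit_h=False)


@dataclass
class LigandTyping:
    """Structural (geometry-free) typing of a ligand topology.

    Shared by every pose of a ligand — and across a congeneric series with a
    common topology — so per-pose center assignment reduces to coordinate
    lookups.
    """

    donor_idx: list[int]
    donor_h_idx: list[list[int]]
    acceptor_idx: list[int]
    halogen_x_idx: list[int]
    halogen_c_idx: list[int]
    hydrophobic_idx: list[int]
    cation_groups: list[tuple[int, ...]]
    anion_groups: list[tuple[int, ...]]
    ring_members: list[tuple[int, ...]]
    has_explicit_h: bool


def ligand_typing(
    elements: Sequence[str],
    bonds: Sequence[tuple[int, int, int]],
    formal_charges: Sequence[int],
) -> LigandTyping:
    """Type a ligand topology (see :func:`assign_ligand_centers`)."""
    n = len(elements)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j, _ in bonds:
        adj[i].append(j)
        adj[j].append(i)
    has_h = "H" in elements

    donor_idx, donor_h_idx = [], []
    acceptor_idx = []
    hal_x, hal_c = [], []
    hydro = []
    for i, e in enumerate(elements):
        if e in ("N", "O"):
            h_here = [j for j in adj[i] if elements[j] == "H"]
            if (has_h and h_here) or not has_h:
                donor_idx.append(i)
                donor_h_idx.append(h_here)
            if formal_charges[i] <= 0:
                acceptor_idx.append(i)
        elif e in HALOGENS:
            carbons = [j for j in adj[i] if elements[j] == "C"]
            if carbons:
                hal_x.append(i)
                hal_c.append(carbons[0])
        elif e == "C":
            polar = any(elements[j] in ("N", "O") or elements[j] in HALOGENS
                        or formal_charges[j] != 0 for j in adj[i])
            if not polar and formal_charges[i] == 0:
                hydro.append(i)

    def charged_group(i: int, partner: str) -> frozenset[int]:
        for j in adj[i]:
            if elements[j] != "C":
                continue
            partners = [k for k in adj[j] if elements[k] == partner]
            if len(partners) >= 2:
                return frozenset([j, *partners])
        return frozenset([i])

    cation_groups: set[frozenset[int]] = set()
    anion_groups: set[frozenset[int]] = set()
    for i, q in enumerate(formal_charges):
        if q > 0:
            cation_groups.add(charged_group(i, "N"))
        elif q < 0:
            anion_groups.add(charged_group(i, "O"))

    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((i, j) for i, j, _ in bonds)
    rings: set[tuple[int, ...]] = set()
    for cyc in nx.minimum_cycle_basis(g):
        if len(cyc) in (5, 6):
            rings.add(tuple(sorted(cyc)))

    return LigandTyping(
        donor_idx=donor_idx, donor_h_idx=donor_h_idx,
        acceptor_idx=acceptor_idx,
        halogen_x_idx=hal_x, halogen_c_idx=hal_c,
        hydrophobic_idx=hydro,
        cation_groups=[tuple(sorted(s)) for s in sorted(cation_groups, key=sorted)],
        anion_groups=[tuple(sorted(s)) for s in sorted(anion_groups, key=sorted)],
        ring_members=sorted(rings),
        has_explicit_h=has_h)


def assign_ligand_centers(
    pose: LigandPose, typing: LigandTyping | None = None
) -> InteractionCenters:
    """Type the interaction centers of a ligand pose.

    Typing needs only elements, bonds and formal charges.  N/O atoms are
    hydrogen-bond donors when they carry an explicit hydrogen, or — in the
    implicit-hydrogen regime (no H atoms anywhere in the molecule) — always;
    acceptors are N/O atoms without positive formal charge.  Positively
    charged groups (the charged atom, merged into an adjacent C(N,N)
    resonance group when present) become cation centers at the group
    centroid; negatively charged groups mirror this for anions.  Carbons not
    bonded to N/O/halogen/charged atoms are the lipophilic centers, and 5- or
    6-membered near-planar rings supply the aromatic systems.
    """
    if typing is None:
        typing = ligand_typing(pose.elements, pose.bonds, pose.formal_charges)
    c = pose.coords
    donor_h = [c[h].reshape(-1, 3) for h in typing.donor_h_idx]
    cations = [c[list(g)].mean(axis=0) for g in typing.cation_groups]
    anions = [c[list(g)].mean(axis=0) for g in typing.anion_groups]
    rings = []
    for members in typing.ring_members:
        pts = c[list(members)]
        normal, resid = _plane_normal(pts)
        if resid > 0.35:
            continue
        rings.append(Ring(tuple(members), pts.mean(axis=0), normal))
    return InteractionCenters(
        donor_pos=c[typing.donor_idx].reshape(-1, 3),
        donor_labels=list(typing.donor_idx), donor_h=donor_h,
        acceptor_pos=c[typing.acceptor_idx].reshape(-1, 3),
        acceptor_labels=list(typing.acceptor_idx),
        halogen_x_pos=c[typing.halogen_x_idx].reshape(-1, 3),
        halogen_c_pos=c[typing.halogen_c_idx].reshape(-1, 3),
        halogen_labels=list(typing.halogen_x_idx),
        cation_pos=_stack(cations), cation_labels=list(typing.cation_groups),
        anion_pos=_stack(anions), anion_labels=list(typing.anion_groups),
        hydrophobic_pos=c[typing.hydrophobic_idx].reshape(-1, 3),
        hydrophobic_labels=list(typing.hydrophobic_idx),
        rings=rings, has_explicit_h=typing.has_explicit_h)


def assign_centers(molecule: LigandPose | RnaModel) -> InteractionCenters:
    """Dispatch: ligand-pose or RNA-model center typing."""
    if isinstance(molecule, LigandPose):
        return assign_ligand_centers(molecule)
    return assign_rna_centers(molecule)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two vectors."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return 0.0
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _pairs_within(pa: np.ndarray, pb: np.ndarray, cutoff: float):
    if len(pa) == 0 or len(pb) == 0:
        return np.zeros((0, 2), dtype=int), np.zeros(0)
    d = cdist(pa, pb)
    ii, jj = np.nonzero(d <= cutoff)
    return np.stack([ii, jj], axis=1), d[ii, jj]


def detect_interactions(
    pose: LigandPose,
    rna: RnaModel,
    rules: RuleTable | None = None,
    ligand_centers: InteractionCenters | None = None,
    rna_centers: InteractionCenters | None = None,
) -> list[Interaction]:
    """Detect all seven interaction categories between a pose and the RNA.

    Precomputed centers can be passed in to amortise typing across many
    poses against one conformation.  Every returned interaction carries the
    category's characteristic distance: donor-acceptor for hydrogen bonds,
    X...acceptor for halogen bonds, C...C for lipophilic contacts,
    charge-center distances for cation-anion, centroid-centroid for
    pi-stacking, and charge-to-centroid for pi-cation / pi-anion.
    """
    if rules is None:
        rules = RuleTable()
    lc = ligand_centers if ligand_centers is not None else assign_ligand_centers(pose)
    rc = rna_centers if rna_centers is not None else assign_rna_centers(rna)
    out: list[Interaction] = []

    def rna_lab(lab):
        return lab[0], lab[1]

    # hydrogen bonds: ligand donor -> RNA acceptor
    pairs, dists = _pairs_within(lc.donor_pos, rc.acceptor_pos, rules.hbond_max)
    for (i, j), d in zip(pairs, dists):
        if lc.has_explicit_h and len(lc.donor_h[i]):
            dpos = lc.donor_pos[i]
            apos = rc.acceptor_pos[j]
            ok = any(_angle(dpos - h, apos - h) >= rules.hbond_angle_min
                     for h in lc.donor_h[i])
            if not ok:
                continue
        res, moi = rna_lab(rc.acceptor_labels[j])
        out.append(Interaction("hydrogen_bond", float(d),
                               lc.donor_labels[i], res, moi))
    # hydrogen bonds: RNA donor -> ligand acceptor (distance-only: RNA
    # inputs carry no explicit hydrogens)
    pairs, dists = _pairs_within(rc.donor_pos, lc.acceptor_pos, rules.hbond_max)
    for (i, j), d in zip(pairs, dists):
        res, moi = rna_lab(rc.donor_labels[i])
        out.append(Interaction("hydrogen_bond", float(d),
                               lc.acceptor_labels[j], res, moi))

    # halogen bonds
    pairs, dists = _pairs_within(lc.halogen_x_pos, rc.acceptor_pos,
                                 rules.halogen_max)
    for (i, j), d in zip(pairs, dists):
        x = lc.halogen_x_pos[i]
        ang = _angle(lc.halogen_c_pos[i] - x, rc.acceptor_pos[j] - x)
        if ang < rules.halogen_angle_min:
            continue
        res, moi = rna_lab(rc.acceptor_labels[j])
        out.append(Interaction("halogen_bond", float(d),
                               lc.halogen_labels[i], res, moi))

    # lipophilic: the full 2-8 A distance structure is recorded; contacts
    # within the classic core cutoff are flagged
    pairs, dists = _pairs_within(lc.hydrophobic_pos, rc.hydrophobic_pos,
                                 rules.lipophilic_max)
    for (i, j), d in zip(pairs, dists):
        res, moi = rna_lab(rc.hydrophobic_labels[j])
        out.append(Interaction("lipophilic", float(d),
                               lc.hydrophobic_labels[i], res, moi,
                               core=bool(d <= rules.lipophilic_core)))

    # cation-anion (ligand cation vs RNA phosphate anion, and the mirrored
    # direction should an RNA cation or ligand anion ever be present)
    pairs, dists = _pairs_within(lc.cation_pos, rc.anion_pos,
                                 rules.cation_anion_max)
    for (i, j), d in zip(pairs, dists):
        res, moi = rna_lab(rc.anion_labels[j])
        out.append(Interaction("cation_anion", float(d),
                               lc.cation_labels[i], res, moi))
    pairs, dists = _pairs_within(lc.anion_pos, rc.cation_pos,
                                 rules.cation_anion_max)
    for (i, j), d in zip(pairs, dists):
        res, moi = rna_lab(rc.cation_labels[j])
        out.append(Interaction("cation_anion", float(d),
                               lc.anion_labels[i], res, moi))

    # pi-stacking
    for lr in lc.rings:
        for rr in rc.rings:
            v = rr.centroid - lr.centroid
            d = float(np.linalg.norm(v))
            if d > rules.pi_stack_max:
                continue
            ang = _angle(lr.normal, rr.normal)
            ang = min(ang, 180.0 - ang)
            planar = ang <= rules.pi_stack_planar_max
            tshape = rules.pi_stack_tshape_min <= ang <= 90.0
            if not (planar or tshape):
                continue
            off_l = np.linalg.norm(v - np.dot(v, lr.normal) * lr.normal)
            off_r = np.linalg.norm(v - np.dot(v, rr.normal) * rr.normal)
            if min(off_l, off_r) > rules.pi_stack_offset_max:
                continue
            res, moi = rna_lab(rr.members[0])
            out.append(Interaction("pi_stacking", d, lr.members, res, moi))

    def _pi_charge(charge_pos, charge_labels, rings, cutoff, angle_max,
                   category, ligand_side_charges: bool):
        for i, cpos in enumerate(charge_pos):
            for ring in rings:
                v = cpos - ring.centroid
                d = float(np.linalg.norm(v))
                if d > cutoff:
                    continue
                ang = _angle(v, ring.normal)
                ang = min(ang, 180.0 - ang)
                if ang > angle_max:
                    continue
                if ligand_side_charges:
                    res, moi = rna_lab(ring.members[0])
                    out.append(Interaction(category, d, charge_labels[i],
                                           res, moi))
                else:
                    res, moi = rna_lab(charge_labels[i])
                    out.append(Interaction(category, d, ring.members, res, moi))

    # pi-cation: ligand cation over RNA ring; RNA cations do not occur
    _pi_charge(lc.cation_pos, lc.cation_labels, rc.rings,
               rules.pi_cation_max, rules.pi_cation_angle_max,
               "pi_cation", True)
    # pi-anion: RNA phosphate anion over a ligand ring, and a ligand anion
    # over an RNA base ring
    _pi_charge(lc.anion_pos, lc.anion_labels, rc.rings,
               rules.pi_anion_max, rules.pi_cation_angle_max,
               "pi_anion", True)
    for i, apos in enumerate(rc.anion_pos):
        for ring in lc.rings:
            v = apos - ring.centroid
            d = float(np.linalg.norm(v))
            if d > rules.pi_anion_max:
                continue
            ang = _angle(v, ring.normal)
            ang = min(ang, 180.0 - ang)
            if ang > rules.pi_cation_angle_max:
                continue
            res, moi = rna_lab(rc.anion_labels[i])
            out.append(Interaction("pi_anion", d, ring.members, res, moi))
    return out


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

def fingerprint_histogram(
    interactions: Sequence[Interaction],
    config: FingerprintConfig | None = None,
) -> np.ndarray:
    """Bin interactions into a 7 x n_bins count matrix.

    An interaction with d_min <= distance < d_max increments bin
    ``floor((distance - d_min)/width)`` of its category row; out-of-range
    interactions are dropped (counted in a debug log).
    """
    if config is None:
        config = FingerprintConfig()
    hist = np.zeros((len(CATEGORY_ORDER), config.n_bins), dtype=int)
    dropped = 0
    for ix in interactions:
        if not (config.d_min <= ix.distance < config.d_max):
            dropped += 1
            continue
        b = int((ix.distance - config.d_min) / config.bin_width)
        b = min(b, config.n_bins - 1)      # guards the d == d_max-eps edge
        hist[CATEGORY_INDEX[ix.category], b] += 1
    if dropped:
        logger.debug("fingerprint_histogram: %d interactions out of range",
                     dropped)
    return hist


def fingerprint_matrix(
    poses: Sequence[LigandPose],
    rna_for_pose,
    config: FingerprintConfig | None = None,
    rules: RuleTable | None = None,
) -> np.ndarray:
    """Flattened fingerprints for many poses: (n_poses, 7 * n_bins).

    ``rna_for_pose`` is either a single :class:`RnaModel` used for every
    pose or a mapping conformation_tag -> RnaModel.  RNA centers are typed
    once per conformation.
    """
    if config is None:
        config = FingerprintConfig()
    if isinstance(rna_for_pose, RnaModel):
        lookup = {None: rna_for_pose}
        get = lambda p: lookup[None]                      # noqa: E731
    else:
        lookup = dict(rna_for_pose)
        get = lambda p: lookup[p.conformation_tag]        # noqa: E731
    center_cache: dict[int, InteractionCenters] = {}
    typing_cache: dict = {}
    rows = np.zeros((len(poses), len(CATEGORY_ORDER) * config.n_bins),
                    dtype=int)
    for k, pose in enumerate(poses):
        rna = get(pose)
        key = id(rna)
        if key not in center_cache:
            center_cache[key] = assign_rna_centers(rna)
        tkey = (tuple(pose.elements), tuple(pose.formal_charges),
                tuple(pose.bonds))
        if tkey not in typing_cache:
            typing_cache[tkey] = ligand_typing(pose.elements, pose.bonds,
                                               pose.formal_charges)
        lc = assign_ligand_centers(pose, typing_cache[tkey])
        inter = detect_interactions(pose, rna, rules=rules,
                                    ligand_centers=lc,
                                    rna_centers=center_cache[key])
        rows[k] = fingerprint_histogram(inter, config).ravel()
    return rows


def average_profile(
    rows: np.ndarray,
    groups: Sequence,
    config: FingerprintConfig | None = None,
) -> dict:
    """Mean fingerprint per group (site or ligand), as 7 x n_bins arrays."""
    if config is None:
        config = FingerprintConfig()
    rows = np.asarray(rows, dtype=float)
    if rows.shape[0] != len(groups):
        raise ValueError("one group label per row required")
    if rows.shape[0] == 0:
        raise ValueError("no rows")
    out: dict = {}
    garr = np.asarray(groups)
    for g in sorted(set(groups)):
        sel = rows[garr == g]
        out[g] = sel.mean(axis=0).reshape(len(CATEGORY_ORDER), config.n_bins)
    return out
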