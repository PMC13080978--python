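"""Synthetic fixtures for every pipeline stage.

Nothing here imitates real chemistry; the generators produce *controlled*
inputs whose ground truth is known exactly, so each analysis stage can be
validated without external data:

* an idealised A-form-like RNA helix (stacked base rings on a regular
  helix, with backbone phosphates and representative donor/acceptor atoms),
* perturbed conformational ensembles with a tunable per-base rotation /
  translation magnitude (a stand-in for MD frame variability),
* a congeneric ligand series sharing a rigid two-arm scaffold whose bond
  graph has exactly two automorphisms (identity + arm swap, the two-fold
  symmetry of a diamidine-like core),
* pose sets planted in well-separated spatial modes near the helix, where
  one designated cluster's interaction geometry encodes a linear
  affinity signal with a calibrated target R², and an affinity table with
  ">500 μM" out-of-range entries.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .io_formats import (AffinityEntry, AffinityTable, DockingManifest,
                         LigandPose, Residue, RnaModel, RnaModelSet)

logger = logging.getLogger(__name__)

HELIX_RISE = 2.8          # Å per residue along the axis
HELIX_TWIST = 32.7        # degrees per residue
BASE_RADIUS = 4.0         # distance of the base-ring centre from the axis
RING_RADIUS = 1.4         # base six-ring radius
PHOSPHATE_RADIUS = 7.0    # backbone phosphorus distance from the axis

# exocyclic donor/acceptor decorations per base (name, ring-angle deg, radius)
_EXOCYCLIC = {
    "A": (("N6", 300.0, 2.6),),
    "U": (("O2", 0.0, 2.6), ("O4", 120.0, 2.6)),
    "G": (("O6", 300.0, 2.6), ("N2", 0.0, 2.6)),
    "C": (("O2", 0.0, 2.6), ("N4", 300.0, 2.6)),
}
_RING_NAMES = ("N1", "C2", "N3", "C4", "C5", "C6")
_RING_ANGLES = (300.0, 0.0, 60.0, 120.0, 180.0, 240.0)


@dataclass
class EnsembleSpec:
    """Controls for the perturbed-ensemble generator."""

    n_residues: int = 44
    n_models: int = 10
    rotation_sd: float = 8.0        # degrees, per-base random rotation
    translation_sd: float = 0.3     # Å, per-base random translation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_sd < 0 or self.translation_sd < 0:
            raise ValueError("perturbation magnitudes must be nonnegative")


@dataclass
class PlantedScenario:
    """Design of the end-to-end planted benchmark.

    One of ``n_clusters`` spatial pose modes (``signal_cluster``) carries an
    interaction pattern linear in a per-ligand driver calibrated so the
    squared correlation between the driver and log10(CD50), over the ligands
    with numeric affinities, equals ``target_r2`` exactly at generation
    time; hydrogen-bond and cation-anion contact counts increase with the
    driver while lipophilic counts decrease.  The other modes carry
    affinity-independent interaction levels.
    """

    n_ligands: int = 15
    poses_per_ligand: int = 200
    n_clusters: int = 3
    signal_cluster: int = 0
    target_r2: float = 0.85
    affinity_range: tuple[float, float] = (1.0, 400.0)
    fraction_out_of_range: float = 0.13
    cluster_fractions: tuple[float, ...] = (0.40, 0.35, 0.25)
    # per category: (baseline engaged count, amplitude per driver unit)
    rates: dict = field(default_factory=lambda: {
        "hydrogen_bond": (6.0, 2.0),
        "cation_anion": (5.0, 2.5),
        "lipophilic": (4.0, -1.2),
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_r2 <= 1):
            raise ValueError("target_r2 must lie in (0, 1]")
        if not (0 <= self.fraction_out_of_range < 1):
            raise ValueError("fraction_out_of_range must lie in [0, 1)")
        if not (0 <= self.signal_cluster < self.n_clusters):
            raise ValueError("signal_cluster out of range")
        if len(self.cluster_fractions) < self.n_clusters:
            raise ValueError("need a fraction per cluster")


# ---------------------------------------------------------------------------
# RNA generators
# ---------------------------------------------------------------------------

def _helix_sequence(n: int) -> list[str]:
    """Alternating A/U with two G-C pairs inserted mid-sequence."""
    seq = ["A" if i % 2 == 0 else "U" for i in range(n)]
    mid = n // 2
    for k, base in zip(range(mid - 2, mid + 2), ("G", "C", "G", "C")):
        if 0 <= k < n:
            seq[k] = base
    return seq


def make_idealized_helix(n_residues: int, seed: int = 0) -> RnaModelSet:
    """A single-model idealised helix (deterministic; the seed is accepted
    for interface symmetry with the stochastic generators).

    Per residue: a planar six-membered base ring (N1/C2/N3/C4/C5/C6) of
    radius 1.4 Å centred 4 Å from the axis, exocyclic donor/acceptor atoms
    per the nucleotide dictionary, and backbone P/OP1/OP2 at 7 Å.  Base
    origins advance 2.8 Å per residue along the axis with a 32.7° twist.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    seq = _helix_sequence(n_residues)
    residues: list[Residue] = []
    for i, base in enumerate(seq):
        theta = np.radians(HELIX_TWIST * i)
        u = np.array([np.cos(theta), np.sin(theta), 0.0])    # radial
        t = np.array([-np.sin(theta), np.cos(theta), 0.0])   # tangential
        z = np.array([0.0, 0.0, 1.0])
        origin = BASE_RADIUS * u + np.array([0.0, 0.0, HELIX_RISE * i])
        names, elements, coords = [], [], []
        for name, ang in zip(_RING_NAMES, _RING_ANGLES):
            a = np.radians(ang)
            pos = origin + RING_RADIUS * (np.cos(a) * u + np.sin(a) * t)
            names.append(name)
            elements.append(name[0])
            coords.append(pos)
        for name, ang, rad in _EXOCYCLIC[base]:
            a = np.radians(ang)
            pos = origin + rad * (np.cos(a) * u + np.sin(a) * t)
            names.append(name)
            elements.append(name[0])
            coords.append(pos)
        p_pos = PHOSPHATE_RADIUS * u + np.array([0.0, 0.0, HELIX_RISE * i])
        for name, off in (("P", 0.0 * z), ("OP1", 1.3 * z + 0.5 * t),
                          ("OP2", -1.3 * z + 0.5 * t)):
            names.append(name)
            elements.append(name[0])
            coords.append(p_pos + off)
        residues.append(Residue(i + 1, base, names, elements, np.array(coords)))
    return RnaModelSet([RnaModel(1, residues)])


def perturb_ensemble(reference: RnaModel, spec: EnsembleSpec) -> RnaModelSet:
    """Ensemble of per-base perturbed copies of a reference conformation.

    Each residue's atoms are rotated about the residue's base-frame origin
    (the C2/C4/C6 centroid) by a random rotation of sd ``rotation_sd``
    degrees and translated by an isotropic Gaussian of sd
    ``translation_sd`` Å.  Seeded and reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    models: list[RnaModel] = []
    for mi in range(spec.n_models):
        residues: list[Residue] = []
        for res in reference.residues:
            pts = np.array([res.atom_position(a) for a in ("C2", "C4", "C6")])
            origin = pts.mean(axis=0)
            angle = rng.normal(0.0, np.radians(spec.rotation_sd))
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            rot = Rotation.from_rotvec(angle * axis)
            shift = rng.normal(0.0, spec.translation_sd, size=3)
            coords = rot.apply(res.coords - origin) + origin + shift
            residues.append(Residue(res.index, res.name, list(res.atom_names),
                                    list(res.elements), coords))
        models.append(RnaModel(mi + 1, residues))
    return RnaModelSet(models)


# ---------------------------------------------------------------------------
# Ligand series
# ---------------------------------------------------------------------------

N_POLAR = 12          # neutral polar substituent pool (N donors/acceptors)
N_CHARGED = 8         # formally +1 amine-like substituent pool
N_LIPO = 10           # lipophilic carbon substituent pool


@dataclass
class LigandTopology:
    """Shared-topology ligand of the synthetic congeneric series."""

    ligand_id: str
    elements: list[str]
    formal_charges: list[int]
    bonds: list[tuple[int, int, int]]
    scaffold_atoms: list[int]
    polar_atoms: list[int]
    charged_atoms: list[int]
    lipo_atoms: list[int]
    substituent_class: str          # charged | polar | lipophilic


def _scaffold_template() -> tuple[list[str], list[tuple[int, int, int]], np.ndarray]:
    """Two-arm scaffold with exactly two bond-graph automorphisms.

    Atoms 0-5: arm-A six-ring (atom 2 is the ring nitrogen, breaking the
    in-ring mirror symmetry); 6-8: N-C-N linker; 9-14: arm-B ring.  The only
    nontrivial automorphism swaps the arms (and the two linker nitrogens).
    """
    elements = ["C", "C", "N", "C", "C", "C",      # arm A ring (0 attaches)
                "N", "C", "N",                     # linker
                "C", "C", "N", "C", "C", "C"]      # arm B ring (9 attaches)
    bonds = []
    for base in (0, 9):
        ring = [base + k for k in range(6)]
        bonds += [(ring[k], ring[(k + 1) % 6], 1) for k in range(6)]
    bonds += [(0, 6, 1), (6, 7, 1), (7, 8, 1), (8, 9, 1)]
    # planar template geometry: rings in the xy-plane around (+-4.2, 0, 0)
    coords = np.zeros((15, 3))
    for base, cx in ((0, -4.2), (9, 4.2)):
        for k in range(6):
            a = np.radians(60.0 * k)
            coords[base + k] = [cx + RING_RADIUS * np.cos(a),
                                RING_RADIUS * np.sin(a), 0.0]
    coords[6] = [-2.2, 0.6, 0.0]
    coords[7] = [0.0, 1.0, 0.0]
    coords[8] = [2.2, 0.6, 0.0]
    return elements, [(i, j, o) for i, j, o in bonds], coords


def make_congeneric_series(
    n_ligands: int, seed: int = 0
) -> tuple[list[LigandTopology], dict[str, list[int]]]:
    """Congeneric series sharing the two-arm scaffold.

    Every ligand carries the full substituent decoration (12 neutral polar
    nitrogens, 8 formally charged nitrogens, 10 lipophilic carbons) attached
    at fixed topological positions, so any planted interaction pattern is
    geometrically realisable for any ligand; the recorded substituent class
    is a per-ligand label drawn from the three classes.  Returns the
    topologies and the scaffold atom map (identical ordered list per
    ligand).
    """
    if n_ligands < 3:
        raise ValueError("need at least 3 ligands")
    rng = np.random.default_rng(seed)
    elements, bonds, _ = _scaffold_template()
    elements = list(elements)
    bonds = list(bonds)
    n0 = len(elements)                       # 15 scaffold atoms

    def add_atom(elem: str, charge: int, bond_to: int,
                 charges: list[int]) -> int:
        idx = len(elements)
        elements.append(elem)
        charges.append(charge)
        bonds.append((bond_to, idx, 1))
        return idx

    charges = [0] * n0
    # stems off the central linker carbon carry the neutral polar pool
    s1 = add_atom("C", 0, 7, charges)
    s2 = add_atom("C", 0, s1, charges)
    polar = [add_atom("N", 0, s1 if k < N_POLAR // 2 else s2, charges)
             for k in range(N_POLAR)]
    # charged nitrogens chain off ring carbons that have no ring-N neighbour
    charged: list[int] = []
    for anchor in (4, 5, 13, 14):
        c1 = add_atom("N", 1, anchor, charges)
        c2 = add_atom("N", 1, c1, charges)
        charged += [c1, c2]
    # lipophilic carbons chain off the remaining ring carbons
    lipo: list[int] = []
    for anchor in (1, 3, 10, 12):
        l1 = add_atom("C", 0, anchor, charges)
        l2 = add_atom("C", 0, l1, charges)
        lipo += [l1, l2]
    lipo.append(add_atom("C", 0, lipo[0], charges))
    lipo.append(add_atom("C", 0, lipo[4], charges))

    classes = ["charged", "polar", "lipophilic"]
    topologies = []
    scaffold = list(range(n0))
    for li in range(n_ligands):
        lig_id = f"L{li + 1:02d}"
        topologies.append(LigandTopology(
            ligand_id=lig_id,
            elements=list(elements),
            formal_charges=list(charges),
            bonds=list(bonds),
            scaffold_atoms=list(scaffold),
            polar_atoms=list(polar),
            charged_atoms=list(charged),
            lipo_atoms=list(lipo),
            substituent_class=classes[int(rng.integers(len(classes)))],
        ))
    scaffold_map = {t.ligand_id: list(scaffold) for t in topologies}
    return topologies, scaffold_map


# ---------------------------------------------------------------------------
# Planted pose sets
# ---------------------------------------------------------------------------

def _calibrated_driver(
    log_cd50: np.ndarray, numeric: np.ndarray, target_r2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-ligand driver with corr(driver, log CD50)^2 == target_r2 exactly
    over the ligands flagged ``numeric`` (variance-budget calibration,
    enforced empirically on the drawn noise)."""
    s = -log_cd50                              # high affinity -> high driver
    sn = s[numeric]
    shat = (s - sn.mean()) / sn.std()
    noise = rng.normal(size=len(s))
    nn = noise[numeric]
    # empirically orthogonalise the noise to the signal over the numeric set
    shn = shat[numeric]
    proj = np.dot(nn, shn) / np.dot(shn, shn)
    noise = noise - proj * shat
    nn = noise[numeric]
    noise = (noise - nn.mean()) / nn.std()
    driver = np.sqrt(target_r2) * shat + np.sqrt(1.0 - target_r2) * noise
    dn = driver[numeric]
    return (driver - dn.mean()) / dn.std()


def _mode_frames(n_clusters: int, helix_length: float):
    """Placement frames (centre, rotation) of the pose modes, spaced along
    and around the helix so inter-mode scaffold RMSD is far above 5 Å."""
    frames = []
    z_mid = helix_length / 2.0
    spacing = min(18.0, max(helix_length - 10.0, 0.0) / max(n_clusters - 1, 1))
    for c in range(n_clusters):
        z = z_mid + (c - (n_clusters - 1) / 2.0) * spacing
        z = float(np.clip(z, 5.0, max(helix_length - 5.0, 5.0)))
        theta = np.radians(120.0 * c)
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        t = np.array([-np.sin(theta), np.cos(theta), 0.0])
        centre = 19.0 * u + np.array([0.0, 0.0, z])
        rot = np.stack([t, np.array([0.0, 0.0, 1.0]), u], axis=0).T
        frames.append((centre, rot, theta, z))
    return frames


def plant_pose_set(
    rna: RnaModel,
    series: Sequence[LigandTopology],
    scenario: PlantedScenario,
) -> tuple[list[LigandPose], AffinityTable, dict]:
    """Generate poses, affinities and ground truth for the planted scenario.

    Poses fall in ``n_clusters`` spatial modes (inter-mode scaffold RMSD far
    above the 5 Å clustering threshold, intra-mode well below).  In the
    signal mode the number of *engaged* polar / charged / lipophilic
    substituents per pose follows binomial counts whose means are linear in
    the calibrated affinity driver; engaged atoms are placed at
    interaction-range distances from RNA acceptors, phosphate oxygens and
    base carbons respectively, disengaged atoms far outside the 8 Å
    detection range.  Returns (poses, affinity table, ground truth).
    """
    rng = np.random.default_rng(scenario.seed)
    n_lig = scenario.n_ligands
    if len(series) < n_lig:
        raise ValueError("series smaller than scenario.n_ligands")
    series = list(series)[:n_lig]

    lo, hi = scenario.affinity_range
    log_cd50 = rng.uniform(np.log10(lo), np.log10(hi), size=n_lig)
    n_oor = int(round(scenario.fraction_out_of_range * n_lig))
    numeric = np.ones(n_lig, dtype=bool)
    if n_oor:
        worst = np.argsort(log_cd50)[-n_oor:]       # weakest binders
        numeric[worst] = False
        log_cd50[worst] = rng.uniform(np.log10(505.0), np.log10(1500.0),
                                      size=n_oor)
    driver = _calibrated_driver(log_cd50, numeric, scenario.target_r2, rng)

    entries: dict[str, AffinityEntry] = {}
    for li, topo in enumerate(series):
        if numeric[li]:
            entries[topo.ligand_id] = AffinityEntry(
                topo.ligand_id, float(10.0 ** log_cd50[li]))
        else:
            entries[topo.ligand_id] = AffinityEntry(
                topo.ligand_id, None, out_of_range=True, bound_uM=500.0)
    affinities = AffinityTable(entries)

    # RNA partner coordinates for engagement placement
    from .interactions import assign_rna_centers
    rc = assign_rna_centers(rna)
    helix_length = HELIX_RISE * len(rna.residues)

    _, _, scaffold_template = _scaffold_template()
    n_scaffold = scaffold_template.shape[0]

    # affinity-independent per-(ligand, cluster) drivers for non-signal modes
    bg_driver = rng.normal(size=(n_lig, scenario.n_clusters))

    fracs = np.array(scenario.cluster_fractions[:scenario.n_clusters], float)
    fracs = fracs / fracs.sum()
    counts = np.floor(fracs * scenario.poses_per_ligand).astype(int)
    counts[0] += scenario.poses_per_ligand - counts.sum()

    frames = _mode_frames(scenario.n_clusters, helix_length)
    # the 120-degree azimuthal spacing alone keeps the mode centres > 30 Å
    # apart; verify the guarantee on the actual template placements
    for ca in range(scenario.n_clusters):
        for cb in range(ca + 1, scenario.n_clusters):
            d = np.linalg.norm(frames[ca][0] - frames[cb][0])
            if d <= 8.0:
                raise RuntimeError(
                    f"pose modes {ca} and {cb} overlap (centres {d:.1f} Å "
                    "apart); choose fewer clusters or a longer helix")

    def partners_near(pos_arr: np.ndarray, z: float, halfwidth: float = 9.0):
        if len(pos_arr) == 0:
            return pos_arr
        sel = np.abs(pos_arr[:, 2] - z) <= halfwidth
        return pos_arr[sel] if sel.any() else pos_arr

    rates = scenario.rates
    pools = {"hydrogen_bond": N_POLAR, "cation_anion": N_CHARGED,
             "lipophilic": N_LIPO}
    dist_ranges = {"hydrogen_bond": (2.8, 3.4), "cation_anion": (3.2, 3.8),
                   "lipophilic": (3.4, 4.4)}

    # charged groups aim at the midpoint of the two non-bridging phosphate
    # oxygens, contacting both at once (a bidentate salt bridge)
    op_mid = []
    for res in rna.residues:
        if res.has_atom("OP1") and res.has_atom("OP2"):
            op_mid.append((res.atom_position("OP1")
                           + res.atom_position("OP2")) / 2.0)
    partner_arrays_global = {
        "hydrogen_bond": np.array([p for p, lab in zip(
            rc.acceptor_pos, rc.acceptor_labels) if lab[1] != "phosphate"]),
        "cation_anion": np.array(op_mid) if op_mid else rc.anion_pos,
        "lipophilic": rc.hydrophobic_pos,
    }

    poses: list[LigandPose] = []
    truth_rows = []
    for li, topo in enumerate(series):
        atom_pools = {"hydrogen_bond": topo.polar_atoms,
                      "cation_anion": topo.charged_atoms,
                      "lipophilic": topo.lipo_atoms}
        partner_arrays = partner_arrays_global
        pose_counter = 0
        for c in range(scenario.n_clusters):
            centre, rot0, theta, z = frames[c]
            z_driver = (driver[li] if c == scenario.signal_cluster
                        else bg_driver[li, c])
            u_out = np.array([np.cos(theta), np.sin(theta), 0.0])
            for _ in range(counts[c]):
                # rigid scaffold placement with small jitter
                jrot = Rotation.from_rotvec(
                    rng.normal(0.0, np.radians(5.0)) * _unit(rng))
                jtr = rng.normal(0.0, 0.5, size=3)
                R = jrot.as_matrix() @ rot0
                coords = np.zeros((len(topo.elements), 3))
                coords[:n_scaffold] = scaffold_template @ R.T + centre + jtr
                # stems sit just outside the scaffold
                coords[n_scaffold] = centre + jtr + 3.0 * u_out
                coords[n_scaffold + 1] = centre + jtr + 4.5 * u_out

                engaged_counts = {}
                for cat, (base, amp) in rates.items():
                    pool = pools[cat]
                    rate = float(np.clip(base + amp * z_driver, 0.0, pool))
                    k = int(rng.binomial(pool, rate / pool))
                    engaged_counts[cat] = k
                    atoms = atom_pools[cat]
                    partners = partners_near(partner_arrays[cat], z)
                    dlo, dhi = dist_ranges[cat]
                    for slot, atom_idx in enumerate(atoms):
                        if slot < k and len(partners):
                            target = partners[int(rng.integers(len(partners)))]
                            radial = target[:2] / max(np.linalg.norm(target[:2]),
                                                      1e-9)
                            direction = np.array([radial[0], radial[1], 0.0])
                            direction = direction + 0.35 * _unit(rng)
                            direction /= np.linalg.norm(direction)
                            d = rng.uniform(dlo, dhi)
                            coords[atom_idx] = target + d * direction
                        else:
                            # parked far outside the 8 Å detection range
                            coords[atom_idx] = (
                                (27.0 + rng.uniform(0, 4.0)) * u_out
                                + np.array([0.0, 0.0,
                                            z + rng.uniform(-6.0, 6.0)]))
                pose_id = f"{topo.ligand_id}_p{pose_counter:04d}"
                program = "progA" if pose_counter % 2 == 0 else "progB"
                poses.append(LigandPose(
                    ligand_id=topo.ligand_id, site_tag="S1",
                    conformation_tag="ref", program_tag=program,
                    elements=list(topo.elements), coords=coords,
                    formal_charges=list(topo.formal_charges),
                    bonds=list(topo.bonds),
                    scaffold_atoms=list(topo.scaffold_atoms),
                    pose_id=pose_id))
                truth_rows.append({
                    "ligand_id": topo.ligand_id, "pose_id": pose_id,
                    "cluster": c, **{f"n_{k}": v
                                     for k, v in engaged_counts.items()}})
                pose_counter += 1

    truth = {
        "cluster_labels": [r["cluster"] for r in truth_rows],
        "pose_table": truth_rows,
        "driver": driver.tolist(),
        "log10_cd50_latent": log_cd50.tolist(),
        "numeric": numeric.tolist(),
        "ligand_ids": [t.ligand_id for t in series],
        "signal_cluster": scenario.signal_cluster,
        "n_clusters": scenario.n_clusters,
        "cluster_counts_per_ligand": counts.tolist(),
    }
    return poses, affinities, truth


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def scenario_manifest(scenario: PlantedScenario,
                      ligand_ids: Sequence[str]) -> DockingManifest:
    """Manifest matching the planted scenario's bookkeeping."""
    return DockingManifest(
        sites=[("S1", 1)],
        programs=["progA", "progB"],
        poses_per_program=scenario.poses_per_ligand // 2,
        ligand_ids=list(ligand_ids),
    )
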