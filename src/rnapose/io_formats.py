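"""Readers, writers and bookkeeping for the external formats of the pipeline.

The pipeline consumes four kinds of input:

* multi-MODEL PDB files holding an ensemble of RNA conformations,
* SDF (V2000) files holding docked ligand poses with connectivity, formal
  charges and per-record metadata tags,
* a CSV affinity table with CD50 values in micromolar (``>500`` marking
  out-of-assay-range compounds),
* YAML files for the docking-design manifest, binding-site residue lists and
  the scaffold atom maps of a congeneric series.

Everything is held in plain dataclasses built on numpy arrays so the
downstream numerical stages never touch a file format again.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

logger = logging.getLogger(__name__)

NUCLEOTIDE_NAMES = {"A", "U", "G", "C", "RA", "RU", "RG", "RC",
                    "ADE", "URA", "GUA", "CYT"}
_NAME_CANON = {"RA": "A", "RU": "U", "RG": "G", "RC": "C",
               "ADE": "A", "URA": "U", "GUA": "G", "CYT": "C"}

FRAME_ATOMS = ("C2", "C4", "C6")


# ---------------------------------------------------------------------------
# RNA containers
# ---------------------------------------------------------------------------

@dataclass
class Residue:
    """One nucleotide: ordered atom names/elements and an (n_atoms, 3) array."""

    index: int
    name: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atom_names), 3):
            raise ValueError(
                f"residue {self.index}: coords shape {self.coords.shape} does "
                f"not match {len(self.atom_names)} atoms"
            )

    def atom_position(self, name: str) -> np.ndarray:
        try:
            return self.coords[self.atom_names.index(name)]
        except ValueError:
            raise KeyError(f"residue {self.index} has no atom {name!r}") from None

    def has_atom(self, name: str) -> bool:
        return name in self.atom_names


@dataclass
class RnaModel:
    """A single RNA conformation (one MODEL record)."""

    model_id: int
    residues: list[Residue]

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if len(set(idx)) != len(idx) or idx != sorted(idx):
            raise ValueError(
                f"model {self.model_id}: residue indices must be unique and "
                "strictly increasing"
            )
        for r in self.residues:
            for a in FRAME_ATOMS:
                if not r.has_atom(a):
                    raise ValueError(
                        f"model {self.model_id}, residue {r.index} ({r.name}) "
                        f"is missing required atom {a}"
                    )
            if not np.all(np.isfinite(r.coords)):
                raise ValueError(
                    f"model {self.model_id}, residue {r.index}: non-finite "
                    "coordinates"
                )

    @property
    def residue_indices(self) -> list[int]:
        return [r.index for r in self.residues]

    def residue(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"no residue with index {index}")

    def subset(self, indices: Iterable[int]) -> "RnaModel":
        keep = set(indices)
        return RnaModel(self.model_id, [r for r in self.residues if r.index in keep])


@dataclass
class RnaModelSet:
    """An ordered ensemble of conformations sharing one residue/atom layout."""

    models: list[RnaModel]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("RnaModelSet needs at least one model")
        ref = self._layout(self.models[0])
        for m in self.models[1:]:
            if self._layout(m) != ref:
                raise ValueError(
                    f"model {m.model_id} has a residue/atom layout differing "
                    f"from model {self.models[0].model_id}"
                )

    @staticmethod
    def _layout(m: RnaModel) -> list[tuple[int, str, tuple[str, ...]]]:
        return [(r.index, r.name, tuple(r.atom_names)) for r in m.residues]

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, i: int) -> RnaModel:
        return self.models[i]


# ---------------------------------------------------------------------------
# Ligand poses
# ---------------------------------------------------------------------------

@dataclass
class LigandPose:
    """One docked pose of one ligand, in the receptor coordinate frame.

    ``scaffold_atoms`` lists, in a series-wide canonical order, the atom
    indices of the scaffold common to the congeneric series; atom *k* of the
    scaffold refers to the same chemical atom in every pose of every ligand.
    """

    ligand_id: str
    site_tag: str
    conformation_tag: str
    program_tag: str
    elements: list[str]
    coords: np.ndarray
    formal_charges: list[int]
    bonds: list[tuple[int, int, int]]          # (i, j, order)
    scaffold_atoms: list[int]
    pose_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError("coords shape does not match element count")
        if len(self.formal_charges) != n:
            raise ValueError("formal_charges length mismatch")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range")
        if any(not (0 <= k < n) for k in self.scaffold_atoms):
            raise ValueError("scaffold atom index out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def scaffold_coords(self) -> np.ndarray:
        return self.coords[self.scaffold_atoms]

    def scaffold_elements(self) -> list[str]:
        return [self.elements[k] for k in self.scaffold_atoms]

    def scaffold_bonds(self) -> list[tuple[int, int]]:
        """Bonds of the scaffold subgraph, re-indexed to scaffold positions."""
        pos = {a: k for k, a in enumerate(self.scaffold_atoms)}
        out = []
        for i, j, _ in self.bonds:
            if i in pos and j in pos:
                out.append((pos[i], pos[j]))
        return out


# ---------------------------------------------------------------------------
# Affinity table
# ---------------------------------------------------------------------------

@dataclass
class AffinityEntry:
    ligand_id: str
    cd50_uM: float | None              # None when out of assay range
    out_of_range: bool = False
    bound_uM: float = 500.0

    def __post_init__(self) -> None:
        if self.out_of_range:
            if self.cd50_uM is not None:
                raise ValueError("out-of-range entry must not carry a CD50")
        else:
            if self.cd50_uM is None or self.cd50_uM <= 0:
                raise ValueError(
                    f"ligand {self.ligand_id}: CD50 must be positive"
                )


@dataclass
class AffinityTable:
    entries: dict[str, AffinityEntry]

    def numeric(self) -> dict[str, float]:
        """Ligand -> CD50 for ligands with an in-range measurement."""
        return {k: e.cd50_uM for k, e in self.entries.items()
                if not e.out_of_range}

    def capped(self) -> dict[str, float]:
        """Ligand -> CD50 with out-of-range entries capped at their bound."""
        return {k: (e.bound_uM if e.out_of_range else e.cd50_uM)
                for k, e in self.entries.items()}


# ---------------------------------------------------------------------------
# Docking manifest
# ---------------------------------------------------------------------------

@dataclass
class DockingManifest:
    """The design of the ensemble-docking run: sites x conformations x
    programs x poses-per-program, and the ligand series."""

    sites: list[tuple[str, int]]
    programs: list[str]
    poses_per_program: int
    ligand_ids: list[str]

    def __post_init__(self) -> None:
        if self.poses_per_program <= 0:
            raise ValueError("poses_per_program must be positive")
        if not self.programs:
            raise ValueError("at least one program required")
        for tag, n in self.sites:
            if n <= 0:
                raise ValueError(f"site {tag}: conformation count must be positive")


def expected_pose_counts(manifest: DockingManifest) -> dict[str | tuple[str, str], int]:
    """Expected pose counts implied by the docking design.

    Returns a mapping with, for every ligand, the per-ligand total under key
    ``ligand_id`` and per-site totals under ``(ligand_id, site_tag)``.  The
    per-ligand total is the sum over sites of
    ``n_conformations * n_programs * poses_per_program``.
    """
    per_conf = len(manifest.programs) * manifest.poses_per_program
    out: dict[str | tuple[str, str], int] = {}
    for lig in manifest.ligand_ids:
        total = 0
        for site_tag, n_conf in manifest.sites:
            c = n_conf * per_conf
            out[(lig, site_tag)] = c
            total += c
        out[lig] = total
    return out


def validate_pose_counts(
    poses: Sequence[LigandPose], manifest: DockingManifest
) -> list[str]:
    """Compare ingested pose counts against the manifest; returns warnings."""
    expected = expected_pose_counts(manifest)
    counts: dict[tuple[str, str], int] = {}
    for p in poses:
        counts[(p.ligand_id, p.site_tag)] = counts.get((p.ligand_id, p.site_tag), 0) + 1
    msgs = []
    for lig in manifest.ligand_ids:
        for site_tag, _ in manifest.sites:
            got = counts.get((lig, site_tag), 0)
            exp = expected[(lig, site_tag)]
            if got != exp:
                msg = (f"ligand {lig}, site {site_tag}: expected {exp} poses, "
                       f"found {got} (discrepancy {got - exp:+d})")
                logger.warning(msg)
                msgs.append(msg)
    return msgs


# ---------------------------------------------------------------------------
# PDB reading / writing (multi-MODEL)
# ---------------------------------------------------------------------------

def read_rna_models(path: str | Path) -> RnaModelSet:
    """Read a (possibly multi-MODEL) PDB file into an :class:`RnaModelSet`.

    Non-nucleotide residues are skipped with a logged warning.  Alternate
    locations other than blank/'A' are dropped.  A retained residue missing
    any of the C2/C4/C6 frame atoms raises a ``ValueError`` naming the model
    and residue.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    models: list[RnaModel] = []
    for mi, gm in enumerate(st):
        residues: list[Residue] = []
        for chain in gm:
            for res in chain:
                name = res.name.strip()
                if name not in NUCLEOTIDE_NAMES:
                    logger.warning(
                        "model %d: skipping non-nucleotide residue %s %d",
                        mi + 1, name, res.seqid.num)
                    continue
                atom_names, elements, coords = [], [], []
                for atom in res:
                    if atom.altloc not in ("", "A", "\0"):
                        continue
                    atom_names.append(atom.name)
                    elements.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                residues.append(Residue(res.seqid.num, _NAME_CANON.get(name, name),
                                        atom_names, elements, np.array(coords)))
        try:
            models.append(RnaModel(mi + 1, residues))
        except ValueError as exc:
            raise ValueError(f"while reading {path}: {exc}") from exc
    return RnaModelSet(models)


def write_rna_models(model_set: RnaModelSet, path: str | Path) -> None:
    """Write an ensemble as a multi-MODEL PDB file (Å, %.3f precision)."""
    st = gemmi.Structure()
    st.name = "rnapose"
    for m in model_set.models:
        gm = gemmi.Model(m.model_id)
        chain = gemmi.Chain("A")
        for r in m.residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.index, " ")
            for name, elem, xyz in zip(r.atom_names, r.elements, r.coords):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(elem)
                atom.pos = gemmi.Position(*map(float, xyz))
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
        st.add_model(gm)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# SDF reading / writing
# ---------------------------------------------------------------------------

_REQUIRED_TAGS = ("ligand_id", "site_tag", "conformation_tag", "program_tag")

_BOND_ORDERS = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                3: Chem.BondType.TRIPLE, 4: Chem.BondType.AROMATIC}
_BOND_ORDERS_INV = {v: k for k, v in _BOND_ORDERS.items()}


def _resolve_scaffold(
    mol: Chem.Mol, spec, ligand_id: str
) -> list[int]:
    """Resolve the scaffold atom order for one record.

    ``spec`` is either a mapping ligand_id -> ordered atom-index list, a
    plain list applying to every ligand, or a SMARTS string matched as a
    substructure (first match, RDKit canonical order).  Explicit index lists
    win over SMARTS.
    """
    if isinstance(spec, Mapping):
        if ligand_id not in spec:
            raise ValueError(f"no scaffold entry for ligand {ligand_id!r}")
        idx = list(spec[ligand_id])
    elif isinstance(spec, str):
        patt = Chem.MolFromSmarts(spec)
        if patt is None:
            raise ValueError(f"invalid scaffold SMARTS: {spec!r}")
        match = mol.GetSubstructMatch(patt)
        if not match:
            raise ValueError(
                f"scaffold SMARTS not found in a pose of ligand {ligand_id!r}")
        idx = list(match)
    else:
        idx = list(spec)
    n = mol.GetNumAtoms()
    bad = [k for k in idx if not (0 <= k < n)]
    if bad:
        raise ValueError(
            f"ligand {ligand_id!r}: scaffold indices {bad} out of range "
            f"(molecule has {n} atoms)")
    return idx


def read_ligand_poses(path: str | Path, scaffold_spec) -> list[LigandPose]:
    """Read docked poses from an SDF file.

    Every record must carry the property tags ``ligand_id``, ``site_tag``,
    ``conformation_tag`` and ``program_tag``; a missing tag is a hard error
    naming the record.  Molecules are read without sanitisation so abstract
    topologies (synthetic ligands) pass through untouched; the scaffold atom
    order is taken from ``scaffold_spec`` verbatim, never re-canonicalised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    poses: list[LigandPose] = []
    for ri, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: unparseable SDF record #{ri}")
        props = mol.GetPropsAsDict()
        missing = [t for t in _REQUIRED_TAGS if t not in props]
        if missing:
            raise ValueError(
                f"{path}: record #{ri} is missing required tags {missing}")
        conf = mol.GetConformer()
        coords = np.array(conf.GetPositions(), dtype=float)
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                  _BOND_ORDERS_INV.get(b.GetBondType(), 1))
                 for b in mol.GetBonds()]
        lig = str(props["ligand_id"])
        try:
            scaffold = _resolve_scaffold(mol, scaffold_spec, lig)
        except ValueError as exc:
            raise ValueError(f"{path}: record #{ri}: {exc}") from exc
        poses.append(LigandPose(
            ligand_id=lig,
            site_tag=str(props["site_tag"]),
            conformation_tag=str(props["conformation_tag"]),
            program_tag=str(props["program_tag"]),
            elements=elements,
            coords=coords,
            formal_charges=charges,
            bonds=bonds,
            scaffold_atoms=scaffold,
            pose_id=str(props.get("pose_id", f"{lig}_{ri}")),
        ))
    return poses


def pose_to_mol(pose: LigandPose) -> Chem.Mol:
    """Build an (unsanitised) RDKit molecule with a conformer from a pose."""
    rw = Chem.RWMol()
    for elem, q in zip(pose.elements, pose.formal_charges):
        a = Chem.Atom(elem)
        a.SetFormalCharge(int(q))
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j, order in pose.bonds:
        rw.AddBond(int(i), int(j), _BOND_ORDERS.get(order, Chem.BondType.SINGLE))
    conf = Chem.Conformer(pose.n_atoms)
    for k, xyz in enumerate(pose.coords):
        conf.SetAtomPosition(k, tuple(float(v) for v in xyz))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return mol


def write_ligand_poses(poses: Sequence[LigandPose], path: str | Path) -> None:
    """Write poses to an SDF (V2000) file with the required property tags."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for p in poses:
        mol = pose_to_mol(p)
        mol.SetProp("_Name", p.pose_id or p.ligand_id)
        mol.SetProp("ligand_id", p.ligand_id)
        mol.SetProp("site_tag", p.site_tag)
        mol.SetProp("conformation_tag", p.conformation_tag)
        mol.SetProp("program_tag", p.program_tag)
        mol.SetProp("pose_id", p.pose_id)
        writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# Affinity CSV
# ---------------------------------------------------------------------------

def read_affinities(path: str | Path, bound_uM: float = 500.0) -> AffinityTable:
    """Read a CSV with columns ``ligand_id, cd50_uM``.

    ``cd50_uM`` is either a positive number (micromolar) or the literal token
    ``>500`` (whitespace tolerated), which is parsed as an out-of-range entry
    with the stated bound.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    required = {"ligand_id", "cd50_uM"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    entries: dict[str, AffinityEntry] = {}
    for _, row in df.iterrows():
        lig = str(row["ligand_id"]).strip()
        raw = str(row["cd50_uM"]).strip()
        if lig in entries:
            raise ValueError(f"{path}: duplicate ligand_id {lig!r}")
        if raw.startswith(">"):
            bound = float(raw[1:])
            entries[lig] = AffinityEntry(lig, None, out_of_range=True,
                                         bound_uM=bound)
        else:
            val = float(raw)
            if val <= 0:
                raise ValueError(f"{path}: ligand {lig}: non-positive CD50 {val}")
            entries[lig] = AffinityEntry(lig, val, bound_uM=bound_uM)
    return AffinityTable(entries)


def write_affinities(table: AffinityTable, path: str | Path) -> None:
    rows = []
    for lig, e in table.entries.items():
        rows.append({"ligand_id": lig,
                     "cd50_uM": f">{e.bound_uM:g}" if e.out_of_range
                     else f"{e.cd50_uM:g}"})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# YAML: manifest, site residue lists, scaffold maps
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> DockingManifest:
    data = yaml.safe_load(Path(path).read_text())
    sites = [(str(s["site_tag"]), int(s["n_conformations"]))
             for s in data["sites"]]
    return DockingManifest(
        sites=sites,
        programs=[str(p) for p in data["programs"]],
        poses_per_program=int(data["poses_per_program"]),
        ligand_ids=[str(x) for x in data["ligand_ids"]],
    )


def write_manifest(manifest: DockingManifest, path: str | Path) -> None:
    data = {
        "sites": [{"site_tag": t, "n_conformations": n}
                  for t, n in manifest.sites],
        "programs": list(manifest.programs),
        "poses_per_program": manifest.poses_per_program,
        "ligand_ids": list(manifest.ligand_ids),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_scaffold_map(path: str | Path) -> dict[str, list[int]] | str:
    """Read a scaffold sidecar YAML.

    Either ``{atoms: {ligand_id: [indices...]}}`` (explicit ordered lists,
    0-based) or ``{smarts: "..."}``; explicit lists win when both present.
    """
    data = yaml.safe_load(Path(path).read_text())
    if "atoms" in data:
        return {str(k): [int(i) for i in v] for k, v in data["atoms"].items()}
    if "smarts" in data:
        return str(data["smarts"])
    raise ValueError(f"{path}: scaffold map needs an 'atoms' or 'smarts' key")


def write_scaffold_map(atoms: Mapping[str, Sequence[int]], path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({"atoms": {k: list(map(int, v)) for k, v in atoms.items()}},
                       sort_keys=True))


def read_site_lists(path: str | Path) -> dict[str, list[int]]:
    """Read ``{site_tag: [residue indices...]}`` from YAML."""
    data = yaml.safe_load(Path(path).read_text())
    return {str(k): [int(i) for i in v] for k, v in data.items()}
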