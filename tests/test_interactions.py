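import numpy as np
import pytest

from rnapose import interactions as ix
from rnapose.io_formats import LigandPose, Residue, RnaModel


def make_ligand(elements, coords, bonds, charges=None, scaffold=None):
    n = len(elements)
    return LigandPose(
        ligand_id="L", site_tag="S", conformation_tag="c", program_tag="p",
        elements=list(elements), coords=np.asarray(coords, float),
        formal_charges=list(charges) if charges else [0] * n,
        bonds=[(i, j, 1) for i, j in bonds],
        scaffold_atoms=scaffold or [0])


def guanine_residue(origin=np.zeros(3)):
    """A full-atom G with standard nucleobase atom names (synthetic planar
    geometry; typing depends on names, not exact coordinates)."""
    names = ["N1", "C2", "N3", "C4", "C5", "C6", "O6", "N2", "N7", "C8",
             "N9", "O2'", "P", "OP1", "OP2"]
    rng = np.random.default_rng(0)
    coords = np.zeros((len(names), 3))
    for k in range(6):                       # planar six-ring
        a = np.radians(60.0 * k)
        coords[k] = [1.4 * np.cos(a), 1.4 * np.sin(a), 0.0]
    coords[6] = [0.0, 2.6, 0.0]              # O6
    coords[7] = [2.6, 0.0, 0.0]              # N2
    for k in range(8, len(names)):           # tail atoms well separated
        coords[k] = [10.0 + 8.0 * (k - 8), 0.0, 0.0]
    coords += origin
    return Residue(1, "G", names, [n[0] for n in names], coords)


# ---------------------------------------------------------------------------
# Center typing
# ---------------------------------------------------------------------------

def test_amidinium_gives_single_cation_center():
    """C(NH2)=NH2+ with the charge on one N types as one cation center at
    the centroid of the resonance group."""
    elements = ["C", "N", "N", "C"]          # amidine C, 2 N, stem C
    coords = [[0, 0, 0], [1.3, 0.8, 0], [1.3, -0.8, 0], [-1.5, 0, 0]]
    bonds = [(0, 1), (0, 2), (0, 3)]
    pose = make_ligand(elements, coords, bonds, charges=[0, 1, 0, 0])
    centers = ix.assign_ligand_centers(pose)
    assert len(centers.cation_pos) == 1
    group = centers.cation_labels[0]
    assert set(group) == {0, 1, 2}
    np.testing.assert_allclose(centers.cation_pos[0],
                               np.mean(np.array(coords)[[0, 1, 2]], axis=0))


def test_guanine_typing_follows_dictionary():
    model = RnaModel(1, [guanine_residue()])
    centers = ix.assign_rna_centers(model)
    donor_names = {lab[2] for lab in centers.donor_labels}
    acceptor_names = {lab[2] for lab in centers.acceptor_labels}
    assert {"N1", "N2"} <= donor_names
    assert {"O6", "N3", "N7"} <= acceptor_names
    anion_names = [lab[2] for lab in centers.anion_labels]
    assert sorted(anion_names) == ["OP1", "OP2"]
    moieties = {lab[2]: lab[1] for lab in centers.anion_labels}
    assert set(moieties.values()) == {"phosphate"}


def test_benzene_fragment_single_ring():
    coords = [[1.4 * np.cos(np.radians(60 * k)),
               1.4 * np.sin(np.radians(60 * k)), 0.0] for k in range(6)]
    bonds = [(k, (k + 1) % 6) for k in range(6)]
    pose = make_ligand(["C"] * 6, coords, bonds)
    centers = ix.assign_ligand_centers(pose)
    assert len(centers.rings) == 1
    ring = centers.rings[0]
    np.testing.assert_allclose(ring.centroid, [0, 0, 0], atol=1e-9)
    np.testing.assert_allclose(np.abs(ring.normal), [0, 0, 1], atol=1e-9)


def test_explicit_hydrogen_donor_typing():
    """With explicit hydrogens present, only N/O carrying an H are donors."""
    elements = ["N", "H", "O", "C"]
    coords = [[0, 0, 0], [1, 0, 0], [3, 0, 0], [5, 0, 0]]
    bonds = [(0, 1), (0, 3), (2, 3)]
    pose = make_ligand(elements, coords, bonds)
    centers = ix.assign_ligand_centers(pose)
    assert centers.has_explicit_h
    assert centers.donor_labels == [0]
    assert set(centers.acceptor_labels) == {0, 2}


def test_typing_is_atom_order_independent(small_scenario):
    """Permuting atom input order permutes labels but leaves the detected
    interaction multiset unchanged."""
    pose = small_scenario["poses"][0]
    rna = small_scenario["ref"]
    perm = list(np.random.default_rng(1).permutation(pose.n_atoms))
    inv = {old: new for new, old in enumerate(perm)}
    permuted = LigandPose(
        ligand_id=pose.ligand_id, site_tag=pose.site_tag,
        conformation_tag=pose.conformation_tag, program_tag=pose.program_tag,
        elements=[pose.elements[i] for i in perm],
        coords=pose.coords[perm],
        formal_charges=[pose.formal_charges[i] for i in perm],
        bonds=[(inv[i], inv[j], o) for i, j, o in pose.bonds],
        scaffold_atoms=[inv[i] for i in pose.scaffold_atoms])
    a = ix.detect_interactions(pose, rna)
    b = ix.detect_interactions(permuted, rna)
    key = lambda i: (i.category, round(i.distance, 9), i.rna_residue)  # noqa
    assert sorted(map(key, a)) == sorted(map(key, b))


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def test_far_ligand_detects_nothing():
    model = RnaModel(1, [guanine_residue()])
    pose = make_ligand(["N", "C"], [[100, 0, 0], [101, 0, 0]], [(0, 1)],
                       charges=[1, 0])
    assert ix.detect_interactions(pose, model) == []


def test_charged_donor_near_phosphate_oxygen():
    """A charged N at 2.9 Å from OP1 yields exactly one hydrogen bond to
    that oxygen plus one cation-anion contact (and no other categories)."""
    res = guanine_residue()
    op1 = res.atom_position("OP1")
    pose = make_ligand(["N", "C"], [op1 + [0, 0, 2.9], op1 + [0, 0, 5.0]],
                       [(0, 1)], charges=[1, 0])
    inter = ix.detect_interactions(pose, RnaModel(1, [res]))
    cats = sorted(i.category for i in inter)
    assert cats == ["cation_anion", "hydrogen_bond"]
    hb = next(i for i in inter if i.category == "hydrogen_bond")
    assert hb.distance == pytest.approx(2.9, abs=1e-9)
    assert hb.rna_moiety == "phosphate"
    ca = next(i for i in inter if i.category == "cation_anion")
    assert ca.distance == pytest.approx(2.9, abs=1e-9)


def test_parallel_stacked_rings():
    """Parallel rings 3.5 Å apart along the normal stack; at a 4 Å lateral
    offset the geometry fails the offset criterion."""
    res = guanine_residue()
    ring_centroid = np.zeros(3)
    coords = [[1.4 * np.cos(np.radians(60 * k)),
               1.4 * np.sin(np.radians(60 * k)), 3.5] for k in range(6)]
    bonds = [(k, (k + 1) % 6) for k in range(6)]
    pose = make_ligand(["C"] * 6, coords, bonds)
    inter = [i for i in ix.detect_interactions(pose, RnaModel(1, [res]))
             if i.category == "pi_stacking"]
    assert len(inter) == 1
    assert inter[0].distance == pytest.approx(3.5, abs=1e-6)
    shifted = make_ligand(["C"] * 6,
                          np.asarray(coords) + [4.0, 0, 0], bonds)
    far = [i for i in ix.detect_interactions(shifted, RnaModel(1, [res]))
           if i.category == "pi_stacking"]
    assert far == []


def test_hbond_angle_criterion_with_explicit_h():
    """With an explicit H pointing away from the acceptor the donor-H-A
    angle fails and no hydrogen bond is recorded; pointing toward, it is."""
    res = guanine_residue()
    o6 = res.atom_position("O6")
    d = o6 + [0, 0, 3.0]
    toward = make_ligand(["N", "H"], [d, d - [0, 0, 1.0]], [(0, 1)])
    away = make_ligand(["N", "H"], [d, d + [0, 0, 1.0]], [(0, 1)])
    hits = lambda p: [i for i in ix.detect_interactions(p, RnaModel(1, [res]))  # noqa
                      if i.category == "hydrogen_bond"
                      and abs(i.distance - 3.0) < 1e-9]
    assert len(hits(toward)) == 1
    assert hits(away) == []


def test_halogen_bond_geometry():
    res = guanine_residue()
    o6 = res.atom_position("O6")
    x = o6 + [0, 0, 3.5]
    linear = make_ligand(["C", "Cl"], [x + [0, 0, 1.8], x], [(0, 1)])
    bent = make_ligand(["C", "Cl"], [x + [1.8, 0, 0], x], [(0, 1)])
    hits = lambda p: [i for i in ix.detect_interactions(p, RnaModel(1, [res]))  # noqa
                      if i.category == "halogen_bond"
                      and abs(i.distance - 3.5) < 1e-9]
    assert len(hits(linear)) == 1
    assert hits(bent) == []


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

def test_histogram_bin_arithmetic():
    """One hydrogen bond at 3.0 Å lands in bin 13 of the hydrogen-bond row
    under the 2-8 Å / 80-bin default (bin width 0.075 Å)."""
    inter = [ix.Interaction("hydrogen_bond", 3.0, 0, 1, "base")]
    h = ix.fingerprint_histogram(inter)
    assert h.shape == (7, 80)
    assert h[0, 13] == 1
    assert h.sum() == 1


def test_histogram_empty_and_out_of_range():
    assert ix.fingerprint_histogram([]).sum() == 0
    dropped = [ix.Interaction("lipophilic", 9.5, 0, 1, "base"),
               ix.Interaction("hydrogen_bond", 1.0, 0, 1, "base")]
    assert ix.fingerprint_histogram(dropped).sum() == 0


def test_histogram_conservation_and_sensitivity():
    rng = np.random.default_rng(8)
    cats = list(ix.CATEGORY_ORDER)
    inter = [ix.Interaction(cats[int(rng.integers(7))],
                            float(rng.uniform(0.5, 9.5)), 0, 1, "base")
             for _ in range(300)]
    h = ix.fingerprint_histogram(inter)
    for ci, cat in enumerate(cats):
        n_in = sum(1 for i in inter
                   if i.category == cat and 2.0 <= i.distance < 8.0)
        assert h[ci].sum() == n_in
    # adding one in-range interaction changes exactly one bin by +1
    h2 = ix.fingerprint_histogram(
        inter + [ix.Interaction("pi_cation", 4.321, 0, 1, "base")])
    diff = h2 - h
    assert diff.sum() == 1 and (diff != 0).sum() == 1


def test_fingerprint_matrix_shape(small_scenario):
    rows = ix.fingerprint_matrix(small_scenario["poses"][:10],
                                 small_scenario["ref"])
    assert rows.shape == (10, 560)
    assert np.all(rows >= 0)


# ---------------------------------------------------------------------------
# Average profiles
# ---------------------------------------------------------------------------

def test_average_profile_basics():
    row0 = np.zeros(560)
    row2 = np.full(560, 2.0)
    prof = ix.average_profile(np.stack([row0, row2]), ["a", "a"])
    np.testing.assert_allclose(prof["a"], 1.0)
    single = ix.average_profile(row2[None, :], ["b"])
    np.testing.assert_allclose(single["b"].ravel(), row2)
    with pytest.raises(ValueError):
        ix.average_profile(np.zeros((0, 560)), [])


def test_average_profile_recovers_planted_peaks():
    """Two groups with lipophilic contacts planted at 4.5/5.5 Å versus a
    sharp 5.0 Å peak have group means peaking at the planted bins."""
    cfg = ix.FingerprintConfig()
    li = ix.CATEGORY_INDEX["lipophilic"]

    def rows_for(dists, n):
        out = []
        for _ in range(n):
            inter = [ix.Interaction("lipophilic", d, 0, 1, "base")
                     for d in dists]
            out.append(ix.fingerprint_histogram(inter, cfg).ravel())
        return out

    rows = np.array(rows_for([4.5, 5.5], 20) + rows_for([5.0], 20))
    prof = ix.average_profile(rows, ["bimodal"] * 20 + ["sharp"] * 20, cfg)
    centers = cfg.bin_edges()[:-1]
    sharp_peak = centers[np.argmax(prof["sharp"][li])]
    assert sharp_peak == pytest.approx(5.0, abs=cfg.bin_width)
    bim = prof["bimodal"][li]
    top2 = sorted(centers[np.argsort(bim)[-2:]])
    assert top2[0] == pytest.approx(4.5, abs=cfg.bin_width)
    assert top2[1] == pytest.approx(5.5, abs=cfg.bin_width)
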