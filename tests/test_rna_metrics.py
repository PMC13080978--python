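import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from conftest import random_rigid_transform, transform_model
from rnapose import rna_metrics as rm
from rnapose import synthetic_data as sd
from rnapose.io_formats import Residue, RnaModel


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def gram_schmidt_frame(c2, c4, c6):
    """Brute-force frame construction, independent of the implementation."""
    origin = (c2 + c4 + c6) / 3.0
    x = (c2 - origin) / np.linalg.norm(c2 - origin)
    y = (c4 - origin) - np.dot(c4 - origin, x) * x
    y = y / np.linalg.norm(y)
    return origin, x, y, np.cross(x, y)


def gvector_scalar(r, a=5.0, b=3.0, r_cut=2.4):
    """Standalone scalar evaluation of the g-vector formula."""
    gamma = np.pi / r_cut
    rt = np.array([r[0] / a, r[1] / a, r[2] / b])
    rho = np.linalg.norm(rt)
    if rho >= r_cut:
        return np.zeros(4)
    return np.array([np.sin(gamma * rho) * rt[0] / rho,
                     np.sin(gamma * rho) * rt[1] / rho,
                     np.sin(gamma * rho) * rt[2] / rho,
                     1.0 + np.cos(gamma * rho)])


def ermsd_brute_force(model_a, model_b):
    """Monolithic oracle: frames, g-vectors and the sum in one slow pass."""
    def frames(model):
        out = []
        for res in model.residues:
            o, x, y, z = gram_schmidt_frame(res.atom_position("C2"),
                                            res.atom_position("C4"),
                                            res.atom_position("C6"))
            out.append((o, np.array([x, y, z])))
        return out

    fa, fb = frames(model_a), frames(model_b)
    n = len(fa)
    total = 0.0
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            ga = gvector_scalar(fa[j][1] @ (fa[k][0] - fa[j][0]))
            gb = gvector_scalar(fb[j][1] @ (fb[k][0] - fb[j][0]))
            total += np.sum((ga - gb) ** 2)
    return np.sqrt(total / n)


def quaternion_superposition_rmsd(xa, xb):
    """Horn's quaternion method, independent of the Kabsch implementation."""
    ya = xa - xa.mean(axis=0)
    yb = xb - xb.mean(axis=0)
    m = ya.T @ yb
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k)[-1]
    e2 = max(np.sum(ya ** 2) + np.sum(yb ** 2) - 2 * lam, 0.0)
    return np.sqrt(e2 / len(xa))


def _single_residue_model(c2, c4, c6):
    coords = np.array([c2, c4, c6])
    return RnaModel(1, [Residue(1, "A", ["C2", "C4", "C6"],
                                ["C", "C", "C"], coords)])


# ---------------------------------------------------------------------------
# Base frames
# ---------------------------------------------------------------------------

def test_planar_frame_construction():
    m = _single_residue_model([1, 0, 0], [-0.5, 0.866, 0], [-0.5, -0.866, 0])
    frame = rm.compute_base_frames(m)[0]
    np.testing.assert_allclose(frame.origin, [0, 0, 0], atol=1e-3)
    np.testing.assert_allclose(frame.axes[0], [1, 0, 0], atol=1e-3)
    assert abs(abs(frame.axes[2][2]) - 1.0) < 1e-3


def test_frames_match_gram_schmidt_oracle(helix20):
    frames = rm.compute_base_frames(helix20)
    for res, frame in zip(helix20.residues, frames):
        o, x, y, z = gram_schmidt_frame(res.atom_position("C2"),
                                        res.atom_position("C4"),
                                        res.atom_position("C6"))
        np.testing.assert_allclose(frame.origin, o, atol=1e-12)
        np.testing.assert_allclose(frame.axes, np.array([x, y, z]),
                                   atol=1e-12)


def test_frame_equivariance_under_rotation(helix20):
    rng = np.random.default_rng(5)
    rot, shift = random_rigid_transform(rng)
    moved = transform_model(helix20, rot, shift)
    f0 = rm.compute_base_frames(helix20)
    f1 = rm.compute_base_frames(moved)
    for a, b in zip(f0, f1):
        np.testing.assert_allclose(b.origin, rot.apply(a.origin) + shift,
                                   atol=1e-9)
        np.testing.assert_allclose(b.axes, a.axes @ rot.as_matrix().T,
                                   atol=1e-9)


def test_collinear_ring_is_error():
    m = _single_residue_model([1, 0, 0], [2, 0, 0], [3, 0, 0])
    with pytest.raises(ValueError, match="residue 1"):
        rm.compute_base_frames(m)


# ---------------------------------------------------------------------------
# g-vectors
# ---------------------------------------------------------------------------

def test_gvector_beyond_cutoff_is_zero():
    assert np.all(gvector_scalar([30.0, 0, 0]) == 0)
    m = RnaModel(1, [
        Residue(1, "A", ["C2", "C4", "C6"], ["C"] * 3,
                np.array([[1, 0, 0], [-0.5, 0.866, 0], [-0.5, -0.866, 0.]])),
        Residue(2, "A", ["C2", "C4", "C6"], ["C"] * 3,
                np.array([[31, 0, 0], [29.5, 0.866, 0], [29.5, -0.866, 0.]])),
    ])
    field = rm.compute_gvectors(rm.compute_base_frames(m))
    assert np.all(field.g == 0)


def test_gvector_matches_scalar_oracle():
    """Hand-placed pair with r = (2.5, 0, 1.5) Å in the first frame."""
    r = np.array([2.5, 0.0, 1.5])
    ring = np.array([[1.4, 0, 0], [-0.7, 1.212, 0], [-0.7, -1.212, 0]])
    m = RnaModel(1, [
        Residue(1, "A", ["C2", "C4", "C6"], ["C"] * 3, ring),
        Residue(2, "A", ["C2", "C4", "C6"], ["C"] * 3, ring + r),
    ])
    field = rm.compute_gvectors(rm.compute_base_frames(m))
    np.testing.assert_allclose(field.g[0, 1], gvector_scalar(r), atol=1e-12)


def test_gvector_short_distance_limit():
    """As the rescaled separation tends to 0, the 4th component tends to 2
    and the in-plane part to gamma times the rescaled vector."""
    eps = 1e-6
    r = np.array([5.0 * eps / np.sqrt(2), 0.0, 3.0 * eps / np.sqrt(2)])
    g = gvector_scalar(r)
    gamma = np.pi / 2.4
    assert g[3] == pytest.approx(2.0, abs=1e-9)
    np.testing.assert_allclose(
        g[:3], gamma * np.array([r[0] / 5, r[1] / 5, r[2] / 3]), rtol=1e-6)


def test_nonzero_gvector_fourth_component_bounds(helix20):
    field = rm.compute_gvectors(rm.compute_base_frames(helix20))
    fourth = field.g[..., 3]
    nz = fourth[np.any(field.g != 0, axis=-1)]
    assert np.all(nz > 0) and np.all(nz <= 2.0)


# ---------------------------------------------------------------------------
# eRMSD
# ---------------------------------------------------------------------------

def test_ermsd_identity_and_symmetry(helix_ensemble):
    a, b = helix_ensemble[0], helix_ensemble[1]
    assert rm.ermsd_from_models(a, a).value == 0.0
    ab = rm.ermsd_from_models(a, b).value
    ba = rm.ermsd_from_models(b, a).value
    assert ab == ba
    assert ab > 0


def test_ermsd_rigid_motion_invariance(helix_ensemble):
    rng = np.random.default_rng(17)
    a, b = helix_ensemble[0], helix_ensemble[2]
    base = rm.ermsd_from_models(a, b).value
    for _ in range(5):
        rot, shift = random_rigid_transform(rng)
        moved = transform_model(b, rot, shift)
        assert abs(rm.ermsd_from_models(a, moved).value - base) < 1e-9


def test_ermsd_matches_brute_force_oracle(helix20):
    rng_seeds = range(30)
    spec = sd.EnsembleSpec(n_residues=20, n_models=2, rotation_sd=10.0,
                           translation_sd=0.5, seed=0)
    import dataclasses
    for seed in rng_seeds:
        ens = sd.perturb_ensemble(helix20,
                                  dataclasses.replace(spec, seed=seed))
        fast = rm.ermsd_from_models(ens[0], ens[1]).value
        slow = ermsd_brute_force(ens[0], ens[1])
        assert abs(fast - slow) < 1e-9


def test_ermsd_mismatched_residues_error(helix20):
    fa = rm.compute_gvectors(rm.compute_base_frames(helix20))
    sub = helix20.subset(range(1, 11))
    fb = rm.compute_gvectors(rm.compute_base_frames(sub))
    with pytest.raises(ValueError):
        rm.ermsd(fa, fb)


def test_mean_ermsd_monotone_in_perturbation(helix20):
    """Larger planted perturbations give larger mean eRMSD to the
    reference (the metric responds monotonically to disorder)."""
    magnitudes = [2.0, 5.0, 10.0, 20.0]
    means = []
    for mag in magnitudes:
        spec = sd.EnsembleSpec(n_residues=20, n_models=12, rotation_sd=mag,
                               translation_sd=mag / 40.0, seed=23)
        ens = sd.perturb_ensemble(helix20, spec)
        means.append(np.mean([rm.ermsd_from_models(helix20, m).value
                              for m in ens.models]))
    rho, _ = spearmanr(magnitudes, means)
    assert rho == 1.0


# ---------------------------------------------------------------------------
# Heavy-atom RMSD
# ---------------------------------------------------------------------------

def test_rmsd_identity_and_translation(helix20):
    assert rm.heavy_atom_rmsd(helix20, helix20) == pytest.approx(0.0, abs=1e-9)
    moved = transform_model(helix20, Rotation.identity(), np.array([3., 4., 5.]))
    assert rm.heavy_atom_rmsd(helix20, moved) == pytest.approx(0.0, abs=1e-9)


def test_rmsd_matches_quaternion_oracle(helix_ensemble):
    from rnapose.rna_metrics import _selected_coords

    for m in helix_ensemble.models[1:]:
        xa = _selected_coords(helix_ensemble[0], None)
        xb = _selected_coords(m, None)
        fast = rm.heavy_atom_rmsd(helix_ensemble[0], m)
        slow = quaternion_superposition_rmsd(xa, xb)
        assert abs(fast - slow) < 1e-6


def test_rmsd_selection_and_small_error(helix20):
    sel = rm.heavy_atom_rmsd(helix20, helix20,
                             selection=lambda i, n: i <= 5)
    assert sel == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        rm.heavy_atom_rmsd(helix20, helix20,
                           selection=lambda i, n: i == 1 and n == "C2")


# ---------------------------------------------------------------------------
# Site feature vectors
# ---------------------------------------------------------------------------

def test_site_feature_vector_lengths(helix20):
    field = rm.compute_gvectors(rm.compute_base_frames(helix20))
    assert rm.site_feature_vector(field, [3, 7]).shape == (8,)
    with pytest.raises(ValueError):
        rm.site_feature_vector(field, [])


def test_site_feature_vector_eight_residue_site():
    """An 8-residue binding-site selection on a 76-residue model yields
    4 * 8 * 7 = 224 features."""
    model = sd.make_idealized_helix(76, seed=0)[0]
    field = rm.compute_gvectors(rm.compute_base_frames(model))
    site = [11, 12, 13, 41, 42, 70, 71, 72]
    assert rm.site_feature_vector(field, site).shape == (224,)


def test_site_feature_vector_identity(helix_ensemble):
    f0 = rm.compute_gvectors(rm.compute_base_frames(helix_ensemble[0]))
    f1 = rm.compute_gvectors(rm.compute_base_frames(helix_ensemble[0]))
    site = [2, 5, 9]
    np.testing.assert_array_equal(rm.site_feature_vector(f0, site),
                                  rm.site_feature_vector(f1, site))
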