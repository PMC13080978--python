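"""RNA structural metrics: base reference frames, g-vectors, eRMSD, RMSD.

The eRMSD metric compares two RNA conformations through the relative
geometry of their nucleobases rather than raw coordinates.  Each base gets a
local right-handed frame built from its C2/C4/C6 ring atoms; the position of
every other base's origin, expressed in that frame and anisotropically
rescaled (in-plane length ``a``, normal length ``b``), is mapped to a smooth
4-component "g-vector" that vanishes beyond a dimensionless cutoff
``r_cut``.  The eRMSD between two conformations is the root-mean-square
difference of all pairwise g-vectors, normalised by the number of residues.
Because the g-vectors respond to base-base geometry, values above roughly
0.7-0.8 (in this package's normalisation) indicate a changed base-pairing
pattern, whereas plain RMSD only measures overall displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .io_formats import FRAME_ATOMS, RnaModel


@dataclass
class ErmsdParameters:
    """Constants of the g-vector metric.

    a: in-plane rescaling length (Å); b: normal rescaling length (Å);
    r_cut: rescaled-distance cutoff (dimensionless). gamma is fixed to
    pi / r_cut so the 4th g-vector component goes smoothly to zero at the
    cutoff.
    """

    a: float = 5.0
    b: float = 3.0
    r_cut: float = 2.4

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.r_cut) <= 0:
            raise ValueError("a, b, r_cut must all be positive")

    @property
    def gamma(self) -> float:
        return np.pi / self.r_cut


@dataclass
class BaseFrame:
    """Local orthonormal frame of one nucleobase.

    origin: centroid of C2/C4/C6; axes rows are the local x (origin->C2),
    y (component of origin->C4 orthogonal to x) and z = x × y unit vectors.
    """

    residue_index: int
    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError(f"residue {self.residue_index}: axes not orthonormal")
        if abs(np.linalg.det(self.axes) - 1.0) > 1e-8:
            raise ValueError(f"residue {self.residue_index}: axes not right-handed")


@dataclass
class GVectorField:
    """All pairwise g-vectors of one conformation.

    ``g[j, k]`` is the 4-vector describing base ``k`` seen from the frame of
    base ``j`` (zero on the diagonal and beyond the cutoff); ``rho`` holds the
    rescaled separations.
    """

    residue_indices: list[int]
    g: np.ndarray            # (N, N, 4)
    rho: np.ndarray          # (N, N)
    params: ErmsdParameters

    @property
    def n_residues(self) -> int:
        return len(self.residue_indices)


@dataclass
class ErmsdValue:
    value: float
    n_residues: int


def compute_base_frames(model: RnaModel) -> list[BaseFrame]:
    """Build one base frame per residue from its C2/C4/C6 atoms.

    The origin is the centroid of the three atoms; x points from the origin
    to C2, y is the component of origin->C4 orthogonal to x, z completes the
    right-handed triad.  Degenerate (collinear) ring geometry is an error.
    """
    frames: list[BaseFrame] = []
    for res in model.residues:
        pts = np.array([res.atom_position(a) for a in FRAME_ATOMS])
        origin = pts.mean(axis=0)
        vx = pts[0] - origin
        nx = np.linalg.norm(vx)
        if nx < 1e-9:
            raise ValueError(f"residue {res.index}: degenerate ring geometry")
        x = vx / nx
        v4 = pts[1] - origin
        vy = v4 - np.dot(v4, x) * x
        ny = np.linalg.norm(vy)
        if ny < 1e-9:
            raise ValueError(f"residue {res.index}: collinear C2/C4/C6")
        y = vy / ny
        z = np.cross(x, y)
        frames.append(BaseFrame(res.index, origin, np.array([x, y, z])))
    return frames


def compute_gvectors(
    frames: Sequence[BaseFrame], params: ErmsdParameters | None = None
) -> GVectorField:
    """Compute the 4-component g-vector for every ordered residue pair.

    For pair (j, k): r is origin_k in frame j; r~ = (r_x/a, r_y/a, r_z/b);
    rho~ = |r~|. Inside the cutoff,
    G = (sin(g·rho)·r~/rho, 1 + cos(g·rho)) with g = pi/r_cut; outside, G = 0.
    """
    if params is None:
        params = ErmsdParameters()
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    origins = np.array([f.origin for f in frames])            # (N, 3)
    axes = np.array([f.axes for f in frames])                 # (N, 3, 3)
    n = len(frames)
    # r[j, k] = axes_j @ (origin_k - origin_j)
    diff = origins[None, :, :] - origins[:, None, :]          # (N, N, 3)
    r = np.einsum("jab,jkb->jka", axes, diff)                 # (N, N, 3)
    scale = np.array([params.a, params.a, params.b])
    rt = r / scale
    rho = np.linalg.norm(rt, axis=-1)                         # (N, N)
    np.fill_diagonal(rho, np.inf)                             # no self pair
    if np.any(rho[np.isfinite(rho)] < 1e-9):
        raise ValueError("coincident residue origins")
    inside = rho < params.r_cut
    g = np.zeros((n, n, 4))
    gam = params.gamma
    rho_safe = np.where(inside, rho, 1.0)
    s = np.where(inside, np.sin(gam * rho_safe) / rho_safe, 0.0)
    g[..., :3] = s[..., None] * rt
    g[..., 3] = np.where(inside, 1.0 + np.cos(gam * rho_safe), 0.0)
    rho_out = np.where(np.isfinite(rho), rho, 0.0)
    return GVectorField([f.residue_index for f in frames], g, rho_out, params)


def ermsd(field_a: GVectorField, field_b: GVectorField) -> ErmsdValue:
    """eRMSD between two conformations from their g-vector fields.

    value = sqrt( (1/N) * sum over ordered pairs |G_a - G_b|^2 ), with N the
    residue count.  Zero iff the fields coincide; invariant under rigid
    motions of either conformation because the frames co-rotate.
    """
    if field_a.residue_indices != field_b.residue_indices:
        raise ValueError("g-vector fields cover different residue sets")
    n = field_a.n_residues
    d2 = np.sum((field_a.g - field_b.g) ** 2)
    return ErmsdValue(float(np.sqrt(d2 / n)), n)


def ermsd_from_models(
    model_a: RnaModel,
    model_b: RnaModel,
    params: ErmsdParameters | None = None,
    residue_selection: Iterable[int] | None = None,
) -> ErmsdValue:
    """Convenience wrapper: frames -> g-vectors -> eRMSD, with an optional
    residue subset (e.g. the poly(A) region or one binding site)."""
    if residue_selection is not None:
        model_a = model_a.subset(residue_selection)
        model_b = model_b.subset(residue_selection)
    fa = compute_gvectors(compute_base_frames(model_a), params)
    fb = compute_gvectors(compute_base_frames(model_b), params)
    return ermsd(fa, fb)


def ermsd_matrix(
    models: Sequence[RnaModel],
    params: ErmsdParameters | None = None,
    residue_selection: Iterable[int] | None = None,
) -> np.ndarray:
    """Symmetric matrix of pairwise eRMSD values over an ensemble."""
    fields = []
    for m in models:
        mm = m.subset(residue_selection) if residue_selection is not None else m
        fields.append(compute_gvectors(compute_base_frames(mm), params))
    n = len(fields)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = ermsd(fields[i], fields[j]).value
    return out


def _selected_coords(
    model: RnaModel, selection: Callable[[int, str], bool] | None
) -> np.ndarray:
    coords = []
    for res in model.residues:
        for name, elem, xyz in zip(res.atom_names, res.elements, res.coords):
            if elem == "H":
                continue
            if selection is None or selection(res.index, name):
                coords.append(xyz)
    return np.array(coords)


def heavy_atom_rmsd(
    model_a: RnaModel,
    model_b: RnaModel,
    selection: Callable[[int, str], bool] | None = None,
) -> float:
    """RMSD over selected heavy atoms after optimal rigid superposition.

    ``selection(residue_index, atom_name)`` restricts the atom set (default:
    all non-hydrogen atoms).  The least-squares rotation is found with the
    Kabsch algorithm; translation is removed by centroid subtraction.
    """
    xa = _selected_coords(model_a, selection)
    xb = _selected_coords(model_b, selection)
    if xa.shape != xb.shape:
        raise ValueError("selections yield different atom sets")
    if xa.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    ya, yb = xa - ca, xb - cb
    rot, _ = Rotation.align_vectors(ya, yb)
    yb_fit = rot.apply(yb)
    return float(np.sqrt(np.mean(np.sum((ya - yb_fit) ** 2, axis=1))))


def site_feature_vector(field: GVectorField, site_residues: Iterable[int]) -> np.ndarray:
    """Flatten the g-vectors of all ordered pairs inside one binding site.

    Pairs are taken in lexicographic (j, k) order over the site residues (in
    model residue order), giving a vector of length 4·m·(m−1) for m site
    residues.  This is the per-conformation feature vector used for
    site-restricted conformational PCA.
    """
    site = set(site_residues)
    if not site:
        raise ValueError("empty site")
    missing = site - set(field.residue_indices)
    if missing:
        raise ValueError(f"site residues {sorted(missing)} not in model")
    pos = [i for i, r in enumerate(field.residue_indices) if r in site]
    feats = []
    for j in pos:
        for k in pos:
            if j != k:
                feats.append(field.g[j, k])
    return np.concatenate(feats)
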