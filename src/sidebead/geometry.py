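"""Backbone geometry: chains, derived peptide atoms, rigid frames, oriented beads.

The model represents each residue by its three backbone heavy atoms N, CA, C.
Everything else is derived deterministically from those coordinates:

* the carbonyl O and amide H are placed by a rigid in-plane construction,
* a per-residue rigid frame is obtained by least-RMSD superposition of an
  ideal reference triple onto the actual N/CA/C positions,
* each coarse side-chain state is represented by a single oriented bead
  (position + unit direction) stored in the residue frame and mapped to the
  lab frame through that superposition.

All placements commute with global rigid motions.  The module also provides
the analytic Jacobians of every placement with respect to the backbone
coordinates; these are the building blocks for pulling derived-atom forces
back onto N/CA/C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AA3",
    "BackboneChain",
    "DerivedAtoms",
    "RigidFrame",
    "OrientedBead",
    "PeptideGeometry",
    "GeometryError",
    "ideal_backbone_triple",
    "place_peptide_atoms",
    "residue_frame",
    "frame_with_jacobian",
    "bead_placement",
    "dihedral",
    "dihedral_gradient",
    "bond_angle",
    "bond_angle_gradient",
    "nerf_place",
    "unit",
    "unit_jacobian",
]

AA3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

#: residues excluded from chi1 scoring (no rotatable chi1 or constrained ring)
CHI1_EXCLUDED = {"ALA", "GLY", "PRO"}


class GeometryError(ValueError):
    """Degenerate or invalid geometric input."""


# ---------------------------------------------------------------------------
# small vector helpers
# ---------------------------------------------------------------------------

def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("cannot normalize near-zero vector")
    return v / n


def unit_jacobian(v: np.ndarray) -> np.ndarray:
    """d(unit(v))/dv = (I - uu^T)/|v|."""
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("cannot normalize near-zero vector")
    u = v / n
    return (np.eye(3) - np.outer(u, u)) / n


def dihedral(a, b, c, d) -> float:
    """Signed dihedral angle (radians, in (-pi, pi]) of atoms a-b-c-d."""
    b1 = np.asarray(b) - np.asarray(a)
    b2 = np.asarray(c) - np.asarray(b)
    b3 = np.asarray(d) - np.asarray(c)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


def dihedral_gradient(a, b, c, d):
    """Analytic gradient of the dihedral with respect to the four atoms.

    Returns a (4, 3) array; rows sum to zero (translation invariance).
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    sq1 = np.dot(n1, n1)
    sq2 = np.dot(n2, n2)
    if sq1 < 1e-18 or sq2 < 1e-18 or nb2 < 1e-9:
        raise GeometryError("degenerate dihedral")
    ga = nb2 / sq1 * n1
    gd = -nb2 / sq2 * n2
    p = np.dot(b1, b2) / nb2**2
    q = np.dot(b3, b2) / nb2**2
    gb = -(p + 1.0) * ga + q * gd
    gc = p * ga - (q + 1.0) * gd
    return np.stack([ga, gb, gc, gd])


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in radians."""
    u = np.asarray(a) - np.asarray(b)
    v = np.asarray(c) - np.asarray(b)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def bond_angle_gradient(a, b, c):
    """Gradient of the a-b-c angle with respect to the three atoms, (3, 3)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    cosang = np.clip(np.dot(uh, vh), -1.0, 1.0)
    sinang = np.sqrt(max(1.0 - cosang**2, 1e-16))
    ga = -(vh - cosang * uh) / (nu * sinang)
    gc = -(uh - cosang * vh) / (nv * sinang)
    gb = -ga - gc
    return np.stack([ga, gb, gc])


def nerf_place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to atoms a-b-c.

    ``angle`` is the b-c-d angle and ``torsion`` the a-b-c-d dihedral, both in
    radians (natural extension reference frame construction).
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d2 = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(torsion),
        -np.sin(angle) * np.sin(torsion),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BackboneChain:
    """Ordered backbone trace: one (N, CA, C) triple per residue.

    Coordinates are in Angstrom; residue indexing is 0-based.
    """

    residue_types: list[str]
    N: np.ndarray   # (n, 3)
    CA: np.ndarray  # (n, 3)
    C: np.ndarray   # (n, 3)
    chain_id: str = "A"

    def __post_init__(self):
        self.N = np.asarray(self.N, dtype=float).reshape(-1, 3)
        self.CA = np.asarray(self.CA, dtype=float).reshape(-1, 3)
        self.C = np.asarray(self.C, dtype=float).reshape(-1, 3)
        n = len(self.residue_types)
        if n < 1:
            raise ValueError("chain must contain at least one residue")
        if not (self.N.shape[0] == self.CA.shape[0] == self.C.shape[0] == n):
            raise ValueError("coordinate arrays inconsistent with sequence length")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite backbone coordinates")
        if n > 1:
            gaps = np.linalg.norm(self.N[1:] - self.C[:-1], axis=1)
            if np.any(gaps <= 0.0) or not np.all(np.isfinite(gaps)):
                raise ValueError("invalid consecutive C->N distances")

    def __len__(self) -> int:
        return len(self.residue_types)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3, 3) array with atom axis ordered [N, CA, C]."""
        return np.stack([self.N, self.CA, self.C], axis=1)

    @classmethod
    def from_coords(cls, residue_types, coords, chain_id="A") -> "BackboneChain":
        coords = np.asarray(coords, dtype=float)
        return cls(list(residue_types), coords[:, 0], coords[:, 1], coords[:, 2],
                   chain_id=chain_id)

    def transformed(self, rotation=None, translation=None) -> "BackboneChain":
        R = np.eye(3) if rotation is None else np.asarray(rotation)
        t = np.zeros(3) if translation is None else np.asarray(translation)
        return BackboneChain(
            list(self.residue_types),
            self.N @ R.T + t, self.CA @ R.T + t, self.C @ R.T + t,
            chain_id=self.chain_id,
        )

    def phi_psi(self, i: int):
        """(phi, psi) of residue i in radians; missing values are None."""
        phi = psi = None
        if i > 0:
            phi = dihedral(self.C[i - 1], self.N[i], self.CA[i], self.C[i])
        if i < len(self) - 1:
            psi = dihedral(self.N[i], self.CA[i], self.C[i], self.N[i + 1])
        return phi, psi


@dataclass
class PeptideGeometry:
    """Fixed internal coordinates for the deterministic O/H placement.

    The carbonyl O sits in the CA/C/N(next) plane along the external bisector
    at the C=O bond length; the amide H sits in the C(prev)/N/CA plane along
    the external bisector at the N-H bond length (trans to the carbonyl).
    These are data, carried in the parameter file.
    """

    co_bond: float = 1.229   # Angstrom
    nh_bond: float = 1.010   # Angstrom
    # ideal-geometry backbone internal coordinates (springs, frame reference,
    # virtual-N extrapolation at the C terminus)
    n_ca_bond: float = 1.453
    ca_c_bond: float = 1.526
    c_n_bond: float = 1.300
    n_ca_c_angle_deg: float = 109.5
    ca_c_n_angle_deg: float = 120.0
    c_n_ca_angle_deg: float = 120.0


@dataclass
class DerivedAtoms:
    """Deterministically placed carbonyl O and amide H positions.

    ``has_H`` is False for the first residue and for proline.  Every residue
    carries an O (the C-terminal one via a virtual next-N extrapolated at
    ideal geometry through the residue frame).
    """

    O: np.ndarray        # (n, 3)
    H: np.ndarray        # (n, 3); rows with has_H False are NaN
    has_O: np.ndarray    # (n,) bool
    has_H: np.ndarray    # (n,) bool


@dataclass
class RigidFrame:
    """Rigid transform x -> rotation @ x + translation."""

    rotation: np.ndarray     # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) @ self.rotation.T + self.translation

    def apply_direction(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v) @ self.rotation.T


@dataclass
class OrientedBead:
    """Single-bead side-chain representative: position plus unit direction."""

    position: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        self.direction = d / np.linalg.norm(d)


def ideal_backbone_triple(geom: PeptideGeometry | None = None) -> np.ndarray:
    """Reference (N, CA, C) coordinates at ideal bond lengths/angles, (3, 3).

    CA at the origin, N on the -x axis, C in the xy plane.
    """
    g = geom or PeptideGeometry()
    theta = np.deg2rad(g.n_ca_c_angle_deg)
    N = np.array([-g.n_ca_bond, 0.0, 0.0])
    CA = np.zeros(3)
    C = g.ca_c_bond * np.array([-np.cos(theta), np.sin(theta), 0.0])
    return np.stack([N, CA, C])


def ideal_next_n(geom: PeptideGeometry | None = None) -> np.ndarray:
    """Reference-frame position of the following residue's N (psi = 180)."""
    g = geom or PeptideGeometry()
    ref = ideal_backbone_triple(g)
    return nerf_place(ref[0], ref[1], ref[2], g.c_n_bond,
                      np.deg2rad(g.ca_c_n_angle_deg), np.pi)


# ---------------------------------------------------------------------------
# derived-atom placement
# ---------------------------------------------------------------------------

def _bisector_place(center, nb1, nb2, bond):
    """Point at `bond` from `center` along the external bisector of the two
    center->neighbor directions; lies exactly in the neighbors' plane."""
    u1 = unit(np.asarray(nb1) - np.asarray(center))
    u2 = unit(np.asarray(nb2) - np.asarray(center))
    w = u1 + u2
    return np.asarray(center) + bond * (-w / np.linalg.norm(w))


def _bisector_jacobian(center, nb1, nb2, bond):
    """Jacobians of the bisector placement w.r.t. (center, nb1, nb2).

    Returns (3, 3, 3): leading axis indexes the defining atom.
    """
    center = np.asarray(center, dtype=float)
    v1 = np.asarray(nb1, dtype=float) - center
    v2 = np.asarray(nb2, dtype=float) - center
    u1, u2 = unit(v1), unit(v2)
    J1, J2 = unit_jacobian(v1), unit_jacobian(v2)
    w = u1 + u2
    nw = np.linalg.norm(w)
    Jw = (np.eye(3) - np.outer(w, w) / nw**2) / nw   # d(w/|w|)/dw
    # x = center - bond * (w/|w|)
    d_nb1 = -bond * Jw @ J1
    d_nb2 = -bond * Jw @ J2
    d_center = np.eye(3) - d_nb1 - d_nb2
    return np.stack([d_center, d_nb1, d_nb2])


def place_peptide_atoms(chain: BackboneChain,
                        geom: PeptideGeometry | None = None) -> DerivedAtoms:
    """Place carbonyl O and amide H atoms for every residue (Step 1).

    O_i lies in the plane of CA_i, C_i, N_{i+1} along the external bisector at
    the C=O bond length.  H_i lies in the plane of C_{i-1}, N_i, CA_i along
    the external bisector at the N-H length.  The first residue and prolines
    get no H.  The last residue's O uses a virtual next-N placed at ideal
    geometry through the residue frame.
    """
    g = geom or PeptideGeometry()
    n = len(chain)
    O = np.full((n, 3), np.nan)
    H = np.full((n, 3), np.nan)
    has_O = np.zeros(n, dtype=bool)
    has_H = np.zeros(n, dtype=bool)
    ref = ideal_backbone_triple(g)
    nref = ideal_next_n(g)
    for i in range(n):
        if i + 1 < n:
            next_n = chain.N[i + 1]
        else:
            fr = residue_frame(chain.N[i], chain.CA[i], chain.C[i], ref)
            next_n = fr.apply(nref)
        O[i] = _bisector_place(chain.C[i], chain.CA[i], next_n, g.co_bond)
        has_O[i] = True
        if i > 0 and chain.residue_types[i] != "PRO":
            H[i] = _bisector_place(chain.N[i], chain.C[i - 1], chain.CA[i],
                                   g.nh_bond)
            has_H[i] = True
    return DerivedAtoms(O=O, H=H, has_O=has_O, has_H=has_H)


# ---------------------------------------------------------------------------
# rigid frames (Kabsch superposition) and their Jacobians
# ---------------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Least-RMSD rigid superposition of reference points P onto targets Q.

    P, Q: (m, 3) with rows as corresponding points.  Returns (R, t) with
    R @ p + t the fitted image of p.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pbar = P.mean(axis=0)
    qbar = Q.mean(axis=0)
    H = (P - pbar).T @ (Q - qbar)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qbar - R @ pbar
    return R, t


def residue_frame(N, CA, C, reference: np.ndarray) -> RigidFrame:
    """Least-RMSD rigid superposition of the reference triple onto (N, CA, C).

    ``reference`` is a (3, 3) array of reference N/CA/C coordinates.  Raises
    GeometryError for collinear/degenerate triples.
    """
    Q = np.stack([np.asarray(N, float), np.asarray(CA, float),
                  np.asarray(C, float)])
    ref = np.asarray(reference, dtype=float)
    area = np.linalg.norm(np.cross(Q[1] - Q[0], Q[2] - Q[0]))
    if area < 1e-9:
        raise GeometryError("collinear backbone triple; frame undefined")
    R, t = _kabsch(ref, Q)
    return RigidFrame(rotation=R, translation=t)


def _horn_matrix(H: np.ndarray) -> np.ndarray:
    """Davenport/Horn 4x4 matrix whose top eigenvector is the optimal quaternion."""
    Sxx, Sxy, Sxz = H[0]
    Syx, Syy, Syz = H[1]
    Szx, Szy, Szz = H[2]
    return np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])


def _quat_to_matrix_and_grad(q: np.ndarray):
    """Rotation matrix of a unit quaternion (w, x, y, z) and dR/dq, (4, 3, 3).

    For unit q and perturbations orthogonal to q the homogeneous (quadratic)
    form has the same differential as the normalized one.
    """
    w, x, y, z = q
    R = np.array([
        [w * w + x * x - y * y - z * z, 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), w * w - x * x + y * y - z * z, 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), w * w - x * x - y * y + z * z],
    ])
    dW = 2 * np.array([[w, -z, y], [z, w, -x], [-y, x, w]])
    dX = 2 * np.array([[x, y, z], [y, -x, -w], [z, w, -x]])
    dY = 2 * np.array([[-y, x, w], [x, y, z], [-w, z, -y]])
    dZ = 2 * np.array([[-z, -w, x], [w, -z, y], [x, y, z]])
    return R, np.stack([dW, dX, dY, dZ])


def frame_with_jacobian(Q: np.ndarray, reference: np.ndarray):
    """Rigid frame plus its derivatives with respect to the target points.

    Q: (3, 3) actual N/CA/C coordinates; reference: (3, 3) reference triple.
    Returns (R, t, dR, dt) where dR has shape (3, 3, 3, 3) indexed by
    [atom, coordinate, :, :] and dt has shape (3, 3, 3).

    The rotation is computed through the quaternion (Davenport) eigenproblem;
    its derivative follows from first-order eigenvector perturbation of the
    4x4 matrix, which is linear in the target coordinates.
    """
    P = np.asarray(reference, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pbar = P.mean(axis=0)
    Pc = P - pbar
    qbar = Q.mean(axis=0)
    Qc = Q - qbar
    H = Pc.T @ Qc
    K = _horn_matrix(H)
    evals, evecs = np.linalg.eigh(K)
    q = evecs[:, -1]
    lam = evals[-1]
    R, dRdq = _quat_to_matrix_and_grad(q)
    t = qbar - R @ pbar

    # perturbation: dq = sum_m v_m (v_m^T dK q) / (lam - lam_m)
    gaps = lam - evals[:-1]
    if np.any(gaps < 1e-9):
        raise GeometryError("degenerate superposition; frame Jacobian undefined")
    Vm = evecs[:, :-1]                      # (4, 3)
    coeff = Vm / gaps[None, :]              # (4, 3)

    dR = np.zeros((3, 3, 3, 3))
    dt = np.zeros((3, 3, 3))
    eye = np.eye(3)
    for k in range(3):          # target atom
        for a in range(3):      # coordinate
            dH = np.outer(Pc[k], eye[a])
            dK = _horn_matrix(dH)
            dq = coeff @ (Vm.T @ (dK @ q))
            dRk = np.einsum("q,qij->ij", dq, dRdq)
            dR[k, a] = dRk
            dt[k, a] = eye[a] / 3.0 - dRk @ pbar
    return R, t, dR, dt


def bead_placement(frame: RigidFrame, residue_type: str, state: int,
                   bead_refs: dict) -> OrientedBead:
    """Map the stored reference bead of (residue_type, state) through a frame.

    ``bead_refs`` maps residue type -> dict with ``positions`` (n_states, 3)
    and ``directions`` (n_states, 3) in the residue frame.  The returned
    direction is renormalized.
    """
    try:
        ref = bead_refs[residue_type]
    except KeyError:
        raise KeyError(f"no bead reference data for residue type {residue_type!r}")
    pos = np.asarray(ref["positions"], dtype=float)
    dirs = np.asarray(ref["directions"], dtype=float)
    if not (0 <= state < pos.shape[0]):
        raise KeyError(
            f"state {state} out of range for {residue_type} "
            f"({pos.shape[0]} coarse states)")
    return OrientedBead(position=frame.apply(pos[state]),
                        direction=frame.apply_direction(dirs[state]))
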