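"""Backbone geometry: derived-atom placement, frames, beads, gradients."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sidebead import geometry as geo
from sidebead import synthetic as syn


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=seed).as_matrix()
    t = rng.normal(scale=5.0, size=3)
    return R, t


# --------------------------------------------------------------------------
# independent NERF oracle (test-side implementation, distinct from package)
# --------------------------------------------------------------------------

def nerf_oracle(a, b, c, bond, angle, torsion):
    """Internal-coordinate placement via an explicit local frame."""
    a, b, c = map(np.asarray, (a, b, c))
    bc = (c - b) / np.linalg.norm(c - b)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


class TestPeptideAtomPlacement:
    def test_rigid_equivariance(self):
        chain = syn.gen_toy_protein(0, 6, "random", noise=0.1)
        da = geo.place_peptide_atoms(chain)
        for seed in range(5):
            R, t = random_rigid(seed)
            da2 = geo.place_peptide_atoms(chain.transformed(R, t))
            assert np.allclose(da.O @ R.T + t, da2.O, atol=1e-9)
            mask = da.has_H
            assert np.allclose(da.H[mask] @ R.T + t, da2.H[mask], atol=1e-9)

    def test_matches_nerf_oracle_on_ideal_dipeptide(self):
        """O/H from the bisector construction equal an independent
        internal-coordinate (NERF) placement on an ideal dipeptide."""
        g = geo.PeptideGeometry()
        chain = syn.gen_toy_protein(0, 2, "extended", geom=g)
        assert np.isclose(np.linalg.norm(chain.N[1] - chain.C[0]), 1.300)
        da = geo.place_peptide_atoms(chain, g)
        # O_0: bond 1.229, angle(CA, C, O) = 180 - gamma/2, torsion 180
        gamma = geo.bond_angle(chain.CA[0], chain.C[0], chain.N[1])
        O_ref = nerf_oracle(chain.N[1], chain.CA[0], chain.C[0],
                            g.co_bond, np.pi - gamma / 2, np.pi)
        assert np.allclose(da.O[0], O_ref, atol=1e-9)
        # H_1: bond 1.010, angle(C_0, N_1, H) = 180 - gamma/2, torsion 180
        gamma = geo.bond_angle(chain.C[0], chain.N[1], chain.CA[1])
        H_ref = nerf_oracle(chain.CA[1], chain.C[0], chain.N[1],
                            g.nh_bond, np.pi - gamma / 2, np.pi)
        assert np.allclose(da.H[1], H_ref, atol=1e-9)

    def test_planarity(self):
        chain = syn.gen_toy_protein(3, 5, "random", noise=0.2)
        da = geo.place_peptide_atoms(chain)
        for i in range(4):
            n = np.cross(chain.CA[i] - chain.C[i], chain.N[i + 1] - chain.C[i])
            n /= np.linalg.norm(n)
            assert abs(np.dot(da.O[i] - chain.C[i], n)) < 1e-6
        for i in range(1, 5):
            if not da.has_H[i]:
                continue
            n = np.cross(chain.C[i - 1] - chain.N[i], chain.CA[i] - chain.N[i])
            n /= np.linalg.norm(n)
            assert abs(np.dot(da.H[i] - chain.N[i], n)) < 1e-6

    def test_terminal_and_proline_rules(self):
        chain = syn.gen_toy_protein(
            0, 4, "helix", residue_types=["SER", "PRO", "VAL", "LEU"])
        da = geo.place_peptide_atoms(chain)
        assert not da.has_H[0]            # N terminus
        assert not da.has_H[1]            # proline
        assert da.has_H[2] and da.has_H[3]
        assert da.has_O.all()             # C-terminal O via virtual N

    def test_deterministic(self):
        chain = syn.gen_toy_protein(0, 5, "helix")
        a = geo.place_peptide_atoms(chain)
        b = geo.place_peptide_atoms(chain)
        assert np.array_equal(a.O, b.O)
        assert np.array_equal(a.H[a.has_H], b.H[b.has_H])


# --------------------------------------------------------------------------
# independent quaternion (Horn) superposition oracle
# --------------------------------------------------------------------------

def horn_oracle(P, Q):
    pbar, qbar = P.mean(0), Q.mean(0)
    S = (P - pbar).T @ (Q - qbar)
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    w, V = np.linalg.eigh(K)
    q = V[:, -1]
    R = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
    return R, qbar - R @ pbar


class TestResidueFrame:
    def test_identity(self):
        ref = geo.ideal_backbone_triple()
        fr = geo.residue_frame(ref[0], ref[1], ref[2], ref)
        assert np.allclose(fr.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(fr.translation, 0.0, atol=1e-9)

    def test_orthonormal_and_proper(self):
        ref = geo.ideal_backbone_triple()
        rng = np.random.default_rng(0)
        for _ in range(20):
            Q = ref + rng.normal(scale=0.3, size=(3, 3))
            fr = geo.residue_frame(Q[0], Q[1], Q[2], ref)
            R = fr.rotation
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
            assert np.isclose(np.linalg.det(R), 1.0, atol=1e-9)

    def test_least_rmsd_vs_random_transforms(self):
        ref = geo.ideal_backbone_triple()
        rng = np.random.default_rng(1)
        Q = ref @ Rotation.random(random_state=2).as_matrix().T + \
            rng.normal(size=3) + rng.normal(scale=0.2, size=(3, 3))
        fr = geo.residue_frame(Q[0], Q[1], Q[2], ref)
        best = np.sum((ref @ fr.rotation.T + fr.translation - Q) ** 2)
        for seed in range(1000):
            R, t = random_rigid(seed + 10)
            rmsd = np.sum((ref @ R.T + t - Q) ** 2)
            assert best <= rmsd + 1e-9

    def test_agrees_with_quaternion_oracle(self):
        ref = geo.ideal_backbone_triple()
        rng = np.random.default_rng(7)
        for _ in range(20):
            Q = ref @ Rotation.random(
                random_state=int(rng.integers(1000))).as_matrix().T \
                + rng.normal(size=3) + rng.normal(scale=0.2, size=(3, 3))
            fr = geo.residue_frame(Q[0], Q[1], Q[2], ref)
            R2, t2 = horn_oracle(ref, Q)
            assert np.abs(fr.rotation - R2).max() < 1e-8
            assert np.abs(fr.translation - t2).max() < 1e-8

    def test_collinear_raises(self):
        ref = geo.ideal_backbone_triple()
        with pytest.raises(geo.GeometryError):
            geo.residue_frame([0, 0, 0], [1, 0, 0], [2, 0, 0], ref)

    def test_frame_jacobian_matches_fd(self):
        ref = geo.ideal_backbone_triple()
        rng = np.random.default_rng(3)
        Q = ref @ Rotation.random(random_state=5).as_matrix().T + \
            rng.normal(size=3) + 0.1 * rng.normal(size=(3, 3))
        R, t, dR, dt = geo.frame_with_jacobian(Q, ref)
        h = 1e-6
        for k in range(3):
            for a in range(3):
                Qp, Qm = Q.copy(), Q.copy()
                Qp[k, a] += h
                Qm[k, a] -= h
                Rp, tp, _, _ = geo.frame_with_jacobian(Qp, ref)
                Rm, tm, _, _ = geo.frame_with_jacobian(Qm, ref)
                assert np.abs((Rp - Rm) / (2 * h) - dR[k, a]).max() < 1e-6
                assert np.abs((tp - tm) / (2 * h) - dt[k, a]).max() < 1e-6


class TestBeadPlacement:
    refs = {"SER": {"positions": np.array([[1.0, 0.5, 0.3],
                                           [0.2, 1.5, -0.4]]),
                    "directions": np.array([[0.0, 0.0, 2.0],
                                            [1.0, 1.0, 0.0]])}}

    def test_identity_frame_returns_reference(self):
        fr = geo.RigidFrame(np.eye(3), np.zeros(3))
        bead = geo.bead_placement(fr, "SER", 0, self.refs)
        assert np.allclose(bead.position, [1.0, 0.5, 0.3])
        assert np.allclose(bead.direction, [0.0, 0.0, 1.0])  # renormalized

    def test_rigid_equivariance(self):
        R, t = random_rigid(4)
        fr = geo.RigidFrame(R, t)
        bead = geo.bead_placement(fr, "SER", 1, self.refs)
        ref_d = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        assert np.allclose(bead.position, R @ [0.2, 1.5, -0.4] + t)
        assert np.allclose(bead.direction, R @ ref_d)

    def test_lookup_errors(self):
        fr = geo.RigidFrame(np.eye(3), np.zeros(3))
        with pytest.raises(KeyError):
            geo.bead_placement(fr, "TRP", 0, self.refs)
        with pytest.raises(KeyError):
            geo.bead_placement(fr, "SER", 5, self.refs)


class TestDifferentialGeometry:
    def test_dihedral_gradient_matches_fd(self):
        rng = np.random.default_rng(11)
        h = 1e-6
        for _ in range(10):
            pts = rng.normal(scale=2.0, size=(4, 3))
            grad = geo.dihedral_gradient(*pts)
            assert abs(grad.sum(axis=0)).max() < 1e-9   # translation invariance
            for k in range(4):
                for a in range(3):
                    pp, pm = pts.copy(), pts.copy()
                    pp[k, a] += h
                    pm[k, a] -= h
                    fd = (geo.dihedral(*pp) - geo.dihedral(*pm)) / (2 * h)
                    assert abs(fd - grad[k, a]) < 1e-6

    def test_bond_angle_gradient_matches_fd(self):
        rng = np.random.default_rng(13)
        h = 1e-6
        for _ in range(10):
            pts = rng.normal(scale=2.0, size=(3, 3))
            grad = geo.bond_angle_gradient(*pts)
            for k in range(3):
                for a in range(3):
                    pp, pm = pts.copy(), pts.copy()
                    pp[k, a] += h
                    pm[k, a] -= h
                    fd = (geo.bond_angle(*pp) - geo.bond_angle(*pm)) / (2 * h)
                    assert abs(fd - grad[k, a]) < 1e-6


class TestBackboneChain:
    def test_validation(self):
        with pytest.raises(ValueError):
            geo.BackboneChain([], np.zeros((0, 3)), np.zeros((0, 3)),
                              np.zeros((0, 3)))
        with pytest.raises(ValueError):
            geo.BackboneChain(["ALA"], [[np.nan, 0, 0]], [[1, 0, 0]],
                              [[2, 1, 0]])

    def test_phi_psi_termini(self):
        chain = syn.gen_toy_protein(0, 4, "helix")
        phi, psi = chain.phi_psi(0)
        assert phi is None and psi is not None
        phi, psi = chain.phi_psi(3)
        assert phi is not None and psi is None
        phi, psi = chain.phi_psi(1)
        assert np.isclose(np.rad2deg(phi), -57.0, atol=1e-6)
        assert np.isclose(np.rad2deg(psi), -47.0, atol=1e-6)
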