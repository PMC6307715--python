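"""Analytic derivatives of the side-chain free energy w.r.t. the backbone.

Because the BP marginals minimize the Bethe free energy, its total backbone
derivative reduces to the expectation of the energy derivatives (the
envelope identity): the entropy contributes nothing, and

    dG^SC/db_k = sum_i sum_s p_i(s) dv_i(s)/db_k
              + sum_edges sum_{s,s'} p_ij(s,s') dv_ij(s,s')/db_k.

The energy derivatives chain through every placement: the Kabsch residue
frames (quaternion eigenvector perturbation), the carbonyl-O / amide-H
bisector constructions and their directions, the backbone interaction
beads, the phi/psi dependence of the rotamer prior, and the hydrogen-bond
confidence factors kappa = 1 - f.  All Jacobians are analytic; finite
differences guard correctness in the test suite.
"""

from __future__ import annotations

import warnings

import numpy as np

from .geometry import (
    dihedral_gradient, frame_with_jacobian, ideal_next_n, unit_jacobian,
    _bisector_jacobian,
)
from .potential import SideChainSystem, _block_geometry
from .free_energy import MarginalSet
from .tables import periodic_bilinear

__all__ = ["side_chain_gradient", "side_chain_forces", "pullback_forces",
           "derived_atom_jacobians"]


def pullback_forces(site_force: np.ndarray, jacobian_entries,
                    grad_out: np.ndarray) -> None:
    """Transfer a (negated-force) gradient on a derived site onto backbone atoms.

    ``jacobian_entries`` is a list of (residue, atom, J) with J the (3, 3)
    matrix d(site)/d(atom coords); ``grad_out`` is the (n, 3, 3) accumulator.
    The transfer is exact for rigid placements and linear in the force.
    """
    for (res, atom, J) in jacobian_entries:
        grad_out[res, atom] += J.T @ site_force


def _block_energy_grad(entry, y1, n1, y2, n2, kappa, cfg, directional):
    """Eq-17 energy block and its gradients w.r.t. y1, n1, y2, n2.

    Shapes: E (S1, S2); gy1, gn1 (S1, S2, 3); gy2, gn2 (S1, S2, 3).
    """
    r, n12, x1, x2 = _block_geometry(y1, n1, y2, n2)
    vr, ang1, ang2, vang = entry.curves()
    Vr = vr(r)
    dVr = vr.derivative(r)
    S1, S2 = r.shape
    gy1 = dVr[..., None] * n12
    gn1 = np.zeros((S1, S2, 3))
    gn2 = np.zeros((S1, S2, 3))
    if cfg.repulsive_only:
        mask = (Vr > 0)[..., None]
        E = np.maximum(Vr, 0.0)
        gy1 = np.where(mask, gy1, 0.0)
    else:
        E = Vr.copy()
        use_dir = directional and not cfg.isotropic_only and x1 is not None
        if use_dir:
            A1, A2, Va = ang1(x1), ang2(x2), vang(r)
            dA1 = ang1.derivative(x1)
            dA2 = ang2.derivative(x2)
            dVa = vang.derivative(r)
            E = E + A1 * A2 * Va
            ndot1 = -x1  # n1 . n12
            ndot2 = x2
            rr = np.where(r < 1e-12, 1.0, r)
            dx1_dy1 = -(n1[:, None, :] - ndot1[..., None] * n12) / rr[..., None]
            dx2_dy1 = (n2[None, :, :] - ndot2[..., None] * n12) / rr[..., None]
            extra = ((A2 * Va * dA1)[..., None] * dx1_dy1
                     + (A1 * Va * dA2)[..., None] * dx2_dy1
                     + (A1 * A2 * dVa)[..., None] * n12)
            gy1 = gy1 + extra
            gn1 = (A2 * Va * dA1)[..., None] * (-n12)
            gn2 = (A1 * Va * dA2)[..., None] * n12
    gy2 = -gy1
    return kappa * E, kappa * gy1, kappa * gn1, kappa * gy2, kappa * gn2


def derived_atom_jacobians(chain, derived, geom, frame_jacs=None):
    """Jacobian entries of every O/H placement w.r.t. backbone atoms.

    Returns (O_jac, H_jac, Odir_jac, Hdir_jac): per residue a list of
    (residue, atom, J) entries with J = d(site)/d(atom coords), or None
    where the site is absent.  ``frame_jacs`` optionally supplies
    precomputed per-residue (R, t, dR, dt) tuples (only the last residue's
    frame is needed, for the virtual-N carbonyl placement).
    """
    n = len(chain)
    ref_triple = None
    nref = ideal_next_n(geom)
    O_jac = [None] * n
    H_jac = [None] * n
    Odir_jac = [None] * n
    Hdir_jac = [None] * n
    for i in range(n):
        if i + 1 < n:
            nxt = chain.N[i + 1]
            B = _bisector_jacobian(chain.C[i], chain.CA[i], nxt, geom.co_bond)
            entries = [(i, 2, B[0]), (i, 1, B[1]), (i + 1, 0, B[2])]
        else:
            if frame_jacs is not None:
                R, t, dR, dt = frame_jacs[i]
            else:
                from .geometry import ideal_backbone_triple
                ref_triple = ideal_backbone_triple(geom)
                R, t, dR, dt = frame_with_jacobian(chain.coords[i], ref_triple)
            nxt = R @ nref + t
            B = _bisector_jacobian(chain.C[i], chain.CA[i], nxt, geom.co_bond)
            entries = [(i, 2, B[0]), (i, 1, B[1])]
            # chain rule through the frame for the virtual N
            for k in range(3):
                J = np.zeros((3, 3))
                for a in range(3):
                    J[:, a] = B[2] @ (dR[k, a] @ nref + dt[k, a])
                entries.append((i, k, J))
        O_jac[i] = _merge_entries(entries)
        JU = unit_jacobian(derived.O[i] - chain.C[i])
        dir_entries = [(res, atom, JU @ J) for res, atom, J in O_jac[i]]
        dir_entries.append((i, 2, -JU))
        Odir_jac[i] = _merge_entries(dir_entries)

        if derived.has_H[i]:
            B = _bisector_jacobian(chain.N[i], chain.C[i - 1], chain.CA[i],
                                   geom.nh_bond)
            entries = [(i, 0, B[0]), (i - 1, 2, B[1]), (i, 1, B[2])]
            H_jac[i] = entries
            JU = unit_jacobian(derived.H[i] - chain.N[i])
            dir_entries = [(res, atom, JU @ J) for res, atom, J in entries]
            dir_entries.append((i, 0, -JU))
            Hdir_jac[i] = _merge_entries(dir_entries)
    return O_jac, H_jac, Odir_jac, Hdir_jac


class _Placements:
    """Per-residue placement Jacobians for one system configuration."""

    def __init__(self, system: SideChainSystem):
        self.sys = system
        chain = system.chain
        params = system.params
        n = len(chain)
        ref = params.reference_triple
        X = chain.coords

        self.dR = []
        self.dt = []
        self.bead_dy = []   # (S, 3, 3, 3): state, atom, coord, site-xyz
        self.bead_dn = []
        frame_jacs = []
        for i in range(n):
            R, t, dR, dt = frame_with_jacobian(X[i], ref)
            frame_jacs.append((R, t, dR, dt))
            self.dR.append(dR)
            self.dt.append(dt)
            rt = chain.residue_types[i]
            xr = params.bead_positions[rt]
            # raw frame direction before renormalization
            draw = params.bead_directions[rt]
            dlen = np.linalg.norm(draw, axis=-1, keepdims=True)
            dr = draw / dlen
            self.bead_dy.append(
                np.einsum("kaij,sj->skai", dR, xr) + dt[None, :, :, :])
            self.bead_dn.append(np.einsum("kaij,sj->skai", dR, dr))

        self.O_jac, self.H_jac, self.Odir_jac, self.Hdir_jac = (
            derived_atom_jacobians(chain, system.derived, params.geom,
                                   frame_jacs=frame_jacs))

    def site_entries(self, site: str, j: int):
        """Jacobian entries for a backbone site's position and direction."""
        if site == "O":
            return self.O_jac[j], self.Odir_jac[j]
        if site == "H":
            return self.H_jac[j], self.Hdir_jac[j]
        k = ("N", "CA", "C").index(site)
        params = self.sys.params
        xr = params.backbone_bead_refs[k]
        dr = params.backbone_bead_dirs[k]
        dR, dt = self.dR[j], self.dt[j]
        pos_entries, dir_entries = [], []
        for atom in range(3):
            Jp = np.zeros((3, 3))
            Jd = np.zeros((3, 3))
            for a in range(3):
                Jp[:, a] = dR[atom, a] @ xr + dt[atom, a]
                Jd[:, a] = dR[atom, a] @ dr
            pos_entries.append((j, atom, Jp))
            dir_entries.append((j, atom, Jd))
        return pos_entries, dir_entries


def _merge_entries(entries):
    merged: dict[tuple[int, int], np.ndarray] = {}
    for res, atom, J in entries:
        key = (res, atom)
        merged[key] = merged.get(key, 0) + J
    return [(res, atom, J) for (res, atom), J in merged.items()]


def _hbond_site_grad_entries(system: SideChainSystem, pl: _Placements,
                             site: str, j: int):
    """Jacobian entries for the site hydrogen-bond confidence f_site.

    f_site = 1 - prod_p (1 - f_p) over the pairs touching the site; each
    pair's gradient chains through the H/O placements.
    """
    hb = system.hbonds
    chain = system.chain
    pairs = [(d, a, f, g) for (d, a, f, g) in hb.pairs
             if (site == "H" and d == j) or (site == "O" and a == j)]
    if not pairs:
        return []
    entries = []
    for idx, (d, a, f, g) in enumerate(pairs):
        # d f_site / d f_p = prod_{q != p} (1 - f_q); g rows are the
        # derivatives of f_p w.r.t. (H_d, O_a, N_d, C_a)
        w = np.prod([1.0 - fq for q, (_, _, fq, _) in enumerate(pairs)
                     if q != idx])
        # H placement chain
        for res, atom, J in pl.H_jac[d]:
            entries.append((res, atom, w * (J.T @ g[0])))
        # O placement chain
        for res, atom, J in pl.O_jac[a]:
            entries.append((res, atom, w * (J.T @ g[1])))
        # direct N and C dependence
        entries.append((d, 0, w * g[2]))
        entries.append((a, 2, w * g[3]))
    merged: dict[tuple[int, int], np.ndarray] = {}
    for res, atom, v in entries:
        merged[(res, atom)] = merged.get((res, atom), 0) + v
    return [(res, atom, v) for (res, atom), v in merged.items()]


def side_chain_gradient(system: SideChainSystem,
                        marginals: MarginalSet) -> np.ndarray:
    """dG^SC/dX, shape (n_residues, 3 atoms [N, CA, C], 3)."""
    if not marginals.converged:
        warnings.warn("BP marginals not converged; gradient is approximate",
                      RuntimeWarning, stacklevel=2)
    chain = system.chain
    params = system.params
    cfg = params.config
    n = len(chain)
    grad = np.zeros((n, 3, 3))
    pl = _Placements(system)

    def pull_bead(i, weights_y, weights_n):
        # weights_*: (S, 3) gradient w.r.t. bead position/direction of res i
        grad[i] += np.einsum("si,skai->ka", weights_y, pl.bead_dy[i])
        grad[i] += np.einsum("si,skai->ka", weights_n, pl.bead_dn[i])

    # --- side chain - side chain terms ----------------------------------
    for term in system.sc_terms:
        entry = params.pair[term.key]
        i, j = term.i, term.j
        if term.swapped:
            r1, r2 = j, i
        else:
            r1, r2 = i, j
        E, gy1, gn1, gy2, gn2 = _block_energy_grad(
            entry, system.bead_pos[r1], system.bead_dir[r1],
            system.bead_pos[r2], system.bead_dir[r2], 1.0, cfg, True)
        W = marginals.p2[(i, j)]
        if term.swapped:
            W = W.T     # now indexed (states of r1, states of r2)
        pull_bead(r1, np.einsum("ab,abx->ax", W, gy1),
                  np.einsum("ab,abx->ax", W, gn1))
        pull_bead(r2, np.einsum("ab,abx->bx", W, gy2),
                  np.einsum("ab,abx->bx", W, gn2))

    # --- side chain - backbone site terms -------------------------------
    for term in system.site_terms:
        entry = params.pair[term.key]
        i, j, site = term.i, term.j, term.site
        p2pos = system.site_pos[site][j][None, :]
        p2dir = (system.site_dir[site][j][None, :]
                 if term.directional else None)
        E, gy1, gn1, gy2, gn2 = _block_energy_grad(
            entry, system.bead_pos[i], system.bead_dir[i], p2pos, p2dir,
            term.kappa, cfg, term.directional)
        w = marginals.p1[i]
        pull_bead(i, w[:, None] * gy1[:, 0, :], w[:, None] * gn1[:, 0, :])
        pos_entries, dir_entries = pl.site_entries(site, j)
        fpos = np.einsum("s,sx->x", w, gy2[:, 0, :])
        pullback_forces(fpos, pos_entries, grad)
        if term.directional:
            fdir = np.einsum("s,sx->x", w, gn2[:, 0, :])
            pullback_forces(fdir, dir_entries, grad)
        # kappa = 1 - f_site dependence for O/H partners
        if site in ("O", "H"):
            hb_entries = _hbond_site_grad_entries(system, pl, site, j)
            if hb_entries:
                if term.kappa != 0.0:
                    e_raw = E[:, 0] / term.kappa
                else:
                    e_raw = _block_energy_grad(
                        entry, system.bead_pos[i], system.bead_dir[i], p2pos,
                        p2dir, 1.0, cfg, term.directional)[0][:, 0]
                scalar = float(np.dot(w, e_raw))
                for res, atom, v in hb_entries:
                    grad[res, atom] += -scalar * v   # d kappa = -d f_site

    # --- phi/psi dependence of the rotamer prior ------------------------
    for i in range(n):
        phi, psi = system.phi_psi[i]
        table = system.vrot_tables[i]
        _, dphi, dpsi = periodic_bilinear(
            table, phi if phi is not None else 0.0,
            psi if psi is not None else 0.0)
        w = marginals.p1[i]
        if phi is not None:
            gphi = dihedral_gradient(chain.C[i - 1], chain.N[i],
                                     chain.CA[i], chain.C[i])
            coeff = float(np.dot(w, dphi))
            for (res, atom), gv in zip(
                    [(i - 1, 2), (i, 0), (i, 1), (i, 2)], gphi):
                grad[res, atom] += coeff * gv
        if psi is not None:
            gpsi = dihedral_gradient(chain.N[i], chain.CA[i], chain.C[i],
                                     chain.N[i + 1])
            coeff = float(np.dot(w, dpsi))
            for (res, atom), gv in zip(
                    [(i, 0), (i, 1), (i, 2), (i + 1, 0)], gpsi):
                grad[res, atom] += coeff * gv
    return grad


def side_chain_forces(system: SideChainSystem,
                      marginals: MarginalSet) -> np.ndarray:
    """Forces on the backbone atoms, -dG^SC/dX, shape (n, 3, 3), k_BT/A."""
    return -side_chain_gradient(system, marginals)
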