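"""Oriented-bead pair potential, hydrogen-bond coupling, and local energies.

Every interacting pair of beads/sites contributes

    V = kappa * ( V_radial(r12) + ang1(-n1.n12) * ang2(n2.n12) * V_angular(r12) )

with r12 the separation, n12 the displacement unit vector and n1, n2 the
bead directions.  The four curves are clamped cubic splines (radial knots at
0.5 A up to the cutoff, forced to zero at and beyond it; angular knots every
1/6 in cos(theta)).  Side chain-side chain terms use kappa = 1; side chain-
carbonyl-O and side chain-amide-H terms use kappa = 1 - f where f is the
backbone hydrogen-bond confidence of the site, so those directional terms
switch off when the site is already hydrogen bonded; the three N/CA/C
backbone interaction beads use kappa = 1 and, by default, radial terms only.

Energies are in natural units, k_B T = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import splines
from .geometry import (
    BackboneChain, DerivedAtoms, GeometryError, PeptideGeometry,
    RigidFrame, ideal_backbone_triple, place_peptide_atoms, residue_frame,
    unit, unit_jacobian,
)
from .graph import BACKBONE_SITES, SideChainGraph, build_graph
from .rotamer import PhiPsiGrid
from .tables import periodic_bilinear

__all__ = [
    "HBondCriteria", "hbond_confidence", "hbond_site_scores", "HBondNetwork",
    "PotentialConfig", "PairInteraction", "ParameterSet",
    "pair_energy", "SideChainSystem", "build_system", "build_local_energies",
]


# ---------------------------------------------------------------------------
# hydrogen-bond confidence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriteria:
    """Distance/angle criteria for a backbone N-H...O=C hydrogen bond.

    The distance switch turns on over [d_on, d_off] (H-O distance); the two
    angular switches (N-H-O and H-O-C) have their half-height at
    ``half_angle_deg`` off of collinear.  All switches are cubic smoothsteps.
    """

    d_on: float = 1.4
    d_off: float = 2.5
    half_angle_deg: float = 47.0

    @property
    def cos_floor(self) -> float:
        # smoothstep midpoint placed exactly at the half angle
        return 2.0 * np.cos(np.deg2rad(self.half_angle_deg)) - 1.0


def _smoothstep(t: float):
    if t <= 0.0:
        return 0.0, 0.0
    if t >= 1.0:
        return 1.0, 0.0
    return t * t * (3.0 - 2.0 * t), 6.0 * t * (1.0 - t)


def _cos_vertex(A, B, C):
    """cos of the A-B-C angle (vertex B) and its gradients w.r.t. A, B, C."""
    u = A - B
    v = C - B
    uh, vh = unit(u), unit(v)
    c = float(np.dot(uh, vh))
    gA = unit_jacobian(u) @ vh
    gC = unit_jacobian(v) @ uh
    gB = -gA - gC
    return c, gA, gB, gC


def hbond_confidence(H, O, N, C, criteria: HBondCriteria | None = None,
                     with_grad: bool = False):
    """Hydrogen-bond confidence f in [0, 1] for one N-H...O=C geometry.

    ``N`` is the donor nitrogen, ``C`` the acceptor carbonyl carbon.  With
    ``with_grad`` also returns the (4, 3) gradient w.r.t. (H, O, N, C).
    Missing atoms (any None) give f = 0.
    """
    crit = criteria or HBondCriteria()
    if H is None or O is None or N is None or C is None:
        return (0.0, np.zeros((4, 3))) if with_grad else 0.0
    H, O, N, C = (np.asarray(x, dtype=float) for x in (H, O, N, C))
    if not all(np.all(np.isfinite(x)) for x in (H, O, N, C)):
        return (0.0, np.zeros((4, 3))) if with_grad else 0.0

    dv = H - O
    d = float(np.linalg.norm(dv))
    if d < 1e-9:
        raise GeometryError("coincident H and O in hydrogen-bond geometry")
    td = (crit.d_off - d) / (crit.d_off - crit.d_on)
    Sd, dSd = _smoothstep(td)

    c0 = crit.cos_floor
    # N-H-O angle, vertex H; collinear means angle 180 => -cos = 1
    c1, g1N, g1H, g1O = _cos_vertex(N, H, O)
    t1 = (-c1 - c0) / (1.0 - c0)
    S1, dS1 = _smoothstep(t1)
    # H-O-C angle, vertex O
    c2, g2H, g2O, g2C = _cos_vertex(H, O, C)
    t2 = (-c2 - c0) / (1.0 - c0)
    S2, dS2 = _smoothstep(t2)

    f = Sd * S1 * S2
    if not with_grad:
        return f

    g = np.zeros((4, 3))
    # distance factor
    pref_d = dSd * S1 * S2 * (-1.0 / (crit.d_off - crit.d_on))
    g[0] += pref_d * dv / d
    g[1] -= pref_d * dv / d
    # first angle factor (gradient of -c1)
    pref_1 = Sd * dS1 * S2 * (-1.0 / (1.0 - c0))
    g[0] += pref_1 * g1H
    g[1] += pref_1 * g1O
    g[2] += pref_1 * g1N
    # second angle factor
    pref_2 = Sd * S1 * dS2 * (-1.0 / (1.0 - c0))
    g[0] += pref_2 * g2H
    g[1] += pref_2 * g2O
    g[3] += pref_2 * g2C
    return f, g


@dataclass
class HBondNetwork:
    """Per-site hydrogen-bond confidences and the contributing pairs.

    ``pairs`` holds (donor residue, acceptor residue, f, grad) with grad the
    (4, 3) derivative of f w.r.t. (H_don, O_acc, N_don, C_acc).  Site scores
    combine pair confidences as f_site = 1 - prod(1 - f_pair).
    """

    f_H: np.ndarray
    f_O: np.ndarray
    pairs: list[tuple[int, int, float, np.ndarray]]

    def total_confidence(self) -> float:
        return float(sum(p[2] for p in self.pairs))


def hbond_site_scores(chain: BackboneChain, derived: DerivedAtoms,
                      criteria: HBondCriteria | None = None,
                      min_seq_sep: int = 2) -> HBondNetwork:
    """Score every donor H and acceptor O site of the backbone."""
    n = len(chain)
    crit = criteria or HBondCriteria()
    pairs = []
    one_minus_H = np.ones(n)
    one_minus_O = np.ones(n)
    for i in range(n):          # donor
        if not derived.has_H[i]:
            continue
        for j in range(n):      # acceptor
            if not derived.has_O[j] or abs(i - j) < min_seq_sep:
                continue
            if np.linalg.norm(derived.H[i] - derived.O[j]) > crit.d_off + 0.5:
                continue
            f, g = hbond_confidence(derived.H[i], derived.O[j],
                                    chain.N[i], chain.C[j], crit,
                                    with_grad=True)
            if f > 0.0:
                pairs.append((i, j, f, g))
                one_minus_H[i] *= 1.0 - f
                one_minus_O[j] *= 1.0 - f
    return HBondNetwork(f_H=1.0 - one_minus_H, f_O=1.0 - one_minus_O,
                        pairs=pairs)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class PotentialConfig:
    """Switches selecting which interaction classes are active."""

    sc_sc_cutoff: float = 7.0
    sc_bb_cutoff: float = 5.0
    min_seq_sep: int = 1
    include_own_backbone: bool = False
    include_ho: bool = True          # side chain - carbonyl O / amide H terms
    include_ncac: bool = True        # side chain - N/CA/C bead terms
    ncac_directional: bool = False   # N/CA/C beads carry directional terms
    isotropic_only: bool = False     # drop all directional terms
    repulsive_only: bool = False     # keep only the positive isotropic part
    sc_sc_only: bool = False
    sc_bb_only: bool = False
    phi_psi_independent_rot: bool = False


@dataclass
class PairInteraction:
    """Spline coefficients of one ordered interaction-type pair.

    ``c_unif``/``c_dir`` are knot values of V_radial/V_angular on the radial
    grid (the value at the cutoff knot is pinned to zero); ``a1``/``a2`` are
    raw coefficients of the angular factors, positivity-constrained through
    an exponential transform: ang(x) is the clamped spline through exp(a).
    """

    r_cutoff: float
    c_unif: np.ndarray
    c_dir: np.ndarray
    a1: np.ndarray
    a2: np.ndarray

    def __post_init__(self):
        nk = splines.radial_knots(self.r_cutoff).shape[0]
        na = splines.angular_knots().shape[0]
        for name, arr, want in (("c_unif", self.c_unif, nk),
                                ("c_dir", self.c_dir, nk),
                                ("a1", self.a1, na), ("a2", self.a2, na)):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (want,):
                raise ValueError(f"{name}: expected shape ({want},)")
            setattr(self, name, arr)

    def curves(self):
        # treated as immutable after construction; trainers build new instances
        cached = getattr(self, "_curves", None)
        if cached is None:
            rk = splines.radial_knots(self.r_cutoff)
            ak = splines.angular_knots()
            cached = (
                splines.ClampedSpline(rk, self.c_unif, zero_tail=True),
                splines.ClampedSpline(ak, np.exp(self.a1)),
                splines.ClampedSpline(ak, np.exp(self.a2)),
                splines.ClampedSpline(rk, self.c_dir, zero_tail=True),
            )
            object.__setattr__(self, "_curves", cached)
        return cached


def pair_key(t1: str, t2: str) -> tuple[tuple[str, str], bool]:
    """Canonical storage key for an interaction pair and whether the
    supplied order was swapped relative to it.

    Side chain-backbone pairs are keyed (residue_type, site); side chain-
    side chain pairs are keyed in sorted order.
    """
    if t2 in BACKBONE_SITES:
        return (t1, t2), False
    if t1 in BACKBONE_SITES:
        return (t2, t1), True
    if t1 <= t2:
        return (t1, t2), False
    return (t2, t1), True


@dataclass
class ParameterSet:
    """All trainable parameters plus the fixed reference geometry."""

    grid: PhiPsiGrid
    pair: dict[tuple[str, str], PairInteraction]
    bead_positions: dict[str, np.ndarray]     # residue type -> (S, 3)
    bead_directions: dict[str, np.ndarray]    # residue type -> (S, 3)
    rotamer_energy: dict[str, np.ndarray]     # residue type -> (S, G1, G2)
    chi1_of_state: dict[str, np.ndarray]      # residue type -> (S,)
    backbone_bead_refs: np.ndarray = None     # (3, 3) N/CA/C bead positions
    backbone_bead_dirs: np.ndarray = None     # (3, 3)
    geom: PeptideGeometry = field(default_factory=PeptideGeometry)
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    config: PotentialConfig = field(default_factory=PotentialConfig)

    def __post_init__(self):
        if self.backbone_bead_refs is None:
            self.backbone_bead_refs = ideal_backbone_triple(self.geom)
        if self.backbone_bead_dirs is None:
            self.backbone_bead_dirs = np.tile([0.0, 0.0, 1.0], (3, 1))
        self.backbone_bead_refs = np.asarray(self.backbone_bead_refs, float)
        self.backbone_bead_dirs = np.asarray(self.backbone_bead_dirs, float)

    @property
    def reference_triple(self) -> np.ndarray:
        return ideal_backbone_triple(self.geom)

    def n_states(self, residue_type: str) -> int:
        return self.bead_positions[residue_type].shape[0]

    def residue_types(self) -> list[str]:
        return sorted(self.bead_positions)

    def get_pair(self, t1: str, t2: str):
        key, swapped = pair_key(t1, t2)
        try:
            return self.pair[key], swapped
        except KeyError:
            raise KeyError(f"no pair parameters for {key}")

    def bead_refs(self) -> dict[str, dict[str, np.ndarray]]:
        return {rt: {"positions": self.bead_positions[rt],
                     "directions": self.bead_directions[rt]}
                for rt in self.bead_positions}


# ---------------------------------------------------------------------------
# pair-energy evaluation
# ---------------------------------------------------------------------------

def pair_energy(y1, n1, y2, n2, entry: PairInteraction, kappa: float = 1.0,
                directional: bool = True) -> float:
    """Energy of one oriented-bead pair (slot 1 first, per the stored order)."""
    y1, y2 = np.asarray(y1, float), np.asarray(y2, float)
    r = float(np.linalg.norm(y1 - y2))
    if r < 1e-9:
        raise GeometryError("coincident beads in pair energy")
    if kappa == 0.0 or r >= entry.r_cutoff:
        return 0.0
    vr, ang1, ang2, vang = entry.curves()
    e = float(vr(r))
    if directional and n1 is not None and n2 is not None:
        n12 = (y1 - y2) / r
        x1 = -float(np.dot(np.asarray(n1, float), n12))
        x2 = float(np.dot(np.asarray(n2, float), n12))
        e += float(ang1(x1)) * float(ang2(x2)) * float(vang(r))
    return kappa * e


def _block_geometry(y1, n1, y2, n2):
    """Pairwise r, n12, x1, x2 between state arrays (S1, 3) and (S2, 3)."""
    dy = y1[:, None, :] - y2[None, :, :]
    r = np.linalg.norm(dy, axis=-1)
    rsafe = np.where(r < 1e-12, 1.0, r)
    n12 = dy / rsafe[..., None]
    x1 = None if n1 is None else -np.einsum("ik,ijk->ij", n1, n12)
    x2 = None if n2 is None else np.einsum("jk,ijk->ij", n2, n12)
    return r, n12, x1, x2


def _block_energy(entry: PairInteraction, r, x1, x2, kappa,
                  cfg: PotentialConfig, directional: bool):
    vr, ang1, ang2, vang = entry.curves()
    radial = vr(r)
    if cfg.repulsive_only:
        return kappa * np.maximum(radial, 0.0)
    e = radial
    if directional and not cfg.isotropic_only and x1 is not None:
        e = e + ang1(x1) * ang2(x2) * vang(r)
    return kappa * e


# ---------------------------------------------------------------------------
# term records and system assembly
# ---------------------------------------------------------------------------

@dataclass
class SCSCTerm:
    """One side chain-side chain interaction: residue pair (i, j), i < j.

    Geometry arrays are indexed [state_of_slot1, state_of_slot2]; ``swapped``
    records whether slot 1 is residue j (canonical key ordering).
    """

    i: int
    j: int
    key: tuple[str, str]
    swapped: bool
    r: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    directional: bool


@dataclass
class SiteTerm:
    """One side chain-backbone interaction: residue i's bead (slot 1) with
    backbone site ``site`` of residue j (slot 2)."""

    i: int
    j: int
    site: str
    key: tuple[str, str]
    kappa: float
    r: np.ndarray
    x1: np.ndarray | None
    x2: np.ndarray | None
    directional: bool


@dataclass
class SideChainSystem:
    """Everything derived from one backbone configuration.

    Holds placements (frames, beads, derived atoms, backbone sites), the
    interaction graph, the hydrogen-bond network and the assembled discrete
    energies v_i / v_ij that define the side-chain Markov random field.
    """

    chain: BackboneChain
    params: ParameterSet
    derived: DerivedAtoms
    frames: list[RigidFrame]
    bead_pos: list[np.ndarray]
    bead_dir: list[np.ndarray]
    site_pos: dict[str, np.ndarray]
    site_dir: dict[str, np.ndarray]
    hbonds: HBondNetwork
    graph: SideChainGraph
    v1: list[np.ndarray]
    v2: dict[tuple[int, int], np.ndarray]
    sc_terms: list[SCSCTerm]
    site_terms: list[SiteTerm]
    vrot_tables: list[np.ndarray]   # per residue (S, G1, G2) effective table
    phi_psi: list[tuple[float | None, float | None]]

    @property
    def state_counts(self) -> np.ndarray:
        return self.graph.state_counts


def _site_kappa(site: str, j: int, hb: HBondNetwork) -> float:
    if site == "O":
        return 1.0 - float(hb.f_O[j])
    if site == "H":
        return 1.0 - float(hb.f_H[j])
    return 1.0


def build_system(chain: BackboneChain, params: ParameterSet,
                 derived: DerivedAtoms | None = None,
                 graph: SideChainGraph | None = None) -> SideChainSystem:
    """Place all derived geometry and assemble v_i, v_ij (Steps 1-2).

    Raises a KeyError if a residue type lacks bead/partition data.
    """
    cfg = params.config
    n = len(chain)
    for rt in chain.residue_types:
        if rt not in params.bead_positions:
            raise KeyError(f"no coarse-state data for residue type {rt}")
    if derived is None:
        derived = place_peptide_atoms(chain, params.geom)
    ref = params.reference_triple

    frames = [residue_frame(chain.N[i], chain.CA[i], chain.C[i], ref)
              for i in range(n)]
    bead_pos, bead_dir = [], []
    for i, rt in enumerate(chain.residue_types):
        bead_pos.append(frames[i].apply(params.bead_positions[rt]))
        d = frames[i].apply_direction(params.bead_directions[rt])
        bead_dir.append(d / np.linalg.norm(d, axis=-1, keepdims=True))

    # backbone interaction sites
    site_pos: dict[str, np.ndarray] = {}
    site_dir: dict[str, np.ndarray] = {}
    if cfg.include_ho and not cfg.sc_sc_only:
        site_pos["O"] = derived.O
        site_pos["H"] = derived.H
        site_dir["O"] = np.full((n, 3), np.nan)
        site_dir["H"] = np.full((n, 3), np.nan)
        for i in range(n):
            if derived.has_O[i]:
                site_dir["O"][i] = unit(derived.O[i] - chain.C[i])
            if derived.has_H[i]:
                site_dir["H"][i] = unit(derived.H[i] - chain.N[i])
    if cfg.include_ncac and not cfg.sc_sc_only:
        for k, site in enumerate(("N", "CA", "C")):
            site_pos[site] = np.stack([
                f.apply(params.backbone_bead_refs[k]) for f in frames])
            site_dir[site] = np.stack([
                f.apply_direction(params.backbone_bead_dirs[k])
                for f in frames])

    hb = hbond_site_scores(chain, derived, params.hbond)

    if graph is None:
        graph = build_graph(
            bead_pos, site_pos if not cfg.sc_sc_only else None,
            sc_sc_cutoff=cfg.sc_sc_cutoff, sc_bb_cutoff=cfg.sc_bb_cutoff,
            min_seq_sep=cfg.min_seq_sep,
            include_own_backbone=cfg.include_own_backbone)

    # one-body rotamer term
    v1, vrot_tables, phi_psi = [], [], []
    for i, rt in enumerate(chain.residue_types):
        table = params.rotamer_energy[rt]
        if cfg.phi_psi_independent_rot:
            table = table.mean(axis=(1, 2), keepdims=True) * np.ones_like(table)
        phi, psi = chain.phi_psi(i)
        eff = table
        if phi is None:
            eff = eff.mean(axis=1, keepdims=True) * np.ones_like(eff)
        if psi is None:
            eff = eff.mean(axis=2, keepdims=True) * np.ones_like(eff)
        val, _, _ = periodic_bilinear(eff, phi if phi is not None else 0.0,
                                      psi if psi is not None else 0.0)
        v1.append(np.array(val, dtype=float))
        vrot_tables.append(eff)
        phi_psi.append((phi, psi))

    # side chain-backbone terms
    site_terms: list[SiteTerm] = []
    if not cfg.sc_sc_only:
        for (i, j, site) in graph.bb_terms:
            if site in ("O", "H") and not cfg.include_ho:
                continue
            if site in ("N", "CA", "C") and not cfg.include_ncac:
                continue
            rt = chain.residue_types[i]
            key, _ = pair_key(rt, site)
            if key not in params.pair:
                continue
            entry = params.pair[key]
            p2 = site_pos[site][j]
            if not np.all(np.isfinite(p2)):
                continue
            directional = site in ("O", "H") or cfg.ncac_directional
            d2 = site_dir[site][j][None, :] if directional else None
            r, n12, x1, x2 = _block_geometry(
                bead_pos[i], bead_dir[i], p2[None, :], d2)
            kappa = _site_kappa(site, j, hb)
            term = SiteTerm(i=i, j=j, site=site, key=key, kappa=kappa,
                            r=r[:, 0],
                            x1=None if x1 is None else x1[:, 0],
                            x2=None if x2 is None else x2[:, 0],
                            directional=directional)
            site_terms.append(term)
            e = _block_energy(entry, term.r, term.x1, term.x2, kappa, cfg,
                              directional)
            v1[i] = v1[i] + e

    # side chain-side chain terms
    v2: dict[tuple[int, int], np.ndarray] = {}
    sc_terms: list[SCSCTerm] = []
    if not cfg.sc_bb_only:
        for (i, j) in graph.sc_edges:
            ti, tj = chain.residue_types[i], chain.residue_types[j]
            key, swapped = pair_key(ti, tj)
            entry = params.pair[key]
            if swapped:
                r, n12, x1, x2 = _block_geometry(
                    bead_pos[j], bead_dir[j], bead_pos[i], bead_dir[i])
            else:
                r, n12, x1, x2 = _block_geometry(
                    bead_pos[i], bead_dir[i], bead_pos[j], bead_dir[j])
            term = SCSCTerm(i=i, j=j, key=key, swapped=swapped, r=r,
                            x1=x1, x2=x2, directional=True)
            sc_terms.append(term)
            e = _block_energy(entry, r, x1, x2, 1.0, cfg, True)
            v2[(i, j)] = e.T if swapped else e
    elif graph.sc_edges:
        graph = SideChainGraph(n_residues=n, state_counts=graph.state_counts,
                               sc_edges=[], bb_terms=graph.bb_terms)

    return SideChainSystem(
        chain=chain, params=params, derived=derived, frames=frames,
        bead_pos=bead_pos, bead_dir=bead_dir, site_pos=site_pos,
        site_dir=site_dir, hbonds=hb, graph=graph, v1=v1, v2=v2,
        sc_terms=sc_terms, site_terms=site_terms, vrot_tables=vrot_tables,
        phi_psi=phi_psi)


def build_local_energies(chain: BackboneChain, params: ParameterSet,
                         derived: DerivedAtoms | None = None,
                         graph: SideChainGraph | None = None):
    """Assembled 1-residue vectors and 2-residue matrices (and the system)."""
    system = build_system(chain, params, derived=derived, graph=graph)
    return system.v1, system.v2, system
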