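"""Deterministic generators for synthetic libraries, backbones and datasets.

Everything every test or example needs is generated here from a seed: toy
fine rotamer libraries with backbone-dependent state probabilities, smooth
Ramachandran densities, ideal-geometry backbones for standard topologies,
planted spline parameter sets, and training sets whose native coarse states
are drawn *exactly* from the Boltzmann distribution of the planted discrete
potential by complete enumeration (so a failure of parameter recovery
implicates the trainer, never the sampler).

All generators are pure functions of (seed, arguments).
"""

from __future__ import annotations

import numpy as np

from .geometry import BackboneChain, PeptideGeometry, nerf_place
from .potential import (HBondCriteria, PairInteraction, ParameterSet,
                        PotentialConfig, build_system, pair_key)
from .rotamer import (CoarsePartition, FineRotamerLibrary, PhiPsiGrid,
                      RamachandranDensity, ResidueFineStates,
                      optimize_partition)
from . import splines

__all__ = [
    "gen_rotamer_library", "gen_rama_density", "gen_toy_protein",
    "gen_parameter_set", "gen_training_set", "DEFAULT_TYPES",
]

# real residue names so the chi1 exclusion rule is exercised naturally
DEFAULT_TYPES = ["SER", "VAL", "LEU", "ASN", "PHE", "LYS", "THR", "ILE"]


def _factor_states(n: int) -> tuple[int, int]:
    """Split a fine-state count into (n_chi1, n_chi2) bins."""
    if n == 1:
        return 1, 1
    for c1 in (3, 2, 1):
        if n % c1 == 0:
            return c1, n // c1
    return 1, n


def gen_rotamer_library(seed: int, n_residue_types: int = 3,
                        states_per_type: int = 9,
                        grid: PhiPsiGrid | None = None,
                        n_atoms: int = 3,
                        residue_types: list[str] | None = None,
                        ) -> FineRotamerLibrary:
    """Toy fine rotamer library with smooth (phi, psi)-dependent weights.

    Fine-state base weights are Dirichlet draws, modulated smoothly over the
    Ramachandran torus so that probabilities remain normalized at every grid
    point.  Atom positions sit 1.5-4 A from the frame origin, clustered by
    chi1 bin so that coarse-graining by chi1/chi2 is geometrically sensible.
    """
    if not 1 <= states_per_type <= 81:
        raise ValueError("states_per_type must be in [1, 81]")
    rng = np.random.default_rng(seed)
    grid = grid or PhiPsiGrid()
    types = residue_types or DEFAULT_TYPES[:n_residue_types]
    phi, psi = grid.centers()
    PHI, PSI = np.meshgrid(phi, psi, indexing="ij")

    residues = {}
    for rt in types:
        n_chi1, n_chi2 = _factor_states(states_per_type)
        F = states_per_type
        chi1 = np.repeat(np.arange(n_chi1), n_chi2)
        chi2 = np.tile(np.arange(n_chi2), n_chi1)
        base = rng.dirichlet(np.full(F, 2.0))
        amp = rng.uniform(0.3, 1.2, size=F)
        phi0 = rng.uniform(-np.pi, np.pi, size=F)
        psi0 = rng.uniform(-np.pi, np.pi, size=F)
        logits = (np.log(base)[:, None, None]
                  + amp[:, None, None] * np.cos(PHI[None] - phi0[:, None, None])
                  + amp[:, None, None] * np.cos(PSI[None] - psi0[:, None, None]))
        logits -= logits.max(axis=0)
        probs = np.exp(logits)
        probs /= probs.sum(axis=0)

        # chi1 bins at 120-degree spaced base directions; chi2 spreads within
        atoms = np.zeros((F, n_atoms, 3))
        for f in range(F):
            a1 = 2 * np.pi * chi1[f] / max(n_chi1, 1)
            a2 = 0.6 * (chi2[f] - (n_chi2 - 1) / 2) / max(n_chi2, 1)
            direction = np.array([
                np.cos(a1 + a2) * np.cos(0.5),
                np.sin(a1 + a2) * np.cos(0.5),
                np.sin(0.5),
            ])
            radii = np.linspace(1.5, min(4.0, 1.5 + 1.2 * n_atoms), n_atoms)
            jitter = rng.normal(scale=0.15, size=(n_atoms, 3))
            atoms[f] = radii[:, None] * direction[None, :] + jitter
        residues[rt] = ResidueFineStates(
            chi1_bin=chi1, chi2_bin=chi2, higher_bin=np.zeros(F, dtype=int),
            probs=probs, atoms=atoms, n_chi1_bins=n_chi1, n_chi2_bins=n_chi2)
    lib = FineRotamerLibrary(grid=grid, residues=residues)
    lib.validate()
    return lib


def gen_rama_density(seed: int = 0,
                     grid: PhiPsiGrid | None = None) -> RamachandranDensity:
    """Smooth two-basin (helix/sheet) stand-in Ramachandran density."""
    grid = grid or PhiPsiGrid()
    phi, psi = grid.centers()
    PHI, PSI = np.meshgrid(phi, psi, indexing="ij")
    basins = [((-1.05, -0.79), 2.5, 0.55),   # alpha helix
              ((-2.36, 2.36), 1.8, 0.45)]    # beta sheet
    dens = np.zeros(grid.shape)
    for (p0, s0), conc, w in basins:
        dens += w * np.exp(conc * (np.cos(PHI - p0) + np.cos(PSI - s0)))
    dens += 0.02 * dens.mean()
    dens /= dens.sum() * grid.cell_area
    rama = RamachandranDensity(grid=grid, density=dens)
    rama.validate()
    return rama


_TOPOLOGY_ANGLES = {
    "helix": (-57.0, -47.0),
    "extended": (-135.0, 135.0),
}


def gen_toy_protein(seed: int, n_residues: int, topology: str = "helix",
                    residue_types: list[str] | None = None,
                    noise: float = 0.0,
                    geom: PeptideGeometry | None = None) -> BackboneChain:
    """Backbone at ideal bond lengths/angles with topology-set dihedrals.

    ``topology`` is "helix", "extended" or "random" (dihedrals drawn near
    the helix/sheet basins).  ``noise`` adds Gaussian jitter (A) to every
    atom after construction.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    g = geom or PeptideGeometry()
    if residue_types is None:
        residue_types = [DEFAULT_TYPES[rng.integers(len(DEFAULT_TYPES))]
                         for _ in range(n_residues)]
    if topology == "random":
        basins = np.array([[-57.0, -47.0], [-135.0, 135.0]])
        pick = rng.integers(0, 2, size=n_residues)
        phis = basins[pick, 0] + rng.normal(scale=12.0, size=n_residues)
        psis = basins[pick, 1] + rng.normal(scale=12.0, size=n_residues)
    else:
        try:
            phi0, psi0 = _TOPOLOGY_ANGLES[topology]
        except KeyError:
            raise ValueError(f"unknown topology {topology!r}")
        phis = np.full(n_residues, phi0)
        psis = np.full(n_residues, psi0)
    phis, psis = np.deg2rad(phis), np.deg2rad(psis)

    ang_ncac = np.deg2rad(g.n_ca_c_angle_deg)
    ang_cacn = np.deg2rad(g.ca_c_n_angle_deg)
    ang_cnca = np.deg2rad(g.c_n_ca_angle_deg)
    omega = np.pi

    N = np.zeros((n_residues, 3))
    CA = np.zeros((n_residues, 3))
    C = np.zeros((n_residues, 3))
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [g.n_ca_bond, 0.0, 0.0]
    C[0] = CA[0] + g.ca_c_bond * np.array(
        [-np.cos(ang_ncac), np.sin(ang_ncac), 0.0])
    for i in range(1, n_residues):
        N[i] = nerf_place(N[i - 1], CA[i - 1], C[i - 1], g.c_n_bond,
                          ang_cacn, psis[i - 1])
        CA[i] = nerf_place(CA[i - 1], C[i - 1], N[i], g.n_ca_bond,
                           ang_cnca, omega)
        C[i] = nerf_place(C[i - 1], N[i], CA[i], g.ca_c_bond,
                          ang_ncac, phis[i])
    if noise > 0:
        N += rng.normal(scale=noise, size=N.shape)
        CA += rng.normal(scale=noise, size=CA.shape)
        C += rng.normal(scale=noise, size=C.shape)
    return BackboneChain(list(residue_types), N, CA, C)


def _planted_pair(rng, r_cutoff: float, planted: bool) -> PairInteraction:
    rk = splines.radial_knots(r_cutoff)
    nk = rk.shape[0]
    na = splines.angular_knots().shape[0]
    # steric core decaying smoothly; zero tail at the cutoff
    c_unif = 5.0 * np.exp(-rk / 0.8)
    if planted:
        bump = rng.normal(scale=0.6, size=nk) * np.exp(-((rk - 4.0) / 1.6) ** 2)
        c_unif = c_unif + bump
        c_dir = rng.normal(scale=0.8, size=nk) * np.exp(-((rk - 3.5) / 1.5) ** 2)
        a1 = rng.normal(scale=0.4, size=na)
        a2 = rng.normal(scale=0.4, size=na)
    else:
        c_dir = np.zeros(nk)
        a1 = np.zeros(na)
        a2 = np.zeros(na)
    c_unif[-1] = 0.0
    c_dir[-1] = 0.0
    return PairInteraction(r_cutoff=r_cutoff, c_unif=c_unif, c_dir=c_dir,
                           a1=a1, a2=a2)


def gen_parameter_set(library: FineRotamerLibrary,
                      partition: CoarsePartition | None = None,
                      rama: RamachandranDensity | None = None,
                      seed: int | None = 0,
                      config: PotentialConfig | None = None,
                      max_states: int = 6) -> ParameterSet:
    """Parameter set derived from a coarse-grained library.

    Bead positions are the Ramachandran-averaged coarse atom centroids;
    directions point from the first to the last coarse atom.  The one-body
    rotamer energy defaults to -log q^c(phi, psi).  With ``seed`` not None
    the pair splines are planted (random smooth attractive/directional
    structure on top of the steric core); with ``seed=None`` they are purely
    repulsive.
    """
    cfg = config or PotentialConfig()
    rama = rama or gen_rama_density(0, library.grid)
    if partition is None:
        partition = optimize_partition(library, rama, max_states=max_states)
    rng = np.random.default_rng(0 if seed is None else seed)
    planted = seed is not None

    bead_pos, bead_dir, vrot, chi1 = {}, {}, {}, {}
    w = rama.density * library.grid.cell_area
    for rt, part in partition.residues.items():
        S = part.n_coarse
        pos = np.zeros((S, 3))
        dirs = np.zeros((S, 3))
        for c in range(S):
            # ramachandran-averaged atom positions of the coarse state
            yc = np.einsum("gh,ghak->ak", w, part.y[c])
            pos[c] = yc.mean(axis=0)
            d = yc[-1] - yc[0] if yc.shape[0] > 1 else pos[c]
            nd = np.linalg.norm(d)
            dirs[c] = d / nd if nd > 1e-9 else np.array([0.0, 0.0, 1.0])
        bead_pos[rt] = pos
        bead_dir[rt] = dirs
        vrot[rt] = -np.log(np.clip(part.q, 1e-6, None))
        chi1[rt] = part.chi1_of_state.copy()

    types = sorted(partition.residues)
    pair = {}
    for i, t1 in enumerate(types):
        for t2 in types[i:]:
            key, _ = pair_key(t1, t2)
            pair[key] = _planted_pair(rng, cfg.sc_sc_cutoff, planted)
        for site in ("O", "H", "N", "CA", "C"):
            key, _ = pair_key(t1, site)
            pair[key] = _planted_pair(rng, cfg.sc_bb_cutoff, planted)

    return ParameterSet(grid=library.grid, pair=pair, bead_positions=bead_pos,
                        bead_directions=bead_dir, rotamer_energy=vrot,
                        chi1_of_state=chi1, config=cfg,
                        hbond=HBondCriteria())


def gen_training_set(planted_params: ParameterSet,
                     chains: list[BackboneChain], seed: int,
                     max_joint_states: int = 10_000_000):
    """Training examples with natives sampled exactly from the planted model.

    For each chain the discrete side-chain Boltzmann distribution of the
    planted potential is enumerated completely and one joint state is drawn
    from it.  Chains whose joint state space exceeds ``max_joint_states``
    are refused.
    """
    from .training import TrainingExample   # local import avoids a cycle

    rng = np.random.default_rng(seed)
    out = []
    for chain in chains:
        system = build_system(chain, planted_params)
        counts = [len(v) for v in system.v1]
        total = int(np.prod(counts))
        if total > max_joint_states:
            raise ValueError(
                "joint state space too large for exact sampling; "
                "use smaller chains")
        # enumerate the joint distribution for exact sampling
        n = len(counts)
        logw = np.zeros(counts)
        for i, v in enumerate(system.v1):
            shape = [1] * n
            shape[i] = counts[i]
            logw = logw - v.reshape(shape)
        for (i, j), vij in system.v2.items():
            shape = [1] * n
            shape[i], shape[j] = counts[i], counts[j]
            logw = logw - vij.reshape(shape)
        flat = np.exp(logw - logw.max()).ravel()
        flat /= flat.sum()
        draw = rng.choice(flat.size, p=flat)
        native = np.array(np.unravel_index(draw, counts))
        out.append(TrainingExample(chain=chain, native_states=native))
    return out
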