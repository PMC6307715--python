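"""Langevin dynamics of the backbone trace on the side-chain free energy.

The six-step inner loop: (1) place O/H, (2) place the state beads and build
the interaction graph, (3) solve BP for the side-chain marginals, (4) take
the envelope-identity forces, (5) pull derived-site forces back onto
N/CA/C, (6) advance the backbone by a BAOAB Langevin-Verlet step.  The
side-chain free energy enters the integrator simply as a smooth many-body
potential added to the backbone terms (springs, angle restraints, soft
sterics, a Ramachandran statistical energy and a backbone hydrogen-bond
term).

Friction is 1/thermalization-timescale; with friction off the splitting
reduces to plain velocity Verlet and conserves energy.  Replica exchange
swaps adjacent temperatures by the Metropolis rule on alternating
even/odd pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forces import derived_atom_jacobians, side_chain_gradient
from .free_energy import solve_marginals
from .geometry import (BackboneChain, PeptideGeometry, bond_angle,
                       bond_angle_gradient, dihedral_gradient,
                       place_peptide_atoms)
from .potential import ParameterSet, build_system, hbond_site_scores
from .rotamer import RamachandranDensity
from .tables import periodic_bilinear

__all__ = [
    "REPLICA_LADDER", "SimulationConfig", "Trajectory", "BackboneParams",
    "backbone_energy", "langevin_step", "Replica", "replica_exchange_step",
    "run_simulation",
]

#: replica-exchange temperature ladder (natural units)
REPLICA_LADDER = (0.500, 0.532, 0.566, 0.600, 0.636, 0.672, 0.709,
                  0.748, 0.787, 0.828, 0.869, 0.912, 0.955, 1.000)


@dataclass
class BackboneParams:
    """Force constants of the backbone potential terms.

    Equilibrium bond lengths/angles are the ideal peptide values carried in
    PeptideGeometry; the soft-sphere repulsion acts below ``steric_radius``.
    The spring constants are model choices (k_B T / A^2 and k_B T / rad^2).
    """

    k_bond: float = 100.0
    k_angle: float = 20.0
    k_steric: float = 4.0
    steric_radius: float = 3.0
    min_steric_sep: int = 3       # in backbone-atom bonds along the chain


@dataclass
class SimulationConfig:
    dt: float = 0.009
    thermalization_time: float = 0.135
    temperature: float = 1.0
    temperatures: tuple = REPLICA_LADDER
    hbond_energy: float = -1.8
    seed: int = 0
    n_steps: int = 0
    save_interval: int = 10
    exchange_interval: int = 100
    mass: float = 1.0
    use_side_chain: bool = True
    use_rama: bool = True
    bp_tol: float = 1e-3
    bp_max_iter: int = 200
    bp_warm_start: bool = True
    backbone: BackboneParams = field(default_factory=BackboneParams)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        temps = tuple(self.temperatures)
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing")

    @property
    def gamma(self) -> float:
        return 1.0 / self.thermalization_time


@dataclass
class Trajectory:
    residue_types: list[str]
    frames: list[np.ndarray]
    energies: list[dict]
    temperature: float

    def __len__(self):
        return len(self.frames)


# ---------------------------------------------------------------------------
# backbone potential
# ---------------------------------------------------------------------------

def backbone_energy(chain: BackboneChain, derived=None,
                    rama: RamachandranDensity | None = None,
                    bb: BackboneParams | None = None,
                    geom: PeptideGeometry | None = None,
                    hbond_energy: float = 0.0,
                    hbond_criteria=None,
                    use_rama: bool = True):
    """Backbone springs, angle restraints, sterics, Ramachandran and H-bond
    energy, with analytic forces.

    Returns (energy, grad) with grad = dE/dX of shape (n, 3, 3); forces are
    the negative.  ``use_rama`` requires a Ramachandran density; omitting it
    while requested is a configuration error.
    """
    bb = bb or BackboneParams()
    g = geom or PeptideGeometry()
    if derived is None:
        derived = place_peptide_atoms(chain, g)
    n = len(chain)
    X = chain.coords
    E = 0.0
    grad = np.zeros((n, 3, 3))

    # --- bond springs ----------------------------------------------------
    bonds = []
    for i in range(n):
        bonds.append(((i, 0), (i, 1), g.n_ca_bond))
        bonds.append(((i, 1), (i, 2), g.ca_c_bond))
        if i + 1 < n:
            bonds.append(((i, 2), (i + 1, 0), g.c_n_bond))
    for (ra, aa), (rb, ab), d0 in bonds:
        dv = X[ra, aa] - X[rb, ab]
        d = np.linalg.norm(dv)
        E += 0.5 * bb.k_bond * (d - d0) ** 2
        f = bb.k_bond * (d - d0) * dv / d
        grad[ra, aa] += f
        grad[rb, ab] -= f

    # --- angle restraints ------------------------------------------------
    angles = []
    for i in range(n):
        angles.append(((i, 0), (i, 1), (i, 2),
                       np.deg2rad(g.n_ca_c_angle_deg)))
        if i + 1 < n:
            angles.append(((i, 1), (i, 2), (i + 1, 0),
                           np.deg2rad(g.ca_c_n_angle_deg)))
            angles.append(((i, 2), (i + 1, 0), (i + 1, 1),
                           np.deg2rad(g.c_n_ca_angle_deg)))
    for a, b, c, th0 in angles:
        th = bond_angle(X[a], X[b], X[c])
        gth = bond_angle_gradient(X[a], X[b], X[c])
        E += 0.5 * bb.k_angle * (th - th0) ** 2
        coeff = bb.k_angle * (th - th0)
        for (r, at), gv in zip((a, b, c), gth):
            grad[r, at] += coeff * gv

    # --- soft-sphere sterics --------------------------------------------
    flat = X.reshape(-1, 3)
    nat = flat.shape[0]
    for p in range(nat):
        for q in range(p + bb.min_steric_sep + 1, nat):
            dv = flat[p] - flat[q]
            d = np.linalg.norm(dv)
            if d < bb.steric_radius:
                E += 0.5 * bb.k_steric * (d - bb.steric_radius) ** 2
                f = bb.k_steric * (d - bb.steric_radius) * dv / d
                grad[p // 3, p % 3] += f
                grad[q // 3, q % 3] -= f

    # --- Ramachandran statistical energy --------------------------------
    if use_rama:
        if rama is None:
            raise ValueError("Ramachandran table required (use_rama=True)")
        table = -np.log(np.clip(rama.density, 1e-12, None))
        for i in range(1, n - 1):
            phi, psi = chain.phi_psi(i)
            val, dphi, dpsi = periodic_bilinear(table, phi, psi)
            E += float(val)
            gphi = dihedral_gradient(chain.C[i - 1], chain.N[i],
                                     chain.CA[i], chain.C[i])
            for (r, at), gv in zip([(i - 1, 2), (i, 0), (i, 1), (i, 2)], gphi):
                grad[r, at] += float(dphi) * gv
            gpsi = dihedral_gradient(chain.N[i], chain.CA[i], chain.C[i],
                                     chain.N[i + 1])
            for (r, at), gv in zip([(i, 0), (i, 1), (i, 2), (i + 1, 0)], gpsi):
                grad[r, at] += float(dpsi) * gv

    # --- backbone hydrogen bonds ----------------------------------------
    if hbond_energy != 0.0:
        net = hbond_site_scores(chain, derived, hbond_criteria)
        O_jac, H_jac, _, _ = derived_atom_jacobians(chain, derived, g)
        for (don, acc, f, gf) in net.pairs:
            E += hbond_energy * f
            for res, atom, J in H_jac[don]:
                grad[res, atom] += hbond_energy * (J.T @ gf[0])
            for res, atom, J in O_jac[acc]:
                grad[res, atom] += hbond_energy * (J.T @ gf[1])
            grad[don, 0] += hbond_energy * gf[2]
            grad[acc, 2] += hbond_energy * gf[3]

    return E, grad


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def langevin_step(x: np.ndarray, v: np.ndarray, force: np.ndarray,
                  force_fn, dt: float, gamma: float, temperature: float,
                  rng: np.random.Generator, mass: float = 1.0):
    """One BAOAB Langevin-Verlet step.

    ``force`` is the force at ``x``; ``force_fn`` evaluates the force at
    the new position.  With gamma = 0 the step is plain velocity Verlet.
    Returns (x_new, v_new, force_new).  Aborts on non-finite forces.
    """
    if not np.all(np.isfinite(force)):
        raise FloatingPointError("non-finite forces entering Langevin step")
    v = v + 0.5 * dt * force / mass
    x = x + 0.5 * dt * v
    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(temperature * (1.0 - c1 * c1) / mass)
        v = c1 * v + c2 * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    fnew = force_fn(x)
    if not np.all(np.isfinite(fnew)):
        raise FloatingPointError("non-finite forces after Langevin step")
    v = v + 0.5 * dt * fnew / mass
    return x, v, fnew


@dataclass
class Replica:
    temperature: float
    x: np.ndarray
    v: np.ndarray
    potential_energy: float


def replica_exchange_step(replicas: list[Replica], rng: np.random.Generator,
                          parity: int = 0) -> int:
    """Metropolis temperature swaps between adjacent replicas.

    Pairs (k, k+1) with k of the given parity attempt a swap with
    acceptance min(1, exp((beta_k - beta_{k+1}) (E_k - E_{k+1}))); accepted
    swaps exchange configurations (and rescale velocities to the new
    temperature).  Returns the number of accepted swaps.
    """
    if len(replicas) < 2:
        raise ValueError("need at least two replicas")
    accepted = 0
    for k in range(parity % 2, len(replicas) - 1, 2):
        a, b = replicas[k], replicas[k + 1]
        delta = (1.0 / a.temperature - 1.0 / b.temperature) * (
            a.potential_energy - b.potential_energy)
        if delta >= 0 or rng.random() < np.exp(delta):
            scale_up = np.sqrt(a.temperature / b.temperature)
            a.x, b.x = b.x, a.x
            a.v, b.v = b.v * (1.0 / scale_up), a.v * scale_up
            a.potential_energy, b.potential_energy = (
                b.potential_energy, a.potential_energy)
            accepted += 1
    return accepted


# ---------------------------------------------------------------------------
# full simulation loop
# ---------------------------------------------------------------------------

def _total_energy_forces(coords, residue_types, params, rama, cfg,
                         warm_state):
    chain = BackboneChain.from_coords(residue_types, coords)
    geom = params.geom if params is not None else PeptideGeometry()
    derived = place_peptide_atoms(chain, geom)
    e_bb, g_bb = backbone_energy(
        chain, derived=derived, rama=rama, bb=cfg.backbone, geom=geom,
        hbond_energy=cfg.hbond_energy,
        hbond_criteria=params.hbond if params is not None else None,
        use_rama=cfg.use_rama)
    e_sc = 0.0
    g_sc = np.zeros_like(g_bb)
    new_state = None
    if cfg.use_side_chain:
        system = build_system(chain, params, derived=derived)
        ms = solve_marginals(system.v1, system.v2, tol=cfg.bp_tol,
                             max_iter=cfg.bp_max_iter,
                             warm_start=warm_state if cfg.bp_warm_start
                             else None)
        e_sc = ms.free_energy
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            g_sc = side_chain_gradient(system, ms)
        new_state = ms.belief_state
    return e_bb, e_sc, -(g_bb + g_sc), new_state


def run_simulation(chain: BackboneChain, params: ParameterSet,
                   config: SimulationConfig,
                   rama: RamachandranDensity | None = None) -> Trajectory:
    """Single-replica Langevin run of the six-step loop.

    Energies (backbone, side-chain free energy, kinetic, total) are logged
    every ``save_interval`` steps; the trajectory holds
    n_steps // save_interval + 1 frames.  Deterministic given the seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    x = chain.coords.copy()
    v = np.zeros_like(x)
    rtypes = list(chain.residue_types)
    warm = None

    e_bb, e_sc, f, warm = _total_energy_forces(x, rtypes, params, rama,
                                               cfg, warm)
    traj = Trajectory(residue_types=rtypes, frames=[x.copy()],
                      energies=[{"backbone": e_bb, "side_chain": e_sc,
                                 "kinetic": 0.0,
                                 "total": e_bb + e_sc}],
                      temperature=cfg.temperature)
    for step in range(cfg.n_steps):
        def force_fn(xx):
            nonlocal e_bb, e_sc, warm
            e_bb, e_sc, ff, warm = _total_energy_forces(
                xx, rtypes, params, rama, cfg, warm)
            return ff
        x, v, f = langevin_step(x, v, f, force_fn, cfg.dt, cfg.gamma,
                                cfg.temperature, rng, cfg.mass)
        if (step + 1) % cfg.save_interval == 0:
            ke = 0.5 * cfg.mass * float(np.sum(v * v))
            traj.frames.append(x.copy())
            traj.energies.append({"backbone": e_bb, "side_chain": e_sc,
                                  "kinetic": ke,
                                  "total": e_bb + e_sc + ke})
    return traj
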