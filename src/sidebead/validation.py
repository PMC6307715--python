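"""Validation experiments: self-contained benchmarks of every component.

Each function runs one study — BP exactness on trees, finite-difference
force checks, planted-parameter recovery, integrator diagnostics — from
scratch, generating its own synthetic inputs from a seed, and returns the
measured quantities.  The acceptance script and the acceptance tests both
drive these experiments; nothing here reads external data.

Problem sizes are chosen to finish on a single CPU in minutes: 18 x 18
(phi, psi) grids, chains of 5-50 residues, 500 + 100 chains for the
recovery study.  docs/methods.md discusses what these scales do and do not
establish.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import dynamics as dyn
from . import synthetic as syn
from . import training as tr
from .free_energy import brute_force_reference, check_consistency, \
    solve_marginals
from .forces import side_chain_gradient
from .geometry import BackboneChain
from .potential import build_system
from .rotamer import PhiPsiGrid, optimize_partition, partition_error

GRID = PhiPsiGrid(18, 18)


def _sub(seed: int, k: int) -> int:
    return (seed * 1000 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# belief propagation vs exact enumeration
# ---------------------------------------------------------------------------

def bp_tree_benchmark(seed: int, n_instances: int = 100) -> dict:
    """BP marginals/pair marginals/free energy vs brute force on random
    tree-structured graphs (up to 12 residues, up to 6 states)."""
    rng = np.random.default_rng(_sub(seed, 1))
    worst = {"p1": 0.0, "p2": 0.0, "free_energy": 0.0}
    for _ in range(n_instances):
        n = int(rng.integers(2, 13))
        cap = int(10_000_000 ** (1.0 / n))
        states = rng.integers(2, min(6, max(2, cap)) + 1, size=n)
        v1 = [rng.normal(scale=1.5, size=s) for s in states]
        v2 = {}
        for j in range(1, n):
            i = int(rng.integers(0, j))
            a, b = min(i, j), max(i, j)
            v2[(a, b)] = rng.normal(size=(states[a], states[b]))
        ms = solve_marginals(v1, v2, tol=1e-11, max_iter=5000)
        ex = brute_force_reference(v1, v2)
        worst["p1"] = max(worst["p1"],
                          max(np.abs(p - q).max()
                              for p, q in zip(ms.p1, ex.p1)))
        worst["p2"] = max(worst["p2"],
                          max(np.abs(ms.p2[e] - ex.p2[e]).max()
                              for e in v2))
        worst["free_energy"] = max(worst["free_energy"],
                                   abs(ms.free_energy - ex.free_energy))
    worst["n"] = n_instances
    return worst


def counterexample_violation() -> float:
    """Max pairwise-consistency violation of the perfectly-correlated /
    independent three-variable marginals that admit no joint law."""
    third = np.diag([1 / 3] * 3)
    ninth = np.full((3, 3), 1 / 9)
    p1 = [np.full(3, 1 / 3)] * 3
    rep = check_consistency(p1, {(0, 1): third, (1, 2): third,
                                 (0, 2): ninth})
    return max(rep.values())


# ---------------------------------------------------------------------------
# finite-difference force and gradient checks
# ---------------------------------------------------------------------------

def _fixture(seed: int, n_res: int, n_types: int = 3, states: int = 6):
    lib = syn.gen_rotamer_library(1, n_residue_types=n_types,
                                  states_per_type=states, grid=GRID)
    rama = syn.gen_rama_density(0, GRID)
    params = syn.gen_parameter_set(lib, rama=rama, seed=2)
    types = sorted(lib.residues)
    chain = syn.gen_toy_protein(
        _sub(seed, 2), n_res, "helix",
        residue_types=[types[i % n_types] for i in range(n_res)], noise=0.3)
    return params, rama, chain


def force_fd_benchmark(seed: int, n_res: int = 10) -> dict:
    """Analytic dG^SC/db and backbone-term forces vs central differences."""
    params, rama, chain = _fixture(seed, n_res)

    def G_of(X):
        ch = BackboneChain.from_coords(chain.residue_types, X)
        s = build_system(ch, params)
        return solve_marginals(s.v1, s.v2, tol=1e-11,
                               max_iter=3000).free_energy

    system = build_system(chain, params)
    ms = solve_marginals(system.v1, system.v2, tol=1e-11, max_iter=3000)
    grad = side_chain_gradient(system, ms)
    X0 = chain.coords
    h = 1e-4
    fd = np.zeros_like(grad)
    for i in range(n_res):
        for k in range(3):
            for a in range(3):
                Xp, Xm = X0.copy(), X0.copy()
                Xp[i, k, a] += h
                Xm[i, k, a] -= h
                fd[i, k, a] = (G_of(Xp) - G_of(Xm)) / (2 * h)
    sc_rel = float(np.abs(fd - grad).max() / np.abs(fd).max())

    def bb_of(X):
        ch = BackboneChain.from_coords(chain.residue_types, X)
        return dyn.backbone_energy(ch, rama=rama, hbond_energy=-1.8)[0]

    _, gbb = dyn.backbone_energy(chain, rama=rama, hbond_energy=-1.8)
    fdb = np.zeros_like(gbb)
    hb = 1e-6
    for i in range(n_res):
        for k in range(3):
            for a in range(3):
                Xp, Xm = X0.copy(), X0.copy()
                Xp[i, k, a] += hb
                Xm[i, k, a] -= hb
                fdb[i, k, a] = (bb_of(Xp) - bb_of(Xm)) / (2 * hb)
    bb_rel = float(np.abs(fdb - gbb).max() / np.abs(fdb).max())
    return {"side_chain_rel": sc_rel, "backbone_rel": bb_rel, "n": n_res}


def parameter_gradient_benchmark(seed: int, n_res: int = 5) -> dict:
    """dE_gap/dtheta vs central differences over every trainable
    coefficient on a small fixture."""
    params, _, chain = _fixture(seed, n_res)
    ex = syn.gen_training_set(params, [chain], seed=_sub(seed, 3))[0]
    egap, grad, packer = tr.parameter_gradient(ex, params, bp_tol=1e-11)
    comp = tr.compile_example(ex, params)
    cfg = tr.OptimizerConfig(bp_tol=1e-11, bp_max_iter=3000)
    vec0 = packer.pack(params)

    def f(v):
        th = tr._theta_struct(packer, v)
        return tr._compiled_egap_grad(comp, th, packer, cfg,
                                      want_grad=False)[0]

    h = 1e-5
    scale = max(np.abs(grad).max(), 1e-8)
    worst = 0.0
    for k in range(vec0.size):
        vp, vm = vec0.copy(), vec0.copy()
        vp[k] += h
        vm[k] -= h
        worst = max(worst, abs((f(vp) - f(vm)) / (2 * h) - grad[k]) / scale)
    return {"max_rel": float(worst), "n": int(vec0.size)}


# ---------------------------------------------------------------------------
# planted-parameter recovery
# ---------------------------------------------------------------------------

def planted_recovery_benchmark(seed: int, n_train: int = 500,
                               n_test: int = 100, n_res: int = 8,
                               n_epochs: int = 35) -> dict:
    """Train from a perturbed start on exactly Boltzmann-sampled data and
    compare held-out mean E_gap (per residue) with the planted model.

    Study conditions: two residue types, three coarse states each,
    8-residue random-topology chains, Adam at its default settings,
    perturbation sigma = 0.5.
    """
    lib = syn.gen_rotamer_library(1, n_residue_types=2, states_per_type=3,
                                  grid=GRID)
    rama = syn.gen_rama_density(0, GRID)
    planted = syn.gen_parameter_set(lib, rama=rama, seed=2)
    types = sorted(lib.residues)
    rng = np.random.default_rng(_sub(seed, 4))

    def chains(n):
        return [syn.gen_toy_protein(
            int(rng.integers(2**31)), n_res, "random",
            residue_types=[types[rng.integers(len(types))]
                           for _ in range(n_res)]) for _ in range(n)]

    train_set = syn.gen_training_set(planted, chains(n_train),
                                     seed=_sub(seed, 5))
    test_set = syn.gen_training_set(planted, chains(n_test),
                                    seed=_sub(seed, 6))

    packer = tr.ParameterPacker(planted)
    v0 = packer.pack(planted)
    start = packer.unpack(
        v0 + np.random.default_rng(_sub(seed, 7)).normal(scale=0.5,
                                                         size=v0.size),
        planted)
    cfg = tr.OptimizerConfig(n_epochs=n_epochs, seed=_sub(seed, 8))
    result = tr.train(train_set, start, cfg)

    def heldout(params):
        return float(np.mean([tr.energy_gap(ex, params, per_residue=True)
                              for ex in test_set]))

    e_planted = heldout(planted)
    e_trained = heldout(result.params)
    acc, n_scored = tr.chi1_accuracy(test_set, result.params)
    acc_prior, _ = tr.chi1_accuracy(test_set, result.params, prior_only=True)
    return {
        "heldout_egap_planted": e_planted,
        "heldout_egap_trained": e_trained,
        "excess": e_trained - e_planted,
        "chi1_accuracy": acc,
        "chi1_accuracy_prior": acc_prior,
        "n_train": n_train,
        "n_scored": n_scored,
    }


# ---------------------------------------------------------------------------
# partition optimizer vs unconstrained-enumeration oracle
# ---------------------------------------------------------------------------

def _set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] + [first]] + part[k + 1:]
        yield part + [[first]]


def _admissible(blocks, per_chi1):
    for block in blocks:
        chi1s = {c1 for c1, _ in block}
        if len(chi1s) != 1:
            return False
        c1 = chi1s.pop()
        present = per_chi1[c1]
        idx = sorted(present.index(c2) for _, c2 in block)
        m, mm = len(idx), len(present)
        if not any(sorted((s + k) % mm for k in range(m)) == idx
                   for s in range(mm)):
            return False
    return True


def partition_oracle_benchmark(seed: int) -> dict:
    """Compare optimize_partition with an exhaustive search over *all* set
    partitions filtered by admissibility (a second, independent code
    path), and check sigma^2 monotonicity in max_states."""
    grid = PhiPsiGrid(6, 6)
    lib = syn.gen_rotamer_library(_sub(seed, 9), 1, 9, grid=grid)
    rama = syn.gen_rama_density(0, grid)
    rt = next(iter(lib.residues))
    entry = lib.residues[rt]
    cells = sorted(set(zip(entry.chi1_bin.tolist(),
                           entry.chi2_bin.tolist())))
    per_chi1 = {}
    for c1, c2 in cells:
        per_chi1.setdefault(c1, []).append(c2)
    for c1 in per_chi1:
        per_chi1[c1] = sorted(per_chi1[c1])

    gaps = []
    errs = []
    for max_states in (3, 4, 5, 6):
        part = optimize_partition(lib, rama, max_states=max_states)
        got = partition_error(lib, {rt: part.residues[rt].mapping},
                              rama)[rt]
        best = np.inf
        for blocks in _set_partitions(cells):
            if len(blocks) > max_states or not _admissible(blocks, per_chi1):
                continue
            cmap = {cell: ci for ci, blk in enumerate(blocks)
                    for cell in blk}
            mapping = np.array([cmap[(a, b)] for a, b in
                                zip(entry.chi1_bin, entry.chi2_bin)])
            best = min(best, partition_error(lib, {rt: mapping}, rama)[rt])
        gaps.append(abs(got - best))
        errs.append(got)
    monotone = all(b <= a + 1e-15 for a, b in zip(errs, errs[1:]))
    return {"max_gap": float(max(gaps)), "monotone": monotone,
            "sigma2_at_6": float(errs[-1])}


# ---------------------------------------------------------------------------
# BP convergence speed
# ---------------------------------------------------------------------------

def bp_convergence_benchmark(seed: int, n_instances: int = 30,
                             n_res: int = 50) -> dict:
    """Median iterations to the 0.001 belief tolerance at damping 0.4 on
    random 50-residue loopy systems."""
    lib = syn.gen_rotamer_library(1, n_residue_types=3, states_per_type=6,
                                  grid=GRID)
    rama = syn.gen_rama_density(0, GRID)
    params = syn.gen_parameter_set(lib, rama=rama, seed=2)
    types = sorted(lib.residues)
    rng = np.random.default_rng(_sub(seed, 10))
    iters = []
    for _ in range(n_instances):
        chain = syn.gen_toy_protein(
            int(rng.integers(2**31)), n_res, "random",
            residue_types=[types[rng.integers(3)] for _ in range(n_res)])
        s = build_system(chain, params)
        ms = solve_marginals(s.v1, s.v2, damping=0.4, tol=1e-3,
                             max_iter=1000)
        iters.append(ms.iterations)
    return {"median_iterations": float(np.median(iters)),
            "max_iterations": int(max(iters)), "n": n_instances}


# ---------------------------------------------------------------------------
# integrator diagnostics
# ---------------------------------------------------------------------------

def nve_drift_benchmark(seed: int, n_steps: int = 10_000) -> dict:
    """Secular total-energy drift with friction off (velocity Verlet).

    The test potential is the smooth spring/angle system: truncated or
    switched terms are only C^1 and would turn the bounded symplectic
    energy oscillation into a slow random walk, which is a property of the
    potential, not of the integrator."""
    chain = syn.gen_toy_protein(_sub(seed, 11), 6, "helix", noise=0.12)
    rng = np.random.default_rng(_sub(seed, 12))
    x = chain.coords.copy()
    v = rng.normal(scale=np.sqrt(0.5), size=x.shape)
    last = {}
    bb = dyn.BackboneParams(k_steric=0.0)

    def force(xx):
        ch = BackboneChain.from_coords(chain.residue_types, xx)
        E, G = dyn.backbone_energy(ch, bb=bb, use_rama=False,
                                   hbond_energy=0.0)
        last["E"] = E
        return -G

    f = force(x)
    energies = []
    for _ in range(n_steps):
        x, v, f = dyn.langevin_step(x, v, f, force, 0.009, 0.0, 0.5, rng)
        energies.append(last["E"] + 0.5 * np.sum(v * v))
    e = np.array(energies)
    window = n_steps // 10
    drift = abs(e[-window:].mean() - e[:window].mean()) / abs(
        e[:window].mean())
    return {"relative_drift": float(drift), "n": n_steps}


def equipartition_benchmark(seed: int) -> dict:
    """BAOAB on independent harmonic oscillators: position variance vs the
    Boltzmann value T/k, reported in standard errors."""
    k, T = 1.0, 0.7
    rng = np.random.default_rng(_sub(seed, 13))
    x = np.zeros(256)
    v = rng.normal(scale=np.sqrt(T), size=256)
    force = lambda xx: -k * xx
    f = force(x)
    samples = []
    for step in range(6000):
        x, v, f = dyn.langevin_step(x, v, f, force, 0.05, 1.0 / 0.135, T,
                                    rng)
        if step > 500 and step % 50 == 0:
            samples.append(x.copy())
    s = np.concatenate(samples)
    var = s.var()
    se = (T / k) * np.sqrt(2.0 / s.size)
    return {"variance": float(var), "target": T / k,
            "z": float(abs(var - T / k) / se), "n": int(s.size)}


def replica_exchange_benchmark(seed: int) -> dict:
    """Two-temperature harmonic replica exchange vs single-temperature
    references: minimum KS p-value over the two temperatures.

    The system is small (8 oscillators) and the temperatures close enough
    (0.7 vs 1.0) that swaps are frequent — otherwise the preservation
    check would be vacuous."""
    k = 1.0
    temps = (0.7, 1.0)
    nosc = 8
    dt, gamma = 0.05, 2.0
    rng = np.random.default_rng(_sub(seed, 14))

    def single(T, rngx):
        x = np.zeros(nosc)
        v = rngx.normal(scale=np.sqrt(T), size=nosc)
        f = -k * x
        out = []
        for s in range(4000):
            x, v, f = dyn.langevin_step(x, v, f, lambda xx: -k * xx, dt,
                                        gamma, T, rngx)
            if s > 300 and s % 25 == 0:
                out.append(0.5 * k * x**2)
        return np.concatenate(out).ravel()

    reps = [dyn.Replica(t, np.zeros(nosc),
                        rng.normal(scale=np.sqrt(t), size=nosc), 0.0)
            for t in temps]
    forces = [-k * r.x for r in reps]
    samples = {t: [] for t in temps}
    swaps = 0
    for s in range(4000):
        for idx, r in enumerate(reps):
            r.x, r.v, forces[idx] = dyn.langevin_step(
                r.x, r.v, forces[idx], lambda xx: -k * xx, dt, gamma,
                r.temperature, rng)
            r.potential_energy = float(np.sum(0.5 * k * r.x**2))
        if s % 40 == 0:
            swaps += dyn.replica_exchange_step(reps, rng, parity=0)
            forces = [-k * r.x for r in reps]
        if s > 300 and s % 25 == 0:
            for r in reps:
                samples[r.temperature].append(0.5 * k * r.x**2)
    pmin = 1.0
    for t in temps:
        ref = single(t, np.random.default_rng(_sub(seed, 15)))
        got = np.concatenate(samples[t]).ravel()
        pmin = min(pmin, stats.ks_2samp(got[::17], ref[::17]).pvalue)
    return {"min_ks_pvalue": float(pmin), "n_swaps_accepted": swaps}
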