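"""Maximum-likelihood training of the pair potential.

The loss per example is the energy gap

    E_gap = V(native coarse states) - G^SC = -log p(native states),

the negative log probability of the crystallographic (here: planted) side
chain states under the Boltzmann ensemble of the discrete potential, with
G^SC evaluated by the same BP/Bethe approximation used at inference time.
Because the BP marginals are stationary points of the Bethe free energy,
the parametric gradient reduces to

    dE_gap/dtheta = dV(native)/dtheta - sum_i <dv_i/dtheta>_p
                                      - sum_edges <dv_ij/dtheta>_p,

and since every spline energy is *linear* in its knot values (with the
angular coefficients entering through an exponential transform), each
example compiles once into fixed cardinal-basis arrays; afterwards energies
and gradients are small matrix products.  Optimization uses Adam with the
smoothness/directional-size/steric-core regularization penalties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import splines
from .free_energy import brute_force_reference, solve_marginals
from .geometry import CHI1_EXCLUDED, BackboneChain
from .potential import ParameterSet, PairInteraction, build_system
from .tables import periodic_bilinear

__all__ = [
    "TrainingExample", "OptimizerConfig", "ParameterPacker",
    "CompiledExample", "compile_example", "energy_gap", "regularization",
    "parameter_gradient", "train", "chi1_accuracy", "filter_nonglobular",
    "radius_of_gyration",
]


@dataclass
class TrainingExample:
    """A fixed backbone with its native coarse side-chain states."""

    chain: BackboneChain
    native_states: np.ndarray          # (n,) int
    mask: np.ndarray | None = None     # optional per-residue inclusion flags

    def __post_init__(self):
        self.native_states = np.asarray(self.native_states, dtype=int)
        if self.native_states.shape != (len(self.chain),):
            raise ValueError("one native state required per residue")


@dataclass
class OptimizerConfig:
    """Adam settings and regularization weights."""

    alpha: float = 0.03
    beta1: float = 0.90
    beta2: float = 0.96
    eps: float = 1e-6
    minibatch: int = 256
    n_epochs: int = 50
    seed: int = 0
    reg_smooth: float = 0.01
    reg_dir: float = 0.01
    reg_core: float = 0.01
    egap_per_residue: bool = True
    bp_tol: float = 1e-6
    bp_max_iter: int = 500
    damping: float = 0.4


# ---------------------------------------------------------------------------
# parameter vector packing
# ---------------------------------------------------------------------------

class ParameterPacker:
    """Flatten the trainable spline coefficients into one vector.

    Trainable per interaction pair: the radial knot values of V_radial and
    V_angular except the cutoff knot (pinned to zero), and the raw angular
    coefficients a1, a2 (exponentiated at evaluation).
    """

    def __init__(self, params: ParameterSet):
        self.keys = sorted(params.pair)
        self.slices: dict[tuple, dict[str, slice]] = {}
        off = 0
        for key in self.keys:
            entry = params.pair[key]
            nk = entry.c_unif.shape[0] - 1
            na = entry.a1.shape[0]
            s = {}
            for name, size in (("c_unif", nk), ("c_dir", nk),
                               ("a1", na), ("a2", na)):
                s[name] = slice(off, off + size)
                off += size
            self.slices[key] = s
        self.size = off

    def pack(self, params: ParameterSet) -> np.ndarray:
        v = np.zeros(self.size)
        for key in self.keys:
            e = params.pair[key]
            s = self.slices[key]
            v[s["c_unif"]] = e.c_unif[:-1]
            v[s["c_dir"]] = e.c_dir[:-1]
            v[s["a1"]] = e.a1
            v[s["a2"]] = e.a2
        return v

    def unpack(self, vec: np.ndarray, template: ParameterSet) -> ParameterSet:
        pair = {}
        for key in self.keys:
            e = template.pair[key]
            s = self.slices[key]
            pair[key] = PairInteraction(
                r_cutoff=e.r_cutoff,
                c_unif=np.append(vec[s["c_unif"]], 0.0),
                c_dir=np.append(vec[s["c_dir"]], 0.0),
                a1=vec[s["a1"]].copy(), a2=vec[s["a2"]].copy())
        return replace(template, pair=pair)


# ---------------------------------------------------------------------------
# example compilation
# ---------------------------------------------------------------------------

@dataclass
class _CompiledTerm:
    """One interaction's cardinal-basis arrays; energy is linear algebra."""

    kind: str                  # "site" or "edge"
    i: int
    j: int
    key: tuple
    swapped: bool
    kappa: float
    Brad: np.ndarray           # (rows, n_radial_knots - 1)
    A1: np.ndarray | None      # (rows, n_angular_knots)
    A2: np.ndarray | None
    shape: tuple               # () per-state rows: (S_i,) or (S1, S2)


@dataclass
class CompiledExample:
    counts: list[int]
    vrot: list[np.ndarray]
    terms: list[_CompiledTerm]
    native_states: np.ndarray
    config_flags: tuple


def compile_example(example: TrainingExample,
                    params: ParameterSet) -> CompiledExample:
    """Precompute geometry-dependent basis arrays for a fixed backbone."""
    system = build_system(example.chain, params)
    cfg = params.config
    vrot = []
    for i in range(len(example.chain)):
        phi, psi = system.phi_psi[i]
        val, _, _ = periodic_bilinear(system.vrot_tables[i],
                                      phi if phi is not None else 0.0,
                                      psi if psi is not None else 0.0)
        vrot.append(np.array(val, dtype=float))
    terms: list[_CompiledTerm] = []
    for t in system.site_terms:
        entry = params.pair[t.key]
        rk = splines.radial_knots(entry.r_cutoff)
        Brad = splines.basis_matrix(rk, t.r, zero_tail=True)[:, :-1]
        A1 = A2 = None
        if t.directional and t.x1 is not None:
            ak = splines.angular_knots()
            A1 = splines.basis_matrix(ak, t.x1)
            A2 = splines.basis_matrix(ak, t.x2)
        terms.append(_CompiledTerm(
            kind="site", i=t.i, j=t.j, key=t.key, swapped=False,
            kappa=t.kappa, Brad=Brad, A1=A1, A2=A2, shape=(t.r.shape[0],)))
    for t in system.sc_terms:
        entry = params.pair[t.key]
        rk = splines.radial_knots(entry.r_cutoff)
        rflat = t.r.ravel()
        Brad = splines.basis_matrix(rk, rflat, zero_tail=True)[:, :-1]
        ak = splines.angular_knots()
        A1 = splines.basis_matrix(ak, t.x1.ravel())
        A2 = splines.basis_matrix(ak, t.x2.ravel())
        terms.append(_CompiledTerm(
            kind="edge", i=t.i, j=t.j, key=t.key, swapped=t.swapped,
            kappa=1.0, Brad=Brad, A1=A1, A2=A2, shape=t.r.shape))
    return CompiledExample(
        counts=[len(v) for v in system.v1], vrot=vrot, terms=terms,
        native_states=example.native_states.copy(),
        config_flags=(cfg.isotropic_only, cfg.repulsive_only))


def _term_energy(term: _CompiledTerm, theta: dict, flags):
    isotropic_only, repulsive_only = flags
    th = theta[term.key]
    Vr = term.Brad @ th["c_unif"]
    if repulsive_only:
        return term.kappa * np.maximum(Vr, 0.0)
    e = Vr
    if term.A1 is not None and not isotropic_only:
        e = e + (term.A1 @ th["e1"]) * (term.A2 @ th["e2"]) * (
            term.Brad @ th["c_dir"])
    return term.kappa * e


def _compiled_energies(comp: CompiledExample, theta: dict):
    v1 = [v.copy() for v in comp.vrot]
    v2: dict[tuple[int, int], np.ndarray] = {}
    for term in comp.terms:
        e = _term_energy(term, theta, comp.config_flags)
        if term.kind == "site":
            v1[term.i] = v1[term.i] + e
        else:
            m = e.reshape(term.shape)
            m = m.T if term.swapped else m
            key = (term.i, term.j)
            v2[key] = v2.get(key, 0) + m
    return v1, v2


def _theta_struct(packer: ParameterPacker, vec: np.ndarray) -> dict:
    theta = {}
    for key in packer.keys:
        s = packer.slices[key]
        a1 = vec[s["a1"]]
        a2 = vec[s["a2"]]
        theta[key] = {
            "c_unif": vec[s["c_unif"]], "c_dir": vec[s["c_dir"]],
            "a1": a1, "a2": a2, "e1": np.exp(a1), "e2": np.exp(a2),
        }
    return theta


def _compiled_egap_grad(comp: CompiledExample, theta: dict,
                        packer: ParameterPacker, cfg: OptimizerConfig,
                        want_grad: bool = True,
                        use_brute_force: bool = False):
    """E_gap of a compiled example and (optionally) its parameter gradient."""
    v1, v2 = _compiled_energies(comp, theta)
    nat = comp.native_states
    if use_brute_force:
        ms = brute_force_reference(v1, v2)
    else:
        ms = solve_marginals(v1, v2, damping=cfg.damping, tol=cfg.bp_tol,
                             max_iter=cfg.bp_max_iter)
    vnat = sum(float(v1[i][nat[i]]) for i in range(len(v1)))
    vnat += sum(float(v2[(i, j)][nat[i], nat[j]]) for (i, j) in v2)
    egap = vnat - ms.free_energy
    if not want_grad:
        return egap, None
    grad = np.zeros(packer.size)
    iso, rep = comp.config_flags
    for term in comp.terms:
        th = theta[term.key]
        s = packer.slices[term.key]
        if term.kind == "site":
            w = -ms.p1[term.i].copy()
            w[nat[term.i]] += 1.0
        else:
            W = -ms.p2[(term.i, term.j)].copy()
            W[nat[term.i], nat[term.j]] += 1.0
            if term.swapped:
                W = W.T
            w = W.ravel()
        k = term.kappa
        if rep:
            mask = (term.Brad @ th["c_unif"]) > 0
            grad[s["c_unif"]] += k * ((w * mask) @ term.Brad)
            continue
        grad[s["c_unif"]] += k * (w @ term.Brad)
        if term.A1 is not None and not iso:
            f1 = term.A1 @ th["e1"]
            f2 = term.A2 @ th["e2"]
            vd = term.Brad @ th["c_dir"]
            grad[s["c_dir"]] += k * ((w * f1 * f2) @ term.Brad)
            grad[s["a1"]] += k * ((w * vd * f2) @ term.A1) * th["e1"]
            grad[s["a2"]] += k * ((w * vd * f1) @ term.A2) * th["e2"]
    return egap, grad


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def energy_gap(example: TrainingExample, params: ParameterSet,
               per_residue: bool = False, use_brute_force: bool = False,
               bp_tol: float = 1e-6, bp_max_iter: int = 1000) -> float:
    """E_gap = V(native) - G^SC = -log p(native) for one example."""
    system = build_system(example.chain, params)
    nat = example.native_states
    for i, v in enumerate(system.v1):
        if not 0 <= nat[i] < len(v):
            raise ValueError(f"native state {nat[i]} invalid for residue {i}")
    if use_brute_force:
        ms = brute_force_reference(system.v1, system.v2)
    else:
        ms = solve_marginals(system.v1, system.v2, tol=bp_tol,
                             max_iter=bp_max_iter)
    vnat = sum(float(system.v1[i][nat[i]]) for i in range(len(nat)))
    vnat += sum(float(system.v2[(i, j)][nat[i], nat[j]])
                for (i, j) in system.v2)
    e = vnat - ms.free_energy
    return e / len(nat) if per_residue else e


def regularization(params: ParameterSet,
                   weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
                   ) -> dict[str, float]:
    """Smoothness, directional-size and steric-core penalties.

    Returns the three raw sums (over all pairs, at the knot locations) and
    their weighted total: sum of squared second differences of c_unif, sum
    of squared c_dir, and (c_unif[0] - 5 k_BT)^2.
    """
    smooth = dir_sz = core = 0.0
    for entry in params.pair.values():
        cu = entry.c_unif
        cd = entry.c_dir
        smooth += float(np.sum((2 * cu[1:-1] - cu[:-2] - cu[2:]) ** 2))
        dir_sz += float(np.sum(cd ** 2))
        core += float((cu[0] - 5.0) ** 2)
    total = weights[0] * smooth + weights[1] * dir_sz + weights[2] * core
    return {"smooth": smooth, "dir": dir_sz, "core": core, "total": total}


def _reg_grad(packer: ParameterPacker, vec: np.ndarray,
              cfg: OptimizerConfig):
    """Weighted regularization value and gradient on the packed vector."""
    val = 0.0
    grad = np.zeros_like(vec)
    for key in packer.keys:
        s = packer.slices[key]
        cu = np.append(vec[s["c_unif"]], 0.0)
        cd = np.append(vec[s["c_dir"]], 0.0)
        d2 = 2 * cu[1:-1] - cu[:-2] - cu[2:]
        val += cfg.reg_smooth * float(np.sum(d2 ** 2))
        g = np.zeros_like(cu)
        g[1:-1] += 4 * d2
        g[:-2] -= 2 * d2
        g[2:] -= 2 * d2
        gu = cfg.reg_smooth * g[:-1]
        gu[0] += cfg.reg_core * 2 * (cu[0] - 5.0)
        val += cfg.reg_core * float((cu[0] - 5.0) ** 2)
        grad[s["c_unif"]] += gu
        val += cfg.reg_dir * float(np.sum(cd ** 2))
        grad[s["c_dir"]] += cfg.reg_dir * 2 * cd[:-1]
    return val, grad


def parameter_gradient(example: TrainingExample, params: ParameterSet,
                       packer: ParameterPacker | None = None,
                       use_brute_force: bool = False,
                       bp_tol: float = 1e-8, per_residue: bool = False):
    """dE_gap/dtheta over all trainable spline coefficients.

    Returns (egap, gradient vector, packer).  Coefficients of pairs absent
    from the example get exactly zero gradient.
    """
    packer = packer or ParameterPacker(params)
    comp = compile_example(example, params)
    theta = _theta_struct(packer, packer.pack(params))
    cfg = OptimizerConfig(bp_tol=bp_tol, bp_max_iter=2000)
    egap, grad = _compiled_egap_grad(comp, theta, packer, cfg,
                                     use_brute_force=use_brute_force)
    if per_residue:
        n = len(comp.counts)
        return egap / n, grad / n, packer
    return egap, grad, packer


@dataclass
class TrainResult:
    params: ParameterSet
    loss_trace: list[tuple[int, float, float]]   # (epoch, mean E_gap, reg)
    packer: ParameterPacker


def train(dataset: list[TrainingExample], params0: ParameterSet,
          config: OptimizerConfig | None = None,
          compiled: list[CompiledExample] | None = None) -> TrainResult:
    """Adam minimization of mean E_gap + regularization.

    Deterministic given ``config.seed``; raises on divergent (NaN) loss.
    Examples are compiled once (the backbones are fixed), then each epoch
    visits shuffled minibatches.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    cfg = config or OptimizerConfig()
    packer = ParameterPacker(params0)
    if compiled is None:
        compiled = [compile_example(ex, params0) for ex in dataset]
    vec = packer.pack(params0)
    m = np.zeros_like(vec)
    v = np.zeros_like(vec)
    rng = np.random.default_rng(cfg.seed)
    trace = []
    step = 0
    n = len(compiled)
    for epoch in range(cfg.n_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.minibatch):
            batch = order[start:start + cfg.minibatch]
            theta = _theta_struct(packer, vec)
            g = np.zeros_like(vec)
            loss = 0.0
            for idx in batch:
                comp = compiled[idx]
                egap, grad = _compiled_egap_grad(comp, theta, packer, cfg)
                scale = 1.0 / len(comp.counts) if cfg.egap_per_residue else 1.0
                loss += egap * scale
                g += grad * scale
            loss /= len(batch)
            g /= len(batch)
            rval, rgrad = _reg_grad(packer, vec, cfg)
            loss += rval
            g += rgrad
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"divergent training loss at epoch {epoch}: {loss}")
            epoch_loss += loss * len(batch)
            step += 1
            m = cfg.beta1 * m + (1 - cfg.beta1) * g
            v = cfg.beta2 * v + (1 - cfg.beta2) * g * g
            mhat = m / (1 - cfg.beta1 ** step)
            vhat = v / (1 - cfg.beta2 ** step)
            if cfg.alpha != 0.0:
                vec = vec - cfg.alpha * mhat / (np.sqrt(vhat) + cfg.eps)
        trace.append((epoch, epoch_loss / n,
                      _reg_grad(packer, vec, cfg)[0]))
    return TrainResult(params=packer.unpack(vec, params0),
                       loss_trace=trace, packer=packer)


def chi1_accuracy(dataset: list[TrainingExample], params: ParameterSet,
                  prior_only: bool = False, bp_tol: float = 1e-6
                  ) -> tuple[float, int]:
    """Fraction of eligible residues whose predicted chi1 bin is native.

    The prediction is the argmax of the 1-residue marginal, mapped to its
    chi1 bin (unambiguous: no coarse state mixes chi1 bins).  Alanine,
    glycine and proline are excluded from numerator and denominator; with
    zero eligible residues the accuracy is NaN.  ``prior_only`` scores the
    rotamer prior without any interactions (the no-interaction baseline).
    """
    correct = 0
    total = 0
    for ex in dataset:
        chain = ex.chain
        if prior_only:
            system = build_system(chain, params)
            p1 = []
            for i in range(len(chain)):
                phi, psi = system.phi_psi[i]
                val, _, _ = periodic_bilinear(
                    system.vrot_tables[i],
                    phi if phi is not None else 0.0,
                    psi if psi is not None else 0.0)
                b = np.exp(-(val - val.min()))
                p1.append(b / b.sum())
        else:
            system = build_system(chain, params)
            ms = solve_marginals(system.v1, system.v2, tol=bp_tol,
                                 max_iter=1000)
            p1 = ms.p1
        for i, rt in enumerate(chain.residue_types):
            if rt in CHI1_EXCLUDED:
                continue
            if ex.mask is not None and not ex.mask[i]:
                continue
            chi1 = params.chi1_of_state[rt]
            pred = int(np.argmax(p1[i]))
            if chi1[pred] == chi1[ex.native_states[i]]:
                correct += 1
            total += 1
    if total == 0:
        return float("nan"), 0
    return correct / total, total


def radius_of_gyration(chain: BackboneChain) -> float:
    ca = chain.CA
    return float(np.sqrt(((ca - ca.mean(axis=0)) ** 2).sum(axis=1).mean()))


def filter_nonglobular(chains: list[BackboneChain],
                       residual_threshold: float = 0.1,
                       seed: int = 0, min_samples: int = 2,
                       max_trials: int = 1000):
    """Drop chains that are outliers of the log Rg vs log N_res trend.

    Globular proteins follow a power law R_g ~ N^nu, a straight line in
    log-log space; RANSAC identifies chains off that line (threshold in
    log10 R_g residual).  With fewer than 10 chains the input passes
    through unchanged with a warning.
    """
    if len(chains) < 10:
        warnings.warn("too few chains for RANSAC; passing all through",
                      stacklevel=2)
        return list(chains), np.ones(len(chains), dtype=bool)
    from sklearn.linear_model import LinearRegression, RANSACRegressor

    x = np.log10([len(c) for c in chains]).reshape(-1, 1)
    y = np.log10([radius_of_gyration(c) for c in chains])
    model = RANSACRegressor(LinearRegression(), min_samples=min_samples,
                            residual_threshold=residual_threshold,
                            max_trials=max_trials, random_state=seed)
    model.fit(x, y)
    mask = model.inlier_mask_
    return [c for c, keep in zip(chains, mask) if keep], mask
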