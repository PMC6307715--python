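"""Belief propagation on the side-chain graph and the Bethe free energy.

The side-chain states of a fixed backbone form a pairwise Markov random
field: one discrete variable per residue (its coarse rotamer state), a
1-residue energy vector v_i and a 2-residue energy matrix v_ij per graph
edge.  The free energy G^SC = -log Z is approximated by the Bethe form

    G^SC = <v> - S_approx,

where the entropy keeps node terms and subtracts edge mutual informations
(3-body and higher correlations are ignored).  Belief propagation finds the
stationary single and pair marginals by damped self-consistent iteration;
on tree-structured graphs the result is exact.

Pairwise-consistent marginals need not be representable by any joint
distribution — three variables with p12 = p23 = diag(1/3, 1/3, 1/3) and
p13 uniform 1/9 satisfy every pairwise check yet admit no joint law — so
the consistency report documents a necessary, not sufficient, condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeliefState", "MarginalSet", "bp_initialize", "bp_iterate",
    "solve_marginals", "bethe_free_energy", "check_consistency",
    "brute_force_reference",
]

_FLOOR = 1e-300   # guards message division with strong sterics


def _edges_of(v2: dict) -> list[tuple[int, int]]:
    return sorted(v2.keys())


def _pair_factor(v2, i, j):
    """e^{-v_ij} with rows indexed by states of i, columns by states of j."""
    if (i, j) in v2:
        return np.exp(-v2[(i, j)])
    return np.exp(-v2[(j, i)]).T


@dataclass
class BeliefState:
    """Node beliefs and directed edge beliefs of one BP round.

    ``messages[(j, i)]`` is the belief of edge (i, j) about residue i coming
    from residue j.  Node beliefs are normalized; messages are normalized to
    unit sum each round (the fixed point is scale-invariant per message).
    """

    beliefs: list[np.ndarray]
    messages: dict[tuple[int, int], np.ndarray]
    round: int = 0
    damping: float = 0.4


def bp_initialize(v1: list[np.ndarray], v2: dict, graph=None) -> BeliefState:
    """Round-0 state: b_i ~ e^{-v_i}; messages summed through e^{-v_ij}."""
    beliefs = []
    for v in v1:
        b = np.exp(-(v - v.min()))
        beliefs.append(b / b.sum())
    messages = {}
    for (i, j) in _edges_of(v2):
        for (src, dst) in ((j, i), (i, j)):
            F = _pair_factor(v2, dst, src)      # (S_dst, S_src)
            m = F @ beliefs[src]
            m = np.maximum(m, _FLOOR)
            messages[(src, dst)] = m / m.sum()
    return BeliefState(beliefs=beliefs, messages=messages, round=0)


def bp_iterate(state: BeliefState, v1: list[np.ndarray], v2: dict,
               damping: float = 0.4) -> BeliefState:
    """One synchronous round: all edge messages, then all node beliefs.

    Messages divide the source belief by the reverse message; node beliefs
    mix the new estimate with the previous round through the damping
    constant (damping = 1 leaves them unchanged).
    """
    edges = _edges_of(v2)
    new_msgs: dict[tuple[int, int], np.ndarray] = {}
    for (i, j) in edges:
        for (src, dst) in ((j, i), (i, j)):
            F = _pair_factor(v2, dst, src)
            # edges can appear between rounds (dynamic graph): a missing
            # reverse message acts as uniform, which is scale-equivalent
            # to the round-0 initialization
            rev = state.messages.get(
                (dst, src), np.full(len(state.beliefs[src]),
                                    1.0 / len(state.beliefs[src])))
            ratio = state.beliefs[src] / np.maximum(rev, _FLOOR)
            m = F @ ratio
            m = np.maximum(m, _FLOOR)
            new_msgs[(src, dst)] = m / m.sum()

    incoming: dict[int, list[np.ndarray]] = {}
    for (src, dst), m in new_msgs.items():
        incoming.setdefault(dst, []).append(m)

    new_beliefs = []
    for i, v in enumerate(v1):
        logb = -(v - v.min())
        for m in incoming.get(i, ()):
            logb = logb + np.log(m)
        b = np.exp(logb - logb.max())
        b = np.maximum(b / b.sum(), _FLOOR)
        nb = damping * state.beliefs[i] + (1.0 - damping) * b
        new_beliefs.append(nb / nb.sum())
    return BeliefState(beliefs=new_beliefs, messages=new_msgs,
                       round=state.round + 1, damping=damping)


@dataclass
class MarginalSet:
    """Converged single and pair marginals plus the Bethe free energy."""

    p1: list[np.ndarray]
    p2: dict[tuple[int, int], np.ndarray]
    free_energy: float
    converged: bool
    iterations: int
    belief_state: BeliefState | None = None

    def max_consistency_violation(self) -> float:
        rep = check_consistency(self.p1, self.p2)
        return max(rep.values())


def _pair_marginals(state: BeliefState, v2: dict) -> dict:
    p2 = {}
    for (i, j) in _edges_of(v2):
        F = _pair_factor(v2, i, j)
        qi = state.beliefs[i] / np.maximum(state.messages[(j, i)], _FLOOR)
        qj = state.beliefs[j] / np.maximum(state.messages[(i, j)], _FLOOR)
        m = qi[:, None] * F * qj[None, :]
        p2[(i, j)] = m / m.sum()
    return p2


def solve_marginals(v1: list[np.ndarray], v2: dict, graph=None,
                    damping: float = 0.4, tol: float = 1e-3,
                    max_iter: int = 1000,
                    warm_start: BeliefState | None = None) -> MarginalSet:
    """Iterate BP until node beliefs move less than ``tol`` everywhere.

    Returns the best state flagged non-converged when ``max_iter`` is hit
    (never raises mid-simulation).  ``warm_start`` resumes from a previous
    frame's beliefs.
    """
    state = warm_start
    if state is not None and (
            len(state.beliefs) != len(v1)
            or any(len(b) != len(v) for b, v in zip(state.beliefs, v1))):
        state = None    # incompatible warm state; fall back to cold start
    if state is None:
        state = bp_initialize(v1, v2)
    converged = False
    iterations = 0
    for _ in range(max_iter):
        new = bp_iterate(state, v1, v2, damping=damping)
        iterations += 1
        delta = max((np.abs(nb - ob).max()
                     for nb, ob in zip(new.beliefs, state.beliefs)),
                    default=0.0)
        state = new
        if delta < tol:
            converged = True
            break
    p1 = [b.copy() for b in state.beliefs]
    p2 = _pair_marginals(state, v2)
    g = bethe_free_energy(p1, p2, v1, v2)
    return MarginalSet(p1=p1, p2=p2, free_energy=g, converged=converged,
                       iterations=iterations, belief_state=state)


def _xlogx(p):
    return np.where(p > 0, p * np.log(np.maximum(p, _FLOOR)), 0.0)


def bethe_free_energy(p1: list[np.ndarray], p2: dict,
                      v1: list[np.ndarray], v2: dict, graph=None) -> float:
    """G^SC = <v> - S_approx with node entropies minus edge mutual information.

    Zero-probability states follow the 0 log 0 = 0 convention.
    """
    mean_v = sum(float(np.dot(p, v)) for p, v in zip(p1, v1))
    s = -sum(float(_xlogx(p).sum()) for p in p1)
    for (i, j), pij in p2.items():
        vij = v2[(i, j)]
        mean_v += float((pij * vij).sum())
        outer = p1[i][:, None] * p1[j][None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((pij > 0) & (outer > 0), pij / np.maximum(
                outer, _FLOOR), 1.0)
            mi = np.where(pij > 0, pij * np.log(ratio), 0.0).sum()
        s -= float(mi)
    return mean_v - s


def check_consistency(p1: list[np.ndarray], p2: dict,
                      p2_reverse: dict | None = None) -> dict[str, float]:
    """Max violations of marginalization, normalization and symmetry.

    These are necessary conditions only: pairwise-consistent marginals can
    still fail to be representable by any joint distribution.
    """
    marg = 0.0
    norm = 0.0
    for (i, j), pij in p2.items():
        norm = max(norm, abs(float(pij.sum()) - 1.0))
        marg = max(marg, float(np.abs(pij.sum(axis=1) - p1[i]).max()))
        marg = max(marg, float(np.abs(pij.sum(axis=0) - p1[j]).max()))
    sym = 0.0
    if p2_reverse:
        for (i, j), pij in p2.items():
            if (j, i) in p2_reverse:
                sym = max(sym, float(np.abs(pij - p2_reverse[(j, i)].T).max()))
    return {"marginalization": marg, "normalization": norm, "symmetry": sym}


def brute_force_reference(v1: list[np.ndarray], v2: dict, graph=None,
                          max_states: int = 10_000_000) -> MarginalSet:
    """Exact marginals and -log Z by complete enumeration (testing oracle)."""
    counts = [len(v) for v in v1]
    total = 1
    for c in counts:
        total *= c
        if total > max_states:
            raise ValueError("state space too large for brute-force reference")
    n = len(v1)
    edges = _edges_of(v2)

    # accumulate log-weights over the product space by broadcasting
    logw = np.zeros(counts)
    for i, v in enumerate(v1):
        shape = [1] * n
        shape[i] = counts[i]
        logw = logw - v.reshape(shape)
    for (i, j) in edges:
        shape = [1] * n
        shape[i], shape[j] = counts[i], counts[j]
        logw = logw - v2[(i, j)].reshape(shape)
    m = logw.max()
    w = np.exp(logw - m)
    Z = w.sum()
    neg_logZ = -(m + np.log(Z))
    p = w / Z
    p1 = []
    for i in range(n):
        axes = tuple(k for k in range(n) if k != i)
        p1.append(p.sum(axis=axes))
    p2 = {}
    for (i, j) in edges:
        axes = tuple(k for k in range(n) if k not in (i, j))
        pij = p.sum(axis=axes)
        if i > j:
            pij = pij.T
        p2[(i, j)] = pij
    return MarginalSet(p1=p1, p2=p2, free_energy=float(neg_logZ),
                       converged=True, iterations=0)
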