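"""Optimized aggregation of fine rotamer states into <= 6 coarse states.

A fine rotamer library tabulates, per residue type, discrete side-chain
states f labelled by (chi1, chi2, higher-chi) bins, with backbone-dihedral
dependent probabilities p^f(phi, psi) and representative atom positions.
Coarse-graining groups fine states into at most six coarse states chi~, each
later represented by a single oriented bead.

The grouping is chosen to minimize the Ramachandran-weighted positional
variance of the side-chain atoms within each coarse state, searched by
complete enumeration over all admissible partitions.  Admissibility:

1. the grouping depends only on the (chi1, chi2) bins,
2. each coarse state contains a single chi1 bin (so the coarse -> chi1 map
   is unambiguous),
3. the chi2 bins inside one coarse state form a circularly contiguous run.

Contiguity is judged on the cyclic order of the chi2 bins present for the
given chi1 bin.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhiPsiGrid",
    "ResidueFineStates",
    "FineRotamerLibrary",
    "RamachandranDensity",
    "ResidueCoarsePartition",
    "CoarsePartition",
    "coarse_states",
    "partition_error",
    "optimize_partition",
    "enumerate_admissible_mappings",
]


@dataclass(frozen=True)
class PhiPsiGrid:
    """Regular midpoint grid on (phi, psi) in [-pi, pi)^2."""

    n_phi: int = 36
    n_psi: int = 36

    @property
    def shape(self):
        return (self.n_phi, self.n_psi)

    @property
    def cell_area(self) -> float:
        return (2 * np.pi / self.n_phi) * (2 * np.pi / self.n_psi)

    def centers(self):
        phi = -np.pi + (np.arange(self.n_phi) + 0.5) * 2 * np.pi / self.n_phi
        psi = -np.pi + (np.arange(self.n_psi) + 0.5) * 2 * np.pi / self.n_psi
        return phi, psi


@dataclass
class ResidueFineStates:
    """Fine rotamer states of one residue type.

    ``atoms`` is (F, A, 3) for phi/psi-independent positions or
    (F, n_phi, n_psi, A, 3) for tabulated ones; ``probs`` is
    (F, n_phi, n_psi) and sums to 1 over F at every grid point.
    """

    chi1_bin: np.ndarray          # (F,) int
    chi2_bin: np.ndarray          # (F,) int
    higher_bin: np.ndarray        # (F,) int; chi3+ label, 0 if none
    probs: np.ndarray             # (F, n_phi, n_psi)
    atoms: np.ndarray             # (F, A, 3) or (F, n_phi, n_psi, A, 3)
    n_chi1_bins: int
    n_chi2_bins: int

    @property
    def n_fine(self) -> int:
        return self.probs.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[-2]

    @property
    def grid_atoms(self) -> np.ndarray:
        """atoms broadcast to (F, n_phi, n_psi, A, 3)."""
        if self.atoms.ndim == 3:
            F, A, _ = self.atoms.shape
            _, G1, G2 = self.probs.shape
            return np.broadcast_to(self.atoms[:, None, None], (F, G1, G2, A, 3))
        return self.atoms

    def validate(self, atol: float = 1e-9):
        if np.any(self.probs < -atol):
            raise ValueError("negative fine-state probabilities")
        tot = self.probs.sum(axis=0)
        if np.max(np.abs(tot - 1.0)) > atol:
            raise ValueError("fine-state probabilities do not sum to 1 on the grid")


@dataclass
class FineRotamerLibrary:
    grid: PhiPsiGrid
    residues: dict[str, ResidueFineStates]

    def validate(self, atol: float = 1e-9):
        for name, entry in self.residues.items():
            if entry.probs.shape[1:] != self.grid.shape:
                raise ValueError(f"{name}: probability grid mismatch")
            entry.validate(atol=atol)


@dataclass
class RamachandranDensity:
    """Probability density over (phi, psi); integrates to 1 by midpoint rule."""

    grid: PhiPsiGrid
    density: np.ndarray  # (n_phi, n_psi)

    def validate(self, atol: float = 1e-6):
        if self.density.shape != self.grid.shape:
            raise ValueError("density grid mismatch")
        if np.any(self.density < 0):
            raise ValueError("negative density")
        total = float(self.density.sum() * self.grid.cell_area)
        if abs(total - 1.0) > atol:
            raise ValueError(f"density integrates to {total}, not 1")

    @classmethod
    def uniform(cls, grid: PhiPsiGrid) -> "RamachandranDensity":
        d = np.full(grid.shape, 1.0 / (4 * np.pi**2))
        return cls(grid=grid, density=d)


@dataclass
class ResidueCoarsePartition:
    """Partition of the fine states of one residue type into coarse states."""

    mapping: np.ndarray           # (F,) int, fine -> coarse
    n_coarse: int
    q: np.ndarray                 # (C, n_phi, n_psi) coarse probabilities
    y: np.ndarray                 # (C, n_phi, n_psi, A, 3) coarse positions
    chi1_of_state: np.ndarray     # (C,) chi1 bin per coarse state
    empty_weight_flag: np.ndarray = field(default=None)  # (C, n_phi, n_psi) bool

    @property
    def sigma2_per_grid(self):
        raise AttributeError("use partition_error for the variance")


@dataclass
class CoarsePartition:
    grid: PhiPsiGrid
    residues: dict[str, ResidueCoarsePartition]


def _canonical_mapping(mapping: np.ndarray) -> tuple[int, ...]:
    """Relabel coarse indices by order of first appearance along f."""
    relabel: dict[int, int] = {}
    out = []
    for c in mapping:
        if c not in relabel:
            relabel[c] = len(relabel)
        out.append(relabel[c])
    return tuple(out)


def _coarse_residue(entry: ResidueFineStates,
                    mapping: np.ndarray) -> ResidueCoarsePartition:
    mapping = np.asarray(mapping, dtype=int)
    if mapping.shape != (entry.n_fine,):
        raise ValueError("mapping must cover every fine state")
    used = set(mapping.tolist())
    if used != set(range(int(mapping.max()) + 1)):
        raise ValueError("empty coarse state in mapping")
    canon = np.array(_canonical_mapping(mapping))
    n_coarse = int(canon.max()) + 1
    counts = np.bincount(canon, minlength=n_coarse)
    if np.any(counts == 0):
        raise ValueError("empty coarse state")
    G1, G2 = entry.probs.shape[1:]
    A = entry.n_atoms
    q = np.zeros((n_coarse, G1, G2))
    y = np.zeros((n_coarse, G1, G2, A, 3))
    flag = np.zeros((n_coarse, G1, G2), dtype=bool)
    chi1 = np.zeros(n_coarse, dtype=int)
    gx = entry.grid_atoms
    for c in range(n_coarse):
        members = np.flatnonzero(canon == c)
        w = entry.probs[members]                       # (m, G1, G2)
        x = gx[members]                                # (m, G1, G2, A, 3)
        qc = w.sum(axis=0)
        s1 = np.einsum("mgh,mghak->ghak", w, x)
        zero = qc <= 0.0
        flag[c] = zero
        denom = np.where(zero, 1.0, qc)
        yc = s1 / denom[..., None, None]
        if np.any(zero):
            # q^c = 0 there: fall back to the unweighted member mean
            yc_un = x.mean(axis=0)
            yc = np.where(zero[..., None, None], yc_un, yc)
        q[c] = qc
        y[c] = yc
        bins = set(entry.chi1_bin[members].tolist())
        if len(bins) != 1:
            raise ValueError("coarse state mixes chi1 bins")
        chi1[c] = bins.pop()
    return ResidueCoarsePartition(mapping=canon, n_coarse=n_coarse, q=q, y=y,
                                  chi1_of_state=chi1, empty_weight_flag=flag)


def coarse_states(library: FineRotamerLibrary,
                  partition: dict[str, np.ndarray]) -> CoarsePartition:
    """Aggregate fine states per the given fine -> coarse mappings.

    q^c(phi, psi) is the summed fine probability and y^c the probability-
    weighted mean atom position within each coarse state.
    """
    out = {}
    for name, entry in library.residues.items():
        if name not in partition:
            raise ValueError(f"no mapping supplied for residue type {name}")
        out[name] = _coarse_residue(entry, partition[name])
    return CoarsePartition(grid=library.grid, residues=out)


def _partition_error_entry(entry: ResidueFineStates, mapping: np.ndarray,
                           rama: RamachandranDensity) -> float:
    """Ramachandran-weighted positional variance of one residue's partition."""
    canon = np.array(_canonical_mapping(np.asarray(mapping, dtype=int)))
    n_coarse = int(canon.max()) + 1
    gx = entry.grid_atoms
    G1, G2 = entry.probs.shape[1:]
    sig = np.zeros((G1, G2))
    for c in range(n_coarse):
        members = np.flatnonzero(canon == c)
        w = entry.probs[members]
        x = gx[members]
        W = w.sum(axis=0)
        s1 = np.einsum("mgh,mghak->ghak", w, x)
        s2 = np.einsum("mgh,mghak,mghak->gh", w, x, x)
        denom = np.where(W > 0, W, 1.0)
        # sum_f w_f |x_f - ybar|^2 = s2 - |s1|^2 / W   (zero when W = 0)
        sig += np.where(W > 0, s2 - np.einsum("ghak,ghak->gh", s1, s1) / denom,
                        0.0)
    sig /= entry.n_atoms
    return float((rama.density * sig).sum() * rama.grid.cell_area)


def partition_error(library: FineRotamerLibrary,
                    partition: dict[str, np.ndarray],
                    rama: RamachandranDensity) -> dict[str, float]:
    """sigma^2 (A^2) per residue type for the given partition."""
    return {name: _partition_error_entry(entry, partition[name], rama)
            for name, entry in library.residues.items()}


# ---------------------------------------------------------------------------
# admissible-partition enumeration
# ---------------------------------------------------------------------------

def _cyclic_blocks(m: int, k: int):
    """All splits of a cycle of m items into k circularly contiguous blocks.

    Yields tuples block_of_item (length m) with blocks labelled by order of
    first appearance.
    """
    if k == 1:
        yield tuple([0] * m)
        return
    if k > m:
        return
    # choose k cut positions among the m gaps (gap g separates item g-1, g)
    for cuts in itertools.combinations(range(m), k):
        labels = [0] * m
        # block boundaries at each cut; walk from first cut
        for b in range(k):
            start = cuts[b]
            end = cuts[(b + 1) % k]
            i = start
            while True:
                labels[i] = b
                i = (i + 1) % m
                if i == end:
                    break
        yield tuple(_canonical_mapping(np.array(labels)))


def enumerate_admissible_mappings(entry: ResidueFineStates, max_states: int):
    """Yield every admissible fine -> coarse mapping with <= max_states states.

    Grouping acts on (chi1, chi2) cells; each chi1 bin's present chi2 cells
    (in cyclic order) are split into contiguous blocks, and fine states that
    share (chi1, chi2) always share a coarse state.
    """
    cells = sorted(set(zip(entry.chi1_bin.tolist(), entry.chi2_bin.tolist())))
    chi1_vals = sorted(set(c1 for c1, _ in cells))
    per_chi1 = {c1: sorted(c2 for cc1, c2 in cells if cc1 == c1)
                for c1 in chi1_vals}
    n_chi1 = len(chi1_vals)
    if n_chi1 > max_states:
        raise ValueError(
            f"{n_chi1} chi1 bins cannot fit in {max_states} coarse states")

    # per chi1 bin: all cyclic splits with any block count
    options = []
    for c1 in chi1_vals:
        m = len(per_chi1[c1])
        opts = []
        for k in range(1, min(m, max_states) + 1):
            for labels in set(_cyclic_blocks(m, k)):
                opts.append((k, labels))
        options.append(opts)

    for combo in itertools.product(*options):
        total = sum(k for k, _ in combo)
        if total > max_states:
            continue
        cell_state: dict[tuple[int, int], int] = {}
        offset = 0
        for c1, (k, labels) in zip(chi1_vals, combo):
            for c2, lab in zip(per_chi1[c1], labels):
                cell_state[(c1, c2)] = offset + lab
            offset += k
        mapping = np.array([cell_state[(a, b)] for a, b in
                            zip(entry.chi1_bin, entry.chi2_bin)])
        yield _canonical_mapping(mapping)


def optimize_partition(library: FineRotamerLibrary, rama: RamachandranDensity,
                       max_states: int = 6) -> CoarsePartition:
    """Admissible partition minimizing sigma^2, by complete enumeration.

    Ties are broken by the lexicographically smallest canonical mapping.
    """
    best: dict[str, np.ndarray] = {}
    for name, entry in library.residues.items():
        best_err = np.inf
        best_map: tuple[int, ...] | None = None
        seen: set[tuple[int, ...]] = set()
        for mapping in enumerate_admissible_mappings(entry, max_states):
            if mapping in seen:
                continue
            seen.add(mapping)
            err = _partition_error_entry(entry, np.array(mapping), rama)
            if err < best_err - 1e-15 or (
                    abs(err - best_err) <= 1e-15
                    and (best_map is None or mapping < best_map)):
                best_err = err
                best_map = mapping
        assert best_map is not None
        best[name] = np.array(best_map)
    return coarse_states(library, best)
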