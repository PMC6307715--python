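"""Dynamic residue interaction graph.

Two residues are neighbors when their side-chain beads come within the
side chain-side chain cutoff for *any* pair of coarse states; a side chain
interacts with a backbone site (carbonyl O, amide H, or one of the N/CA/C
interaction beads of another residue) when any of its state beads is within
the side chain-backbone cutoff of that site.  The graph is rebuilt every
time the backbone moves; the potential stays continuous across edge events
because every interaction vanishes at its cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["SideChainGraph", "build_graph", "BACKBONE_SITES"]

BACKBONE_SITES = ("O", "H", "N", "CA", "C")


@dataclass
class SideChainGraph:
    """Neighbor structure for one backbone configuration.

    ``sc_edges``: sorted list of residue index pairs (i < j).
    ``bb_terms``: sorted list of (i, j, site) meaning the side chain of
    residue i interacts with backbone site ``site`` of residue j.
    """

    n_residues: int
    state_counts: np.ndarray
    sc_edges: list[tuple[int, int]] = field(default_factory=list)
    bb_terms: list[tuple[int, int, str]] = field(default_factory=list)

    def neighbors(self, i: int) -> list[int]:
        out = [b for a, b in self.sc_edges if a == i]
        out += [a for a, b in self.sc_edges if b == i]
        return sorted(out)

    def edge_list_text(self) -> str:
        lines = [f"{i}\t{j}\tSC-SC" for i, j in self.sc_edges]
        lines += [f"{i}\t{j}\tSC-{s}" for i, j, s in self.bb_terms]
        return "\n".join(lines) + "\n"


def _min_state_dist_ok(bi: np.ndarray, bj: np.ndarray, cutoff: float) -> bool:
    d2 = np.sum((bi[:, None, :] - bj[None, :, :]) ** 2, axis=-1)
    return bool(d2.min() < cutoff**2)


def build_graph(bead_positions: list[np.ndarray],
                site_positions: dict[str, np.ndarray] | None,
                sc_sc_cutoff: float = 7.0,
                sc_bb_cutoff: float = 5.0,
                min_seq_sep: int = 1,
                include_own_backbone: bool = False,
                method: str = "kdtree") -> SideChainGraph:
    """Construct the interaction graph from per-state bead positions.

    ``bead_positions[i]`` is the (S_i, 3) array of residue i's state beads.
    ``site_positions`` maps site name -> (n, 3) array (NaN rows = absent).
    ``method`` "kdtree" uses a spatial tree prefilter; "brute" checks all
    pairs.  Both produce identical edge sets; the cutoff comparison is a
    strict inequality (energetically irrelevant: the potential vanishes at
    the cutoff).
    """
    n = len(bead_positions)
    counts = np.array([b.shape[0] for b in bead_positions])
    g = SideChainGraph(n_residues=n, state_counts=counts)

    if method == "brute":
        cand = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        flat = np.concatenate(bead_positions, axis=0)
        owner = np.repeat(np.arange(n), counts)
        tree = cKDTree(flat)
        pairs = tree.query_pairs(sc_sc_cutoff, output_type="ndarray")
        cand = sorted({(min(owner[a], owner[b]), max(owner[a], owner[b]))
                       for a, b in pairs if owner[a] != owner[b]})
    for i, j in cand:
        if abs(i - j) < min_seq_sep:
            continue
        if _min_state_dist_ok(bead_positions[i], bead_positions[j],
                              sc_sc_cutoff):
            g.sc_edges.append((i, j))
    g.sc_edges.sort()

    if site_positions:
        for site in BACKBONE_SITES:
            if site not in site_positions:
                continue
            pos = site_positions[site]
            for i in range(n):
                for j in range(n):
                    if j == i and not include_own_backbone:
                        continue
                    p = pos[j]
                    if not np.all(np.isfinite(p)):
                        continue
                    d2 = np.sum((bead_positions[i] - p) ** 2, axis=-1)
                    if d2.min() < sc_bb_cutoff**2:
                        g.bb_terms.append((i, j, site))
        g.bb_terms.sort()
    return g
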