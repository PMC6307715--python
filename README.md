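# sidebead

Coarse-grained side-chain packing and free-energy dynamics for proteins.

`sidebead` is for structural-bioinformatics and molecular-modelling work
that needs side-chain physics without side-chain atoms: χ1 rotamer
prediction from a backbone trace, a side-chain free energy smooth enough
to drive backbone molecular dynamics, and maximum-likelihood training of
the underlying interaction potential from observed rotamer states.

## The model in brief

Each residue is reduced to its backbone N/CA/C atoms plus one *oriented
bead* (position + unit direction) that may sit in up to six coarse
rotamer states χ̃ ∈ {1…6}.  Coarse states are built from a fine rotamer
library by minimizing the Ramachandran-weighted positional variance

σ² = ∫ p^Rama(φ,ψ) Σ_f [p^f(φ,ψ)/N_atom] Σ_ij (x^f_ij − y^{c(f)}_ij)² dφ dψ

over all partitions c(f) in which each coarse state holds a single χ1
bin and a contiguous run of χ2 bins.

For a fixed backbone, the side chains form a pairwise Markov random
field: one-body energies v_i(χ̃_i) (rotamer prior + side chain–backbone
terms) and pair energies v_ij(χ̃_i, χ̃_j) from the oriented-bead potential

V = κ ( V_radial(r₁₂) + ang1(−n₁·n̂₁₂)·ang2(n₂·n̂₁₂)·V_angular(r₁₂) ),

four cubic splines per interaction pair, with κ = 1 − f switching off
side chain–O/H terms at backbone sites whose hydrogen-bond confidence f
is high.  The side-chain free energy is the Bethe approximation

G^SC = ⟨v⟩ − S_approx,  S_approx = Σ_i H(p_i) − Σ_{ij} MI(p_ij),

minimized by damped belief propagation (exact on trees, typically 10–20
iterations on 50-residue systems).  Because the marginals are stationary,
dG^SC/db reduces to the marginal-weighted energy derivatives — analytic
forces on N/CA/C through every placement (Kabsch frames, O/H
constructions, H-bond switches) — and ∂E_gap/∂θ, with
E_gap = V(χ̃_native) − G^SC = −log p(native), drives Adam training of the
spline coefficients.  A BAOAB Langevin integrator with replica exchange
runs backbone dynamics on V_backbone + G^SC.

Everything runs on synthetic data generated in-package: toy rotamer
libraries, ideal-geometry backbones, planted potentials, and training
sets drawn exactly from the planted Boltzmann distribution.

## Worked example

```python
import numpy as np
from sidebead import synthetic as syn
from sidebead.potential import build_system
from sidebead.free_energy import solve_marginals
from sidebead.rotamer import PhiPsiGrid

grid = PhiPsiGrid(18, 18)
library = syn.gen_rotamer_library(seed=1, n_residue_types=3,
                                  states_per_type=6, grid=grid)
rama = syn.gen_rama_density(0, grid)
params = syn.gen_parameter_set(library, rama=rama, seed=2)

chain = syn.gen_toy_protein(5, 10, topology="helix",
                            residue_types=["LEU", "SER", "VAL"] * 3 + ["LEU"],
                            noise=0.3)
system = build_system(chain, params)
marginals = solve_marginals(system.v1, system.v2, tol=1e-3)
print(f"G_SC = {marginals.free_energy:.3f} kT "
      f"({marginals.iterations} BP iterations)")
for i, rt in enumerate(chain.residue_types[:4]):
    pi = ", ".join(f"{p:.3f}" for p in marginals.p1[i])
    chi1 = params.chi1_of_state[rt][np.argmax(marginals.p1[i])]
    print(f"residue {i} ({rt}): chi1 bin {chi1}, p = [{pi}]")
```

prints

```
G_SC = 1.245 kT (8 BP iterations)
residue 0 (LEU): chi1 bin 0, p = [0.638, 0.176, 0.043, 0.027, 0.097, 0.019]
residue 1 (SER): chi1 bin 0, p = [0.262, 0.694, 0.013, 0.001, 0.012, 0.019]
residue 2 (VAL): chi1 bin 2, p = [0.014, 0.103, 0.000, 0.000, 0.856, 0.027]
residue 3 (LEU): chi1 bin 0, p = [0.135, 0.693, 0.001, 0.003, 0.145, 0.022]
```

`G_SC` is the side-chain free energy of this backbone in units of k_BT;
each residue's vector is its marginal distribution over coarse rotamer
states in the Boltzmann ensemble, and the argmax state maps unambiguously
to a χ1 bin — the quantity scored by `training.chi1_accuracy`.

A command-line interface wraps the same pipeline:

```bash
sidebead gen-fixtures --seed 3 --out-dir fx
sidebead coarse-grain fx/library.json fx/rama.json
sidebead pack fx/protein.pdb fx/params.json
sidebead simulate fx/protein.pdb fx/params.json --n-steps 100
```

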