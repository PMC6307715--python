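"""Shared fixtures: small synthetic libraries, parameters and chains.

Everything is generated programmatically at session start with fixed seeds;
the (phi, psi) grids are kept small (18 x 18, 20-degree spacing) so the
whole suite stays fast.
"""

import numpy as np
import pytest

from sidebead import synthetic as syn
from sidebead.free_energy import solve_marginals
from sidebead.potential import build_system
from sidebead.rotamer import PhiPsiGrid


@pytest.fixture(scope="session")
def grid18():
    return PhiPsiGrid(18, 18)


@pytest.fixture(scope="session")
def small_lib(grid18):
    return syn.gen_rotamer_library(1, n_residue_types=3, states_per_type=6,
                                   grid=grid18)


@pytest.fixture(scope="session")
def rama(grid18):
    return syn.gen_rama_density(0, grid18)


@pytest.fixture(scope="session")
def planted_params(small_lib, rama):
    return syn.gen_parameter_set(small_lib, rama=rama, seed=2)


@pytest.fixture(scope="session")
def chain10(small_lib):
    types = sorted(small_lib.residues)
    return syn.gen_toy_protein(
        5, 10, topology="helix",
        residue_types=[types[i % 3] for i in range(10)], noise=0.3)


@pytest.fixture(scope="session")
def system10(chain10, planted_params):
    return build_system(chain10, planted_params)


@pytest.fixture(scope="session")
def marginals10(system10):
    return solve_marginals(system10.v1, system10.v2, tol=1e-11,
                           max_iter=3000)
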