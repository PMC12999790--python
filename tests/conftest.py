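"""Shared fixtures: a small reference system in the bistable regime.

All fixtures are generated programmatically; nothing is read from disk.
The 10-region uniform all-to-all system with the shipped default kinetic
regime is cheap and sits mid-window in the competition level B, so both
landscapes (hypo- and hyper-acetylated) coexist.
"""

import numpy as np
import pytest

import epitip as et
from epitip import wkb


@pytest.fixture(scope="session")
def bundle():
    """(params, scaling, conn, spec, model) for 10 regions, all-to-all."""
    n = 10
    params, scaling = et.default_bistable(n)
    conn = et.make_all_to_all(n, 1.0 / (n - 1))
    spec = et.spectral_quantities(conn)
    model = et.CGModel(params, spec, scaling)
    return params, scaling, conn, spec, model


@pytest.fixture(scope="session")
def cg_model(bundle):
    return bundle[4]


@pytest.fixture(scope="session")
def cg_fixed_points(cg_model):
    return et.find_fixed_points_model(cg_model, grid_density=20)


@pytest.fixture(scope="session")
def base_robustness(cg_model):
    return wkb.robustness(cg_model, grid_density=16)


@pytest.fixture(scope="session")
def micro_network(bundle):
    params, scaling, conn, _, _ = bundle
    return et.build_reaction_network(params, conn, scaling)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
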