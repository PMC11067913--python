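import numpy as np
import pytest

from biogeodec import (
    ModelFamily,
    ModelParams,
    Phylogeny,
    RangeState,
    build_state_space,
    squamate_backbone_fixture,
)
from biogeodec.synthetic_data import SimConfig, simulate_history, simulate_tree

ALL_MODELS = [
    ModelFamily(fam, jump)
    for fam in ("DEC", "DIVALIKE", "BAYAREALIKE")
    for jump in (False, True)
]


@pytest.fixture(scope="session")
def space2():
    return build_state_space(2, 2, include_null=True, area_names=["A", "B"])


@pytest.fixture(scope="session")
def space3():
    return build_state_space(3, 3, include_null=True, area_names=["A", "B", "C"])


@pytest.fixture(scope="session")
def backbone():
    return squamate_backbone_fixture()


@pytest.fixture
def two_tip_tree():
    return Phylogeny.from_newick("(A:1,B:1);")


def random_instance(seed, max_tips=5, max_areas=3):
    """A small simulated dataset under a seed-determined model."""
    rng = np.random.default_rng(seed)
    n_tips = int(rng.integers(2, max_tips + 1))
    n_areas = int(rng.integers(2, max_areas + 1))
    model = ALL_MODELS[seed % len(ALL_MODELS)]
    params = ModelParams(
        d=float(rng.uniform(0.001, 0.1)),
        e=float(rng.uniform(0.001, 0.05)),
        j=float(rng.uniform(0.0, 0.5)) if model.jump else 0.0,
    )
    tree = simulate_tree(n_tips, 0.1, seed=seed)
    config = SimConfig(
        n_tips=n_tips,
        n_areas=n_areas,
        max_range_size=n_areas,
        model=model,
        params=params,
        seed=seed,
    )
    out = simulate_history(tree, config)
    space = build_state_space(n_areas, n_areas, include_null=True)
    return tree, out, space, model, params
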