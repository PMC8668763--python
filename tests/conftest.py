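import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from streamfd import ScenarioConfig, generate_community_series, generate_trait_pool
from streamfd.trait_space import TraitSpace

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def space_from_coords(points: np.ndarray, taxa=None) -> TraitSpace:
    """Wrap explicit coordinates as a TraitSpace for metric fixtures."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, m = pts.shape
    taxa = tuple(taxa) if taxa is not None else tuple(f"t{i}" for i in range(n))
    return TraitSpace(
        taxa=taxa,
        coords=pts,
        eigenvalues=np.ones(m),
        m=m,
        quality=1.0,
        correction="none",
    )


@pytest.fixture(scope="session")
def default_cfg():
    return ScenarioConfig(seed=11)


@pytest.fixture(scope="session")
def trait_pool(default_cfg):
    return generate_trait_pool(default_cfg)


@pytest.fixture(scope="session")
def community(default_cfg, trait_pool):
    return generate_community_series(default_cfg, trait_pool)


@pytest.fixture(scope="session")
def small_cfg():
    # compact scenario for end-to-end runs
    return ScenarioConfig(
        seed=5, n_taxa=30, richness_start=12.0, n_surveys=12, n_years=16,
        n_outliers=8,
    )


def random_fuzzy_traits(rng, n_taxa=8, group_sizes=(3, 2, 4)):
    """Small random fuzzy trait table for property tests."""
    from streamfd.core_data import fuzzy_scale

    cols, groups = [], {}
    for g, size in enumerate(group_sizes):
        mods = [f"g{g}_m{m}" for m in range(size)]
        groups[f"g{g}"] = mods
        cols.extend(mods)
    raw = pd.DataFrame(
        rng.uniform(0.1, 5.0, size=(n_taxa, len(cols))),
        index=[f"t{i}" for i in range(n_taxa)],
        columns=cols,
    )
    return fuzzy_scale(raw, groups)
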