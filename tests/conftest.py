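import numpy as np
import pytest

import divprior as dp


@pytest.fixture(scope="session")
def world():
    """Mid-sized synthetic world shared by read-only tests."""
    return dp.make_world(seed=11)


@pytest.fixture(scope="session")
def analysis(world):
    """Cleaned + gridded world with the four hotspot surfaces."""
    cleaned, report = dp.clean_records(
        world.occurrences, world.land_polygon(), world.native_ranges()
    )
    pm, overflow = dp.rasterize_presence(cleaned, world.grid)
    tree = dp.load_tree(world.phylogeny)
    sr = dp.species_richness(pm)
    pd_s = dp.phylogenetic_diversity(pm, tree)
    pe_s = dp.phylogenetic_endemism(pm, tree)
    surfaces = {
        "SR": sr,
        "SC_rank": dp.complementarity(pm).sc_rank,
        "WE": dp.weighted_endemism(pm),
        "PA": dp.pa_index(pd_s, pe_s),
    }
    return {
        "world": world,
        "cleaned": cleaned,
        "report": report,
        "pm": pm,
        "overflow": overflow,
        "tree": tree,
        "surfaces": surfaces,
        "sr": sr,
        "pd": pd_s,
        "pe": pe_s,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
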