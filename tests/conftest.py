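import numpy as np
import pandas as pd
import pytest

import phylotank as pt


@pytest.fixture
def three_tip_tree() -> pt.Phylogeny:
    return pt.read_phylogeny("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tree() -> pt.Phylogeny:
    return pt.read_phylogeny("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_meta(capacities, predator_present=None, **extra) -> pt.BromeliadMeta:
    ids = [f"b{i + 1}" for i in range(len(capacities))]
    cols = {"capacity_ml": list(capacities)}
    if predator_present is not None:
        cols["predator_present"] = list(predator_present)
    cols.update(extra)
    return pt.BromeliadMeta(pd.DataFrame(cols, index=ids))


def make_table(counts, species, role="colonization", introduced=None):
    ids = [f"b{i + 1}" for i in range(len(counts))]
    df = pd.DataFrame(counts, index=ids, columns=species)
    intro = (
        pd.DataFrame(introduced, index=ids, columns=species)
        if introduced is not None
        else None
    )
    return pt.CommunityTable(df, role, intro)


@pytest.fixture(scope="session")
def null_study() -> pt.SimulatedStudy:
    """One synthetic study with every effect size zero."""
    return pt.simulate_study(pt.SimulationConfig(seed=11))
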