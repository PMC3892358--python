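import numpy as np
import pandas as pd
import pytest

import cladecomm as cc
from cladecomm.communities import CommunityMatrix, PlotMetadata

BASIC_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def basic_tree():
    return cc.read_tree(BASIC_NEWICK)


@pytest.fixture
def yule50():
    return cc.simulate_yule_tree(50, 1.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def presence_matrix(pres: np.ndarray, species, plot_ids=None) -> CommunityMatrix:
    """Build a CommunityMatrix from a boolean presence array (cover 10%)."""
    pres = np.asarray(pres, dtype=bool)
    if plot_ids is None:
        plot_ids = [f"p{i + 1}" for i in range(pres.shape[0])]
    return CommunityMatrix(
        pd.DataFrame(pres.astype(float) * 10.0, index=plot_ids,
                     columns=list(species))
    )


def random_presence(rng, n_plots, species, p=0.3) -> CommunityMatrix:
    """Random presence matrix in which every species occurs at least once."""
    pres = rng.random((n_plots, len(species))) < p
    for j in np.flatnonzero(pres.sum(axis=0) == 0):
        pres[rng.integers(n_plots), j] = True
    return presence_matrix(pres, species)


def metadata_for(cm: CommunityMatrix, elevations) -> PlotMetadata:
    return PlotMetadata(
        pd.DataFrame({"elevation": list(elevations)}, index=list(cm.plot_ids))
    )
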