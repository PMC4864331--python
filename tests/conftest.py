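import numpy as np
import pandas as pd
import pytest

import urbfilter as uf


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down two-city design used where full size is unnecessary."""
    return uf.GeneratorConfig(
        n_cities=2, n_urban_cells=14, n_periurban_cells=8, n_species=12, seed=0
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return uf.generate_study(small_config)


@pytest.fixture()
def toy_survey():
    """3 cells x 2 species with hand-checkable counts."""
    return pd.DataFrame(
        [[1, 0], [2, 2], [0, 3]],
        index=["c1", "c2", "c3"],
        columns=["sp1", "sp2"],
    )


@pytest.fixture()
def toy_tables(toy_survey):
    cells = pd.DataFrame(
        {
            "city": ["t", "t", "t"],
            "habitat": ["urban", "urban", "periurban"],
            "veg_cover": [0.2, 0.3, 0.7],
        },
        index=toy_survey.index,
    )
    traits = pd.DataFrame(
        {
            "diet_guild": ["granivore", "insectivore"],
            "habitat_guild": ["open", "forest"],
            "origin": ["exotic", "native"],
        },
        index=toy_survey.columns,
    )
    return toy_survey, cells, traits
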