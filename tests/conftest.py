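import numpy as np
import pandas as pd
import pytest

import precog as pg


@pytest.fixture(scope="session")
def crossed_design():
    """Two-facet fully crossed design: person x task x rater."""
    return pg.parse_design("p x t x r")


@pytest.fixture(scope="session")
def nested_design():
    """Multi-site assessment: persons nested in sites, crossed forms/stations."""
    return pg.parse_design("p:s x f x st")


@pytest.fixture
def hand_table():
    """The 2x2 person-by-item table [[1,2],[3,4]] with hand-computable ANOVA."""
    return pd.DataFrame(
        {"p": [0, 0, 1, 1], "i": [0, 1, 0, 1], "score": [1.0, 2.0, 3.0, 4.0]}
    )


@pytest.fixture
def pi_design():
    return pg.parse_design("p x i")


def random_balanced_table(design, sizes, seed, scale=1.0):
    """An arbitrary (not model-based) balanced table for identity checks."""
    rng = np.random.default_rng(seed)
    names = list(design.facet_names)
    index = pd.MultiIndex.from_product(
        [np.arange(sizes[n]) for n in names], names=names
    ).to_frame(index=False)
    index["score"] = rng.normal(0.0, scale, size=len(index)) + rng.uniform(-2, 2)
    return index
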