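import numpy as np
import pandas as pd
import pytest

from phylofunc import TraitSpec, TraitTable, parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def three_tip_tree():
    return parse_newick("((a:1,b:1):1,c:2);")


@pytest.fixture
def balanced_four():
    return parse_newick("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture
def conflicting_four():
    return parse_newick("((a:1,c:1):1,(b:1,d:1):1);")


@pytest.fixture
def mixed_table():
    """Three species, three mixed traits, one missing cell (hand-checkable)."""
    df = pd.DataFrame(
        {
            "size": [0.0, 5.0, 10.0],
            "color": ["red", "blue", np.nan],
            "social": ["yes", "no", "no"],
        },
        index=pd.Index(["s1", "s2", "s3"], name="species"),
    )
    schema = {
        "size": TraitSpec("quantitative", "trophic"),
        "color": TraitSpec("categorical", "habitat"),
        "social": TraitSpec("binary", "behavior"),
    }
    return TraitTable(df, schema)
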