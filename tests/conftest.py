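import copy

import pytest

from mddcea import paper_base_case


@pytest.fixture
def base_config():
    """A fresh packaged base-case configuration (mutable per test)."""
    return paper_base_case()


@pytest.fixture
def two_arm_config(base_config):
    """Base case restricted to agomelatine + venlafaxine (fast pairwise runs)."""
    config = copy.deepcopy(base_config)
    config.treatments = [t for t in config.treatments if t.name in ("Agomelatine", "Venlafaxine")]
    return config.validate()
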