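import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from phylodup import studydata, treekit as tk


@pytest.fixture
def groups():
    return tk.default_group_map()


@pytest.fixture
def printed_topologies():
    """The seven collapsed group-level marker topologies of the bundled
    example panel, parsed."""
    return {
        name: tk.parse_newick(nwk)
        for name, nwk in studydata.GROUP_TOPOLOGIES.items()
    }


@pytest.fixture
def rnd():
    return random.Random(20240917)
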