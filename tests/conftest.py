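import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from orthoscope import synth  # noqa: E402


@pytest.fixture(scope="session")
def planted_genome():
    """Seeded synthetic genome with one planted array + anti-repeat."""
    return synth.make_genome_with_array(1)


@pytest.fixture(scope="session")
def amplicon_ref():
    """Synthetic amplicon with adenines at the profiled protospacer positions."""
    return synth.make_amplicon_ref(7, substrate_positions=(7, 9, 11, 14))


@pytest.fixture(scope="session")
def ortholog_panel():
    return synth.make_ortholog_panel(11)
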