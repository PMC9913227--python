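import pytest

from mitorearr import datasets
from mitorearr.gene_order import canonical_vertebrate_order
from mitorearr.synthetic import GeneratorConfig, generate_mitogenome
from mitorearr.tdrl import TDRLEvent


@pytest.fixture(scope="session")
def evermanni():
    return datasets.load_evermanni()


@pytest.fixture(scope="session")
def erabo():
    return datasets.load_erabo()


@pytest.fixture(scope="session")
def canonical():
    return canonical_vertebrate_order()


@pytest.fixture(scope="session")
def duplication_event(canonical):
    """The snake-eel rearrangement: duplicate the ND6-E-Cytb-T-P-CR block,
    keep Cytb/T from the first copy, ND6/E/P from the second, CR from both."""
    block = canonical.anchored()[32:38]
    return TDRLEvent(
        block_start=32,
        block=block,
        retention=("second", "second", "first", "first", "second", "both"),
    )


@pytest.fixture(scope="session")
def synthetic_default():
    return generate_mitogenome(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def synthetic_rearranged(duplication_event):
    return generate_mitogenome(GeneratorConfig(seed=7, tdrl_event=duplication_event))
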