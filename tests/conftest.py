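import numpy as np
import pytest

from specieskg.curation import select_recommended
from specieskg.fixtures import METHYL_ACETATE_BOILING_STRINGS
from specieskg.model import Provenance
from specieskg.quantities import records_from_strings


@pytest.fixture
def provenance():
    return Provenance(label="test source", locator="https://example.org/rec/1")


@pytest.fixture
def methyl_acetate_records(provenance):
    """The five canonical boiling-point records of the curation walk-through."""
    records, discarded = records_from_strings(
        "BoilingPoint", [(s, provenance) for s in METHYL_ACETATE_BOILING_STRINGS]
    )
    assert not discarded
    return records


@pytest.fixture
def methyl_acetate_recommended(methyl_acetate_records):
    return select_recommended(methyl_acetate_records)


@pytest.fixture
def rng():
    return np.random.default_rng(20230401)
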