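import numpy as np
import pytest

from barcodegap import simulate as sim
from barcodegap.seqio import BarcodeAlignment, SequenceRecord


@pytest.fixture(scope="session")
def well_separated_ds():
    return sim.scenario("well_separated", seed=1)


@pytest.fixture()
def small_alignment():
    """Two clean species plus a singleton, hand-written."""
    recs = [
        SequenceRecord("A1", "Alpha", "ACGTACGTAC"),
        SequenceRecord("A2", "Alpha", "ACGTACGTAT"),
        SequenceRecord("B1", "Beta", "TGCATGCATG"),
        SequenceRecord("B2", "Beta", "TGCATGCATC"),
        SequenceRecord("C1", "Gamma", "GGGGCCCCAA"),
    ]
    return BarcodeAlignment(records=recs)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
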