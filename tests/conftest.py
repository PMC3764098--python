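import numpy as np
import pytest

from dldm import sim


@pytest.fixture
def small_locus():
    """40-cytosine amplicon with no GATC site (4-nt CAAT repeat)."""
    return sim.SimulatedLocus.from_sequence("amp40", "CAAT" * 40)


@pytest.fixture
def gatc_locus():
    """Short locus with two planted GATC sites and assorted cytosines."""
    return sim.SimulatedLocus.from_sequence("gatc2", "ACCAGATCTTCCAAGATCACCT")


def make_allele(locus, state, label=None, allele_id="a0"):
    """Epiallele with an explicit state vector; label inferred if omitted."""
    state = np.asarray(state, dtype=np.uint8)
    if label is None:
        label = "on" if state.any() else "off"
    return sim.Epiallele(locus=locus, state=state, label=label, allele_id=allele_id)
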