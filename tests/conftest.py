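import numpy as np
import pytest
from hypothesis import settings

from xlmap.peptide_chem import CrossLinkedPair, Peptide, Provenance, with_cam

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fig_pair() -> CrossLinkedPair:
    """The worked-example pair: a 21-mer (CAM on both Cys, linked at K13)
    bridged to TETTGEKGK (linked at the internal K7)."""
    pep_a = with_cam("YCLFGNNVTLANKFESCSVPR", Provenance("SGC_ALPHA", 594, 614))
    pep_b = Peptide("TETTGEKGK", provenance=Provenance("SGC_BETA", 553, 561))
    return CrossLinkedPair(pep_a, pep_b, 13, 7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20150923)
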