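import numpy as np
import pytest
from hypothesis import settings

from mratlas import HarmonisedInstrument, LdTable, SnpAssociation

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def snp(vid, beta, se=0.01, p=1e-10, ea="A", oa="G", eaf=0.3, n=100_000.0):
    return SnpAssociation(
        variant_id=vid, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, pvalue=p, eaf=eaf, n=n,
    )


def inst(vid, beta_x, beta_y, se_x=0.01, se_y=0.05):
    return HarmonisedInstrument(
        variant_id=vid, beta_x=beta_x, se_x=se_x, beta_y=beta_y, se_y=se_y
    )


@pytest.fixture
def three_instruments():
    """The hand-checked IVW fixture: beta 0.3, Q 14, I2 6/7."""
    return [
        inst("rs1", 1.0, 0.1, se_y=0.1),
        inst("rs2", 1.0, 0.2, se_y=0.1),
        inst("rs3", 1.0, 0.6, se_y=0.1),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
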