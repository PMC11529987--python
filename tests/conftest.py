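import pytest

from tcrspec import Peptide

DECAMER = "VVVGAVGVGK"
NONAMER = "VVGAVGVGK"


@pytest.fixture
def decamer() -> Peptide:
    """KRAS G12V decamer epitope (residues 7-16, V at the codon-12 site)."""
    return Peptide(DECAMER, name="7-16V")


@pytest.fixture
def nonamer() -> Peptide:
    """KRAS G12V nonamer epitope (residues 8-16)."""
    return Peptide(NONAMER, name="8-16V")
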