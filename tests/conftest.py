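import numpy as np
import pytest

from histoform.fragmatch import SpectrumPeaks
from histoform.masscore import Proteoform, fragment_ladder

# H4-like N-terminal tail toy used across modules (K at 5, 8, 12, 16)
H4_TOY = "SGRGKGGKGLGKGGAKR"

# QC synthetic peptide standard from the bottom-up workflow
QC_PARENT = "GVKFRGSTGGKAPRGKAPATSGMVGPHR"

# 50-residue histone-like sequence for recovery tests (K-rich N-tail)
FIFTY_MER = "SGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLA"


@pytest.fixture
def h4_toy():
    return H4_TOY


@pytest.fixture
def qc_parent():
    return QC_PARENT


@pytest.fixture
def fifty_mer():
    return FIFTY_MER


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def noiseless_spectrum(p: Proteoform, series=("c", "zdot")) -> SpectrumPeaks:
    """Complete, exact fragment ladder as a neutral-mass spectrum."""
    ladder = fragment_ladder(p, series)
    return SpectrumPeaks(
        tuple(f.neutral_mass for f in ladder),
        tuple(100.0 for _ in ladder),
        "neutral",
    )
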