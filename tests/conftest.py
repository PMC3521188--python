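import pytest

from cleavesnp import (
    DNA,
    Alphabet,
    SpectraCollection,
    parse_compomer,
)

#: Reference sequence used throughout the worked examples.
EX1_SEQ = "ACATGCTACATTA"

AT = Alphabet("AT")
GT = Alphabet("GT")


@pytest.fixture(scope="session")
def at_alphabet():
    return AT


@pytest.fixture(scope="session")
def example1_seq():
    return EX1_SEQ


@pytest.fixture(scope="session")
def example4_spectra():
    """Two-letter instance: s = ATAAT with C_A = {A0T1, A0T2}, C_T = {A0T0, A1T0}."""
    return SpectraCollection.from_counts(AT, {"A": [(0, 1), (0, 2)], "T": [(0, 0), (1, 0)]})


@pytest.fixture(scope="session")
def example6_spectra():
    """The four-spectrum collection of the compatibility worked example."""
    return SpectraCollection(
        DNA,
        {
            "A": [parse_compomer(t) for t in ["A0C1G0T0", "A0C1G1T2", "A0C0G0T2"]],
            "C": [parse_compomer(t) for t in ["A1C0G0T0", "A1C0G1T1", "A1C0G0T1", "A2C0G0T2"]],
            "G": [parse_compomer(t) for t in ["A2C1G0T1", "A3C2G0T3"]],
            "T": [parse_compomer(t) for t in ["A2C1G0T0", "A0C1G1T0", "A0C0G0T0", "A1C0G0T0"]],
        },
    )
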