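import pytest

import kirpop as kp


@pytest.fixture(scope="session")
def h7():
    """Seven motif-level reference haplotypes (no 3DS1-deletion haplotype)."""
    return kp.build_reference_haplotypes(include_deletion=False,
                                         expand_2DS3S5=False)


@pytest.fixture(scope="session")
def h8():
    """Amended motif-level input set: seven haplotypes + 3DS1 deletion."""
    return kp.build_reference_haplotypes(include_deletion=True,
                                         expand_2DS3S5=False)


@pytest.fixture(scope="session")
def h18(h8):
    """Marker-level catalog: every 2DS3S5 slot assigned."""
    return h8.expand()


@pytest.fixture(scope="session")
def hgdp_meta():
    return kp.load_hgdp_metadata()


@pytest.fixture(scope="session")
def hgdp_carriers():
    return kp.load_hgdp_frequencies("carrier")


@pytest.fixture(scope="session")
def hgdp_genes():
    return kp.load_hgdp_frequencies("gene")


@pytest.fixture(scope="session")
def worldwide_truth():
    """A realistic worldwide-like haplotype frequency vector (motif level),
    with the concrete variants used for simulation (2DS3 centromeric, 2DS5
    telomeric, the pattern typical outside Africa)."""
    parents = {"cA-tA": 0.54, "cA-tB": 0.13, "cB1-tA": 0.12, "cB1-tB": 0.08,
               "cB2-tA": 0.05, "cB2-tB": 0.04, "cB3-tA": 0.02,
               "cB1-tBdel": 0.02}
    variants = {"cA-tA": "cA-tA", "cA-tB": "cA-tB.2DS5",
                "cB1-tA": "cB1-tA.2DS3", "cB1-tB": "cB1-tB.2DS3.2DS5",
                "cB2-tA": "cB2-tA", "cB2-tB": "cB2-tB.2DS5",
                "cB3-tA": "cB3-tA.2DS3",
                "cB1-tBdel": "cB1-tBdel.2DS3.2DS5"}
    return parents, {variants[k]: v for k, v in parents.items()}
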