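import numpy as np
import pytest

from gvpid import synthetic_data as sd
from gvpid.variant_reference import ProteinRecord, SnpRecord


@pytest.fixture(scope="session")
def toy_proteome():
    return [
        ProteinRecord("P1", "KRTA", "MAKDFGHRPSTKWYCEK"),
        ProteinRecord("P2", "KRTB", "GGKLLNRAAAKDDE"),
    ]


@pytest.fixture(scope="session")
def toy_snps(toy_proteome):
    return [
        SnpRecord(
            rs_id="rs1", gene="KRTA", protein_accession="P1", protein_position=5,
            ref_aa="F", alt_aa="L", ref_nuc="C", alt_nuc="A",
            allele_freq={"EUR": 0.10, "AFR": 0.30},
        ),
        SnpRecord(
            rs_id="rs2", gene="KRTB", protein_accession="P2", protein_position=6,
            ref_aa="N", alt_aa="S", ref_nuc="A", alt_nuc="G",
            allele_freq={"EUR": 0.25, "AFR": 0.05},
        ),
        SnpRecord(  # rare everywhere: excluded from the variant database
            rs_id="rs3", gene="KRTB", protein_accession="P2", protein_position=12,
            ref_aa="D", alt_aa="E", ref_nuc="T", alt_nuc="G",
            allele_freq={"EUR": 0.001, "AFR": 0.002},
        ),
    ]


@pytest.fixture(scope="session")
def study():
    """Default toy study including decoy loci, shared across tests."""
    return sd.build_study(sd.default_config(seed=11, with_decoy_loci=True))


@pytest.fixture(scope="session")
def clean_study():
    """Perfect-detection study: sensitivity 1, false-positive rate 0."""
    return sd.build_study(
        sd.default_config(
            seed=13, detection_sensitivity=1.0, false_positive_rate=0.0
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
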