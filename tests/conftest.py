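import numpy as np
import pytest

from varcontext.io import CdsRecord, VariantRecord, VariantSet
from varcontext.simulate import SyntheticConfig, simulate_dataset


@pytest.fixture
def mini_cds() -> CdsRecord:
    # MKTAYIAKQR followed by a stop
    seq = "ATGAAAACCGCTTACATTGCCAAACAGCGGTAA"
    return CdsRecord.from_sequence("G1", "TEST1", seq)


@pytest.fixture
def mini_variant(mini_cds) -> VariantRecord:
    return VariantRecord(
        gene_id="G1", protein_pos=5, ref_aa="Y", alt_aa="C",
        carrier_count=30, source="allofus", var_class="disease",
    )


@pytest.fixture
def mini_variant_set(mini_variant) -> VariantSet:
    benign = VariantRecord(
        gene_id="G1", protein_pos=7, ref_aa="A", alt_aa="T",
        carrier_count=25, source="cosmic", var_class="benign",
    )
    return VariantSet(variants=[mini_variant, benign])


@pytest.fixture(scope="session")
def default_dataset():
    """The study-condition dataset: GATC in every disease window, none benign."""
    return simulate_dataset(SyntheticConfig(seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
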