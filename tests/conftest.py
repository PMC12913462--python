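import numpy as np
import pytest

from peptigen.records_io import Dataset, PeptideHlaRecord


def make_record(
    record_id="r1",
    peptide="SIINFEKLA",
    allele="HLA-A*02:01",
    label="immunogenic",
    **kwargs,
):
    return PeptideHlaRecord(
        record_id=record_id,
        mutant_peptide=peptide,
        hla_allele=allele,
        label=label,
        **kwargs,
    )


@pytest.fixture
def toy_dataset():
    """Six curatable records over two alleles and both classes."""
    peptides = [
        ("SIINFEKLA", "immunogenic"),
        ("KEEDLFRSA", "immunogenic"),
        ("RDDEAGHIK", "immunogenic"),
        ("LLVAGSTPW", "non_immunogenic"),
        ("AVLLGSTMNP", "non_immunogenic"),
        ("TPWLLVAG", "non_immunogenic"),
    ]
    records = [
        make_record(f"r{i}", pep, "HLA-A*02:01" if i % 2 else "HLA-B*07:02", lab)
        for i, (pep, lab) in enumerate(peptides)
    ]
    return Dataset(records=records, role="train")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
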