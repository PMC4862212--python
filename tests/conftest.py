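import pandas as pd
import pytest


def make_psm(rows):
    """Build a PSM table from (spectrum, peptide, accessions, sample, condition, rep)."""
    return pd.DataFrame(
        [
            {
                "spectrum_id": spec,
                "peptide": pep,
                "accessions": tuple(sorted(accs)),
                "sample_id": sample,
                "condition": cond,
                "replicate": rep,
            }
            for spec, pep, accs, sample, cond, rep in rows
        ],
        columns=["spectrum_id", "peptide", "accessions", "sample_id", "condition", "replicate"],
    )


@pytest.fixture
def psm_factory():
    return make_psm


@pytest.fixture
def two_protein_db():
    """Two proteins sharing the peptide GGGGGGGGGGK; each has unique peptides."""
    return {
        "A": "AAAAAAAAAAKGGGGGGGGGGKCCCCCCCCCCK",
        "B": "DDDDDDDDDDKGGGGGGGGGGKEEEEEEEEEEK",
    }
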