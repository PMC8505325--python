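import numpy as np
import pandas as pd
import pytest

from cyt.catalogs import fixture_catalog
from cyt.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def catalog():
    return fixture_catalog()


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """One 24-sample cohort shared across tests (seed fixed)."""
    config = CohortConfig(n_samples=24, seed=11)
    return config, generate_cohort(config, catalog)


def random_mutation_table(rng, n, chrom="chr1", sample="S1", span=50_000_000):
    """Uniform random SNVs for oracle comparisons."""
    pos = np.sort(rng.integers(1, span, size=n))
    refs = rng.choice(list("CT"), size=n)
    alts = np.where(refs == "C", "T", "C")
    return pd.DataFrame({
        "Tumor_Sample_Barcode": sample,
        "Chromosome": chrom,
        "Start_Position": pos,
        "Reference_Allele": refs,
        "Tumor_Seq_Allele2": alts,
        "ref_count": 50,
        "alt_count": 30,
        "trinucleotide_context": ["A" + r + "A" for r in refs],
    })
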