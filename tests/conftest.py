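import logging

import pandas as pd
import pytest

from aeiscan import GenotypeMatrix, quantify, simulate_cohort, stanley_config

# simulator warnings about occasional CNV flags are expected in bulk runs
logging.getLogger("aeiscan").setLevel(logging.ERROR)
logging.getLogger("aeiscan.aei_quant").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def stanley_tables():
    """One full synthetic brain-bank cohort (seed 1)."""
    return simulate_cohort(stanley_config(seed=1))


@pytest.fixture(scope="session")
def stanley_aei(stanley_tables):
    aei, subjects = quantify(stanley_tables.measurements)
    return aei, subjects


@pytest.fixture(scope="session")
def candidate_matrix(stanley_tables):
    """Genotypes restricted to the scanned (non-marker) panel."""
    roles = stanley_tables.genotypes.metadata["role"]
    cand = [s for s in stanley_tables.genotypes.snp_ids if roles[s] != "marker"]
    return GenotypeMatrix(stanley_tables.genotypes.dosage[cand])


@pytest.fixture(scope="session")
def published_scan_cohort():
    """Genotype/category reconstruction of the published AEI scan cohort.

    68 of the 70 scanned subjects are recoverable from the printed
    genotype-by-category counts of the candidate variant: homozygotes
    32/16/2 and heterozygotes 3/6/9 across categories 0/1/2.
    """
    dosages, categories = [], []
    for dosage, counts in [(0, (30, 14, 2)), (1, (3, 6, 9)), (2, (2, 2, 0))]:
        for cat, n in zip((0, 1, 2), counts):
            dosages += [dosage] * n
            categories += [cat] * n
    subject_ids = [f"P{i:02d}" for i in range(len(dosages))]
    genotypes = GenotypeMatrix(
        pd.DataFrame({"candidate": [float(d) for d in dosages]},
                     index=pd.Index(subject_ids, name="subject_id"))
    )
    aei = pd.DataFrame({"subject_id": subject_ids, "category": categories})
    return genotypes, aei
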