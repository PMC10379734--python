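import numpy as np
import pandas as pd
import pytest

from polyscore import GenotypePanel, VariantRecord, make_study_cohort

BASES = "ACGT"


@pytest.fixture(scope="session")
def study_bundle():
    """The study-like synthetic bundle: 32 variants x 1065 individuals."""
    return make_study_cohort(seed=1)


def random_panel(rng: np.random.Generator, n: int, m: int, missing_rate: float = 0.05) -> GenotypePanel:
    """A random dosage panel with arbitrary allele pairs and missingness."""
    variants = []
    for j in range(m):
        ea, nea = rng.choice(list(BASES), size=2, replace=False)
        variants.append(
            VariantRecord(
                variant_id=f"rs{j + 1:04d}",
                locus_label=f"G{j // 3}",
                chrom=str(rng.integers(1, 23)),
                pos=int(rng.integers(1, 10**8)),
                effect_allele=ea,
                non_effect_allele=nea,
            )
        )
    dosages = rng.integers(0, 3, size=(n, m)).astype(float)
    if missing_rate > 0:
        dosages[rng.random((n, m)) < missing_rate] = np.nan
    return GenotypePanel(variants=variants, dosages=dosages, sample_ids=[f"I{i:04d}" for i in range(n)])


def tiny_cohort(rng: np.random.Generator, n: int, depression=None) -> pd.DataFrame:
    """A minimal valid cohort table with random covariates."""
    from polyscore import categorize_pbi

    df = pd.DataFrame(
        {
            "sample_id": [f"I{i:04d}" for i in range(n)],
            "depression": rng.integers(0, 30, size=n) if depression is None else depression,
            "sex": rng.choice(["man", "woman"], size=n),
            "age": rng.uniform(18, 25, size=n),
            "ethnicity": rng.choice(["Russian", "Tatar", "Udmurt", "mixed"], size=n),
            "income": rng.choice(["lower-than-average", "average-and-higher"], size=n),
            "full_family": rng.integers(0, 2, size=n),
            "maltreatment": rng.integers(0, 2, size=n),
            "maternal_care": rng.integers(0, 37, size=n),
            "maternal_protection": rng.integers(0, 40, size=n),
            "paternal_care": rng.integers(0, 37, size=n),
            "paternal_protection": rng.integers(0, 40, size=n),
        }
    )
    return categorize_pbi(df)
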