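import numpy as np
import pandas as pd
import pytest

from polyhazard.synthetic_cohort import (CohortConfig, impute_age_at_onset,
                                         simulate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small cohort: 1200 individuals x 80 SNPs, moderate LD,
    a handful of causal SNPs, onset ages imputed."""
    cfg = CohortConfig(n_individuals=1200, n_snps=80, n_blocks=20,
                       n_causal=8, causal_effect_sd=0.3,
                       birth_cohort_fraction=0.3, seed=42)
    cohort = simulate_cohort(cfg)
    cohort.phenotype = impute_age_at_onset(cohort.phenotype)
    return cohort


@pytest.fixture()
def toy_phenotype():
    """Six-row phenotype table exercising imputation and age filtering."""
    return pd.DataFrame({
        "id": [f"i{k}" for k in range(6)],
        "status": ["case", "case", "case", "control", "control", "control"],
        "age_at_onset": [50.0, 55.0, 60.0, np.nan, np.nan, np.nan],
        "age_last_assessment": [52.0, 58.0, 70.0, 45.0, 55.0, 70.0],
        "sex": [0, 1, 0, 1, 0, 1],
        "pc1": 0.0, "pc2": 0.0, "pc3": 0.0,
        "apoe_e2_count": [0, 1, 0, 0, 2, 0],
        "apoe_e4_count": [1, 0, 0, 2, 0, 0],
    })
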