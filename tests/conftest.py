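import numpy as np
import pandas as pd
import pytest

from compositemr.cohort import CohortTable
from compositemr.plink import FAM_COLUMNS, GenotypeMatrix


def make_fam(iids, fids=None):
    return pd.DataFrame({
        "fid": fids if fids is not None else list(iids),
        "iid": list(iids), "pat": "0", "mat": "0", "sex": 1, "pheno": -9,
    })[FAM_COLUMNS]


def make_genotypes(dosages, ids=None, genes=None):
    """GenotypeMatrix from a raw dosage array with minimal metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ids = ids or [f"snp{j}" for j in range(m)]
    with np.errstate(invalid="ignore"):
        maf = np.nanmean(dosages, axis=0) / 2.0
    variants = pd.DataFrame({
        "chrom": "1", "id": ids, "cm": 0, "pos": np.arange(1, m + 1),
        "a1": "A", "a2": "G", "gene": genes or [""] * m, "maf": maf,
    })
    return GenotypeMatrix(dosages, variants, make_fam([f"ind{i}" for i in range(n)]))


def make_derived_cohort(exposure, outcome, mean_bmi=None, family_id=None, **covariate_overrides):
    """A CohortTable already carrying derived variables, for estimator tests."""
    n = len(exposure)
    data = pd.DataFrame({
        "iid": [f"ind{i}" for i in range(n)],
        "family_id": family_id if family_id is not None else [f"f{i}" for i in range(n)],
        "sex": 1, "race": 1, "education": 1, "smoking": 0, "comorbidity": 0,
        "field_center": 1, "pc1": 0.0, "pc2": 0.0,
        "enrollment_age": 75.0, "event_age": 86.0, "death": 0,
        "mean_bmi": mean_bmi if mean_bmi is not None else np.where(np.asarray(exposure) == 1, 27.0, 22.0),
        "exposure": np.asarray(exposure, dtype=float),
        "outcome": np.asarray(outcome, dtype=float),
        "excluded": False, "exclusion_reason": "",
    })
    for k, v in covariate_overrides.items():
        data[k] = v
    return CohortTable(data, pd.DataFrame({"iid": [], "age": [], "bmi": []}))


@pytest.fixture(scope="session")
def demo_analysis():
    """One small simulated cohort with derived variables, shared across tests."""
    from compositemr.cohort import derive_variables
    from compositemr.simulate import SimulationConfig, simulate_cohort

    g, cohort = simulate_cohort(SimulationConfig(n_individuals=2000, n_snps_per_gene=2, seed=42))
    return g, derive_variables(cohort)
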