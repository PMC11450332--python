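"""Per-individual phenotype/covariate table and derived analysis variables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: categorical covariates with their integer codings
#: sex: 1 male, 2 female; race: 1 white, 2 black, 3 other;
#: education: 0 below-HS, 1 HS, 2 above-HS; smoking: 1 ever, 0 never;
#: comorbidity (cancer/diabetes/CVD): 1 yes, 0 no; field_center: 1 US, 2 Denmark
CATEGORICAL_COVARIATES = ["sex", "race", "education", "smoking", "comorbidity", "field_center"]
CONTINUOUS_COVARIATES = ["pc1", "pc2"]
COVARIATES = CATEGORICAL_COVARIATES + CONTINUOUS_COVARIATES

BASE_COLUMNS = (
    ["iid", "family_id"] + COVARIATES + ["enrollment_age", "event_age", "death"]
)
DERIVED_COLUMNS = ["mean_bmi", "exposure", "outcome", "excluded", "exclusion_reason"]

BMI_WINDOW = (75.0, 85.0)      # closed age window for BMI averaging, years
BMI_NORMAL = (18.5, 25.0)      # [18.5, 25): normal weight
BMI_OVERWEIGHT = (25.0, 30.0)  # [25, 30): overweight
OUTCOME_AGE = 85.0             # survival past this age is the outcome


@dataclass
class CohortTable:
    """Cohort phenotypes: one row per individual plus long-format BMI measures.

    ``data`` holds covariates and (after :func:`derive_variables`) the derived
    exposure/outcome columns; ``bmi`` has columns ``iid, age, bmi`` with one
    row per BMI measurement.
    """

    data: pd.DataFrame
    bmi: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["iid", "age", "bmi"]))

    def __post_init__(self) -> None:
        missing = [c for c in BASE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if self.data["iid"].duplicated().any():
            raise ValueError("duplicate individual ids in cohort table")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def derived(self) -> bool:
        return "excluded" in self.data.columns

    @property
    def retained(self) -> pd.DataFrame:
        """Individuals with defined exposure, outcome and complete covariates."""
        if not self.derived:
            raise ValueError("derive_variables has not been run on this cohort")
        return self.data.loc[~self.data["excluded"]].reset_index(drop=True)


def mean_bmi_in_window(cohort: CohortTable) -> pd.Series:
    """Arithmetic mean of BMI measures at ages in [75, 85], indexed by iid."""
    lo, hi = BMI_WINDOW
    m = cohort.bmi
    inwin = m[(m["age"] >= lo) & (m["age"] <= hi)]
    return inwin.groupby("iid")["bmi"].mean()


def derive_variables(cohort: CohortTable) -> CohortTable:
    """Compute mean BMI over ages 75-85, exposure, outcome and exclusions.

    Exposure is 1 for mean BMI in [25, 30) ("overweight"), 0 for [18.5, 25)
    ("normal weight") and undefined otherwise. Outcome is 1 iff lifespan >= 85
    years (died at >= 85, or censored alive at >= 85), 0 iff died before 85;
    individuals censored alive before 85 have no determinable outcome.
    Individuals are flagged EXCLUDED with a reason code rather than dropped:
    ``no_bmi_in_window``, ``bmi_out_of_range``, ``outcome_undetermined`` or
    ``missing_covariate``. Contradictory records (death before enrollment)
    raise.
    """
    df = cohort.data.copy()
    contradictory = (df["death"] == 1) & (df["event_age"] < df["enrollment_age"])
    if contradictory.any():
        bad = df.loc[contradictory, "iid"].iloc[0]
        raise ValueError(f"individual {bad!r}: death age precedes enrollment age")

    mbmi = mean_bmi_in_window(cohort)
    df["mean_bmi"] = df["iid"].map(mbmi)

    exposure = np.full(len(df), np.nan)
    exposure[(df["mean_bmi"] >= BMI_OVERWEIGHT[0]) & (df["mean_bmi"] < BMI_OVERWEIGHT[1])] = 1.0
    exposure[(df["mean_bmi"] >= BMI_NORMAL[0]) & (df["mean_bmi"] < BMI_NORMAL[1])] = 0.0
    df["exposure"] = exposure

    outcome = np.full(len(df), np.nan)
    outcome[df["event_age"] >= OUTCOME_AGE] = 1.0
    outcome[(df["death"] == 1) & (df["event_age"] < OUTCOME_AGE)] = 0.0
    df["outcome"] = outcome

    reason = np.full(len(df), "", dtype=object)
    covar_missing = df[COVARIATES].isna().any(axis=1) | df[["enrollment_age", "event_age", "death"]].isna().any(axis=1)
    reason[covar_missing.to_numpy()] = "missing_covariate"
    reason[np.isnan(outcome)] = "outcome_undetermined"
    reason[(~df["mean_bmi"].isna()) & np.isnan(exposure)] = "bmi_out_of_range"
    reason[df["mean_bmi"].isna().to_numpy()] = "no_bmi_in_window"
    df["exclusion_reason"] = reason
    df["excluded"] = reason != ""
    return CohortTable(df, cohort.bmi)


def write_phenotypes(cohort: CohortTable, path_prefix: str) -> None:
    """Write the per-individual table and long BMI measures as TSV."""
    cols = BASE_COLUMNS + [c for c in DERIVED_COLUMNS if c in cohort.data.columns]
    cohort.data[cols].to_csv(path_prefix + ".pheno.tsv", sep="\t", index=False)
    cohort.bmi.to_csv(path_prefix + ".bmi.tsv", sep="\t", index=False)


def read_phenotypes(path_prefix: str) -> CohortTable:
    """Read the TSV pair written by :func:`write_phenotypes`."""
    data = pd.read_csv(path_prefix + ".pheno.tsv", sep="\t", dtype={"iid": str, "family_id": str})
    bmi = pd.read_csv(path_prefix + ".bmi.tsv", sep="\t", dtype={"iid": str})
    if "exclusion_reason" in data.columns:
        data["exclusion_reason"] = data["exclusion_reason"].fillna("")
    return CohortTable(data, bmi)
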