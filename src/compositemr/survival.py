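"""Descriptive cohort characteristics and left-truncated Kaplan-Meier curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import CohortTable

SEX_LABELS = {1: "male", 2: "female"}
RACE_LABELS = {1: "white", 2: "black", 3: "other"}

ENTRY_AGE = 75.0  # left truncation at max(enrollment age, 75)


@dataclass
class KMCurve:
    """Product-limit survival estimate for one exposure group.

    ``table`` columns: age, at_risk, events, censored, survival, ci_low,
    ci_high (log-log / exponential-Greenwood bands). ``n_never_at_risk``
    counts individuals excluded because their event precedes their entry.
    """

    group: str
    table: pd.DataFrame
    n_used: int
    n_never_at_risk: int

    def survival_at(self, age: float) -> float:
        t = self.table
        prior = t.loc[t["age"] <= age, "survival"]
        return float(prior.iloc[-1]) if len(prior) else 1.0


def kaplan_meier(cohort: CohortTable, group_by: str = "exposure") -> dict[str, KMCurve]:
    """Kaplan-Meier estimates per group with delayed entry.

    Entry age is max(enrollment age, 75); an individual entering at exactly
    an event age is treated as entering just before it (so they sit in that
    risk set). Individuals whose event/censoring age does not exceed their
    entry age are never at risk and are excluded with a count.
    """
    df = cohort.retained if cohort.derived else cohort.data
    out: dict[str, KMCurve] = {}
    for value, sub in df.groupby(group_by, sort=True):
        entry = np.maximum(sub["enrollment_age"].to_numpy(dtype=float), ENTRY_AGE)
        dur = sub["event_age"].to_numpy(dtype=float)
        ev = sub["death"].to_numpy(dtype=int)
        ok = dur > entry - 1e-9
        never = int((~ok).sum())
        entry, dur, ev = entry[ok], dur[ok], ev[ok]
        # nudge entry below any coincident event time: entry happens first
        entry = entry - 1e-9
        kmf = KaplanMeierFitter()
        kmf.fit(dur, event_observed=ev, entry=entry)
        surv = kmf.survival_function_
        ci = kmf.confidence_interval_
        ages = np.round(surv.index.to_numpy(dtype=float), 6)
        at_risk = np.array([int(((entry < t) & (dur >= t)).sum()) for t in ages])
        events = np.array([int(((dur == t) & (ev == 1)).sum()) for t in ages])
        censored = np.array([int(((dur == t) & (ev == 0)).sum()) for t in ages])
        table = pd.DataFrame({
            "age": ages, "at_risk": at_risk, "events": events, "censored": censored,
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            "ci_low": ci.iloc[:, 0].to_numpy(dtype=float),
            "ci_high": ci.iloc[:, 1].to_numpy(dtype=float),
        })
        out[str(value)] = KMCurve(str(value), table, int(ok.sum()), never)
    return out


def _stratum_row(sub: pd.DataFrame, label: str) -> dict:
    row: dict = {"stratum": label, "n": len(sub)}
    for var in ("enrollment_age", "event_age"):
        x = sub[var].dropna()
        row[f"{var}_mean"] = float(x.mean()) if len(x) else np.nan
        row[f"{var}_sd"] = float(x.std(ddof=1)) if len(x) > 1 else np.nan
        row[f"{var}_missing"] = int(sub[var].isna().sum())
    binaries = {
        "education_hs": sub["education"] == 1,
        "education_above_hs": sub["education"] == 2,
        "ever_smoked": sub["smoking"] == 1,
        "comorbidity": sub["comorbidity"] == 1,
        "overweight": sub["exposure"] == 1,
        "survive_85": sub["outcome"] == 1,
    }
    sources = {"education_hs": "education", "education_above_hs": "education",
               "ever_smoked": "smoking", "comorbidity": "comorbidity",
               "overweight": "exposure", "survive_85": "outcome"}
    for name, ind in binaries.items():
        nonmiss = sub[sources[name]].notna()
        k = int((ind & nonmiss).sum())
        row[f"{name}_n"] = k
        row[f"{name}_pct"] = 100.0 * k / nonmiss.sum() if nonmiss.sum() else np.nan
        row[f"{name}_missing"] = int((~nonmiss).sum())
    return row


def descriptive_table(cohort: CohortTable) -> pd.DataFrame:
    """Cohort characteristics per sex x race stratum and overall.

    One row per stratum (including empty strata with n = 0) plus a total
    row: mean (sd) of enrollment and event ages, n (%) for education,
    smoking, comorbidity, overweight and survival past 85, and per-variable
    missing counts. Percentages are of the stratum's non-missing values.
    """
    df = cohort.retained if cohort.derived else cohort.data
    rows = []
    for sex, sex_label in SEX_LABELS.items():
        for race, race_label in RACE_LABELS.items():
            sub = df[(df["sex"] == sex) & (df["race"] == race)]
            rows.append(_stratum_row(sub, f"{race_label} {sex_label}"))
    rows.append(_stratum_row(df, "total"))
    return pd.DataFrame(rows)
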