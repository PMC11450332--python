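"""Instrument screening: IV assumptions, instrument strength, LD pruning.

A candidate variant (single or composite SNP — both go through the identical
code path) qualifies as an instrument when

* relevance: it predicts the exposure, tested on BOTH codings — logistic on
  the overweight/normal dichotomy and linear on continuous mean BMI — and its
  strength F exceeds ``f_min``;
* independence: it is associated with no identified confounder;
* exclusion: it is not associated with the outcome given exposure and
  confounders (logistic, again for both exposure codings).

Confounders are identified once per cohort: covariates with a significant
coefficient in the logistic regression of outcome on exposure plus
covariates. Candidates surviving the assumption and strength screens are
greedily LD-pruned so every retained pairwise dosage r-squared stays below
``r2_max``, dropping from each offending pair the member less associated
with the exposure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cohort import CATEGORICAL_COVARIATES, COVARIATES, CohortTable
from .plink import GenotypeMatrix


# ---------------------------------------------------------------- model fits

def fit_logit(y: np.ndarray, X: np.ndarray):
    """Logistic fit, Newton with BFGS fallback; warnings suppressed."""
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return model.fit(disp=0)
        except Exception:
            return model.fit(method="bfgs", maxiter=500, disp=0)


def _design(df: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate design; categorical covariates become dummies."""
    parts = [np.ones((len(df), 1))]
    names = ["const"]
    for c in columns:
        x = df[c]
        if c in CATEGORICAL_COVARIATES:
            d = pd.get_dummies(x.astype("category"), prefix=c, drop_first=True, dtype=float)
            parts.append(d.to_numpy())
            names += list(d.columns)
        else:
            parts.append(x.to_numpy(dtype=float)[:, None])
            names.append(c)
    return np.hstack(parts), names


# ----------------------------------------------------- instrument strength

def f_statistic(r2: float, n: int, k: int = 1) -> float:
    """Instrument-strength F = ((n - k - 1) / k) * (r2 / (1 - r2))."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must be in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("n must exceed k + 1")
    return ((n - k - 1) / k) * (r2 / (1.0 - r2))


def r2_for_unrelated(dosage: np.ndarray, exposure: np.ndarray) -> float:
    """Max-rescaled (Nagelkerke) R-squared of the logistic exposure ~ dosage.

    Cox-Snell generalized R-squared ``1 - exp(2 (ll0 - ll1) / n)`` divided by
    its upper bound ``1 - exp(2 ll0 / n)``.
    """
    mask = ~(np.isnan(dosage) | np.isnan(exposure))
    y, d = exposure[mask], dosage[mask]
    n = len(y)
    if n == 0 or len(np.unique(y)) < 2:
        raise ValueError("exposure must take both values")
    X = np.column_stack([np.ones(n), d])
    res = fit_logit(y, X)
    pbar = y.mean()
    ll0 = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - res.llf) / n)
    upper = 1.0 - np.exp(2.0 * ll0 / n)
    return float(min(max(cox_snell / upper, 0.0), 1.0 - 1e-12))


def r2_for_related(dosage: np.ndarray, exposure: np.ndarray,
                   covariates: pd.DataFrame | None, family_ids: np.ndarray) -> float:
    """R-squared for family data via mixed-model residuals.

    Fits exposure ~ covariates with a family-level random intercept
    (variational logistic mixed model), takes response residuals, and returns
    the squared Pearson correlation between residuals and dosage — the
    simple-regression R-squared, identical whichever variable is regressed on
    which. Falls back to a fixed-effects logistic fit with cluster-robust
    errors (warning logged) if the mixed model fails.
    """
    mask = ~(np.isnan(dosage) | np.isnan(exposure))
    if covariates is not None and len(covariates.columns):
        mask &= ~covariates.isna().any(axis=1).to_numpy()
        X = covariates.loc[mask]
        exog = np.column_stack([np.ones(mask.sum()), X.to_numpy(dtype=float)])
    else:
        exog = np.ones((int(mask.sum()), 1))
    y, d = exposure[mask], dosage[mask]
    fams = pd.Series(np.asarray(family_ids)[mask])
    vc = pd.get_dummies(fams, dtype=float).to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.BinomialBayesMixedGLM(y, exog, vc, np.zeros(vc.shape[1], dtype=int))
            fit = model.fit_vb()
            linpred = exog @ fit.fe_mean + vc @ fit.vc_mean
            fitted = 1.0 / (1.0 + np.exp(-linpred))
    except Exception:
        warnings.warn("logistic mixed model failed; falling back to fixed effects "
                      "with cluster-robust errors", stacklevel=2)
        res = fit_logit(y, exog)
        fitted = res.predict()
    resid = y - fitted
    if np.std(resid) == 0 or np.std(d) == 0:
        return 0.0
    r = np.corrcoef(resid, d)[0, 1]
    return float(r * r)


# -------------------------------------------------------------- confounders

@dataclass
class ConfounderSet:
    """Covariates whose coefficient in outcome ~ exposure + covariates is significant."""

    names: list[str]
    pvalues: dict[str, float]
    estimates: dict[str, float]
    alpha: float
    failures: dict[str, str] = field(default_factory=dict)


def identify_confounders(cohort: CohortTable, covariates: list[str] | None = None,
                         alpha: float = 0.05) -> ConfounderSet:
    """One logistic fit of outcome on exposure plus all covariates.

    A categorical covariate is significant if any of its level coefficients
    is. Returns the covariates with p < alpha.
    """
    covariates = COVARIATES if covariates is None else list(covariates)
    df = cohort.retained
    if not covariates:
        return ConfounderSet([], {}, {}, alpha)
    X, names = _design(df, covariates)
    y = df["outcome"].to_numpy(dtype=float)
    X_full = np.column_stack([X[:, :1], df["exposure"].to_numpy(dtype=float), X[:, 1:]])
    names_full = ["const", "exposure"] + names[1:]
    failures: dict[str, str] = {}
    try:
        res = fit_logit(y, X_full)
        pvals = dict(zip(names_full, res.pvalues))
        betas = dict(zip(names_full, res.params))
    except Exception as exc:  # pragma: no cover - separation edge
        return ConfounderSet([], {}, {}, alpha, failures={c: str(exc) for c in covariates})
    sel, pv, est = [], {}, {}
    for cov in covariates:
        terms = [t for t in names_full if t == cov or t.startswith(cov + "_")]
        term_p = [pvals[t] for t in terms if np.isfinite(pvals[t])]
        if not term_p:
            failures[cov] = "no finite p-value (possible separation)"
            continue
        best = min(term_p)
        pv[cov] = best
        est[cov] = betas[[t for t in terms if np.isfinite(pvals[t])][int(np.argmin(term_p))]]
        if best < alpha:
            sel.append(cov)
    return ConfounderSet(sel, pv, est, alpha, failures)


# --------------------------------------------------------- assumption tests

@dataclass
class AssumptionTestResult:
    variant_id: str
    beta1: float = np.nan       # log-odds of exposure per allele (Eq-1 logistic)
    se1: float = np.nan
    p1: float = np.nan
    beta1_cont: float = np.nan  # kg/m^2 BMI per allele (Eq-1 linear)
    p1_cont: float = np.nan
    confounder_assoc: dict[str, float] = field(default_factory=dict)
    beta31: float = np.nan      # log-odds of outcome per allele given exposure+confounders
    p31: float = np.nan
    p31_cont: float = np.nan
    f_value: float = np.nan
    r2: float = np.nan
    n_used: int = 0
    passed: bool = False
    failure_reasons: list[str] = field(default_factory=list)


def test_assumptions(dosage: np.ndarray, cohort: CohortTable, confounders: ConfounderSet,
                     alpha: float = 0.05, f_min: float = 10.0,
                     variant_id: str = "", related: bool = False) -> AssumptionTestResult:
    """Screen one variant against the three IV assumptions and strength F.

    Requires the dosage vector aligned to the *retained* cohort rows.
    """
    df = cohort.retained
    res = AssumptionTestResult(variant_id=variant_id)
    mask = ~np.isnan(dosage)
    d = dosage[mask]
    sub = df.loc[mask].reset_index(drop=True)
    res.n_used = len(sub)
    if len(np.unique(d)) < 2:
        res.failure_reasons.append("monomorphic")
        return res

    exposure = sub["exposure"].to_numpy(dtype=float)
    outcome = sub["outcome"].to_numpy(dtype=float)
    bmi = sub["mean_bmi"].to_numpy(dtype=float)
    ones = np.ones(len(sub))

    # relevance, both codings
    try:
        fit1 = fit_logit(exposure, np.column_stack([ones, d]))
        res.beta1, res.se1, res.p1 = fit1.params[1], fit1.bse[1], fit1.pvalues[1]
    except Exception:
        res.p1 = np.nan
    lin = sm.OLS(bmi, np.column_stack([ones, d])).fit()
    res.beta1_cont, res.p1_cont = lin.params[1], lin.pvalues[1]
    if not (res.p1 < alpha and res.p1_cont < alpha):
        res.failure_reasons.append("relevance")

    # independence: each identified confounder regressed on / tested against dosage
    for cov in confounders.names:
        if cov in CATEGORICAL_COVARIATES:
            tab = pd.crosstab(sub[cov], pd.Series(d, name="dosage"))
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                p = 1.0
            else:
                p = sps.chi2_contingency(tab.to_numpy())[1]
        else:
            p = sm.OLS(sub[cov].to_numpy(dtype=float), np.column_stack([ones, d])).fit().pvalues[1]
        res.confounder_assoc[cov] = float(p)
    if any(p < alpha for p in res.confounder_assoc.values()):
        res.failure_reasons.append("confounder")

    # exclusion: outcome ~ dosage + exposure + confounders, both codings
    if confounders.names:
        C, _ = _design(sub, confounders.names)
        C = C[:, 1:]
    else:
        C = np.empty((len(sub), 0))
    p31 = p31c = np.nan
    try:
        fit3 = fit_logit(outcome, np.column_stack([ones, d, exposure, C]))
        res.beta31, p31 = fit3.params[1], fit3.pvalues[1]
    except Exception:
        pass
    try:
        fit3c = fit_logit(outcome, np.column_stack([ones, d, bmi, C]))
        p31c = fit3c.pvalues[1]
    except Exception:
        pass
    res.p31, res.p31_cont = p31, p31c
    if (np.isfinite(p31) and p31 < alpha) or (np.isfinite(p31c) and p31c < alpha):
        res.failure_reasons.append("exclusion")

    # strength
    try:
        if related:
            cov_df = sub[confounders.names] if confounders.names else None
            res.r2 = r2_for_related(d, exposure, cov_df, sub["family_id"].to_numpy())
        else:
            res.r2 = r2_for_unrelated(d, exposure)
        res.f_value = f_statistic(res.r2, len(sub), 1)
    except (ValueError, ZeroDivisionError):
        res.f_value = np.nan
    if not (res.f_value > f_min):
        res.failure_reasons.append("weak_instrument")

    res.passed = not res.failure_reasons
    return res


# ----------------------------------------------------------------- LD prune

def ld_prune(dosages: pd.DataFrame, exposure_pvalues: pd.Series, r2_max: float = 0.3) -> list[str]:
    """Greedy LD pruning at squared-dosage-correlation threshold ``r2_max``.

    While any retained pair has r2 >= r2_max, the pair with the largest r2 is
    processed first and the member with the larger exposure-association
    p-value removed (ties by r2, then by lexicographically larger id).
    Certifies on exit that every retained pairwise r2 < r2_max.
    """
    ids = list(dosages.columns)
    if len(ids) < 2:
        return ids
    corr = dosages.corr() ** 2
    retained = set(ids)
    while True:
        best = None
        for i, a in enumerate(ids):
            if a not in retained:
                continue
            for b in ids[i + 1:]:
                if b not in retained:
                    continue
                r2 = corr.loc[a, b]
                if np.isnan(r2) or r2 < r2_max:
                    continue
                key = (-r2, a, b)
                if best is None or key < best[0]:
                    best = (key, a, b)
        if best is None:
            break
        _, a, b = best
        pa, pb = exposure_pvalues.get(a, np.nan), exposure_pvalues.get(b, np.nan)
        if np.isnan(pa) and np.isnan(pb):
            drop = max(a, b)
        elif np.isnan(pa):
            drop = a
        elif np.isnan(pb):
            drop = b
        elif pa > pb:
            drop = a
        elif pb > pa:
            drop = b
        else:
            drop = max(a, b)
        retained.discard(drop)
    kept = [i for i in ids if i in retained]
    sub = corr.loc[kept, kept].to_numpy()
    np.fill_diagonal(sub, 0.0)
    assert np.nanmax(sub, initial=0.0) < r2_max, "LD prune postcondition violated"
    return kept


# ------------------------------------------------------------- full screen

@dataclass
class IVRecord:
    """Audit-trail entry for one candidate instrument."""

    variant_id: str
    stage: str                      # qualified | failed stage name
    qualified: bool
    assumption: AssumptionTestResult | None = None
    gwas_p: float = np.nan


SCREEN_STAGES = ["gwas_scan", "relevance", "confounder", "exclusion", "weak_instrument", "ld", "qualified"]


def select_ivs(g: GenotypeMatrix, cohort: CohortTable, mode: str = "candidate_gene",
               covariates: list[str] | None = None, alpha: float = 0.05,
               f_min: float = 10.0, r2_max: float = 0.3, related: bool = False,
               bonferroni: bool = False) -> tuple[list[IVRecord], ConfounderSet]:
    """Run the full screening pipeline over the variants of ``g``.

    ``gwas`` mode first keeps only variants associated with the exposure
    (logistic with all covariates) at p < alpha. ``bonferroni`` divides alpha
    by the candidate count for the screening tests (off by default). Returns
    one IVRecord per candidate — qualified or failed, with the first failed
    stage — plus the identified confounder set.
    """
    if mode not in ("candidate_gene", "gwas"):
        raise ValueError("mode must be 'candidate_gene' or 'gwas'")
    df = cohort.retained
    pos = pd.Index(g.individual_ids)
    idx = pos.get_indexer(df["iid"])
    if (idx < 0).any():
        raise ValueError("retained cohort contains individuals absent from genotype data")
    dosages = g.dosages[idx, :]

    confounders = identify_confounders(cohort, covariates, alpha)
    alpha_screen = alpha / g.n_variants if (bonferroni and g.n_variants) else alpha

    records: dict[str, IVRecord] = {}
    ids = g.variants["id"].tolist()

    candidates = list(range(len(ids)))
    if mode == "gwas":
        X_cov, _ = _design(df, COVARIATES if covariates is None else list(covariates))
        keep = []
        for j in candidates:
            d = dosages[:, j]
            mask = ~np.isnan(d)
            try:
                fit = fit_logit(df["exposure"].to_numpy(dtype=float)[mask],
                                np.column_stack([X_cov[mask], d[mask]]))
                p = fit.pvalues[-1]
            except Exception:
                p = np.nan
            if np.isfinite(p) and p < alpha:
                keep.append(j)
                records[ids[j]] = IVRecord(ids[j], "pending", False, gwas_p=p)
            else:
                records[ids[j]] = IVRecord(ids[j], "gwas_scan", False, gwas_p=p)
        candidates = keep

    survivors: list[int] = []
    for j in candidates:
        a = test_assumptions(dosages[:, j], cohort, confounders, alpha=alpha_screen,
                             f_min=f_min, variant_id=ids[j], related=related)
        if a.passed:
            survivors.append(j)
            records[ids[j]] = IVRecord(ids[j], "pending", False, assumption=a,
                                       gwas_p=records.get(ids[j], IVRecord(ids[j], "", False)).gwas_p)
        else:
            reasons = ["relevance" if s == "monomorphic" else s for s in a.failure_reasons]
            first = next(s for s in ["relevance", "confounder", "exclusion", "weak_instrument"] if s in reasons)
            records[ids[j]] = IVRecord(ids[j], first, False, assumption=a,
                                       gwas_p=records.get(ids[j], IVRecord(ids[j], "", False)).gwas_p)

    dmat = pd.DataFrame({ids[j]: dosages[:, j] for j in survivors})
    pvals = pd.Series({ids[j]: records[ids[j]].assumption.p1 for j in survivors})
    kept = set(ld_prune(dmat, pvals, r2_max)) if survivors else set()
    for j in survivors:
        vid = ids[j]
        if vid in kept:
            records[vid].stage, records[vid].qualified = "qualified", True
        else:
            records[vid].stage = "ld"
    ordered = [records[v] for v in ids]
    if not any(r.qualified for r in ordered):
        warnings.warn("no candidate qualified as an instrument", stacklevel=2)
    return ordered, confounders


def audit_table(records: list[IVRecord]) -> pd.DataFrame:
    """IV audit trail: one row per candidate with stage and statistics."""
    rows = []
    for r in records:
        a = r.assumption
        rows.append({
            "id": r.variant_id, "stage": r.stage, "qualified": r.qualified,
            "gwas_p": r.gwas_p,
            "beta1": a.beta1 if a else np.nan, "p1": a.p1 if a else np.nan,
            "beta1_cont": a.beta1_cont if a else np.nan, "p1_cont": a.p1_cont if a else np.nan,
            "p31": a.p31 if a else np.nan, "p31_cont": a.p31_cont if a else np.nan,
            "f_value": a.f_value if a else np.nan, "r2": a.r2 if a else np.nan,
            "n_used": a.n_used if a else 0,
            "reasons": ";".join(a.failure_reasons) if a else ("gwas_scan" if r.stage == "gwas_scan" else ""),
        })
    return pd.DataFrame(rows)
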