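"""Mendelian-randomization estimators on per-instrument summary statistics.

Per instrument j the one-sample summary statistics are betaX_j (log-odds of
the exposure per coded allele), betaY_j (log-odds of the outcome per coded
allele) and their Wald standard errors, from two univariate logistic
regressions *without covariates*. The causal log-odds of exposure on outcome
is then estimated from the ratio estimates theta_j = betaY_j / betaX_j by

* IVW — inverse-variance weighted mean of the theta_j, with first-order
  (delta-method) se(theta_j) = seY_j / |betaX_j|; algebraically identical to
  weighted least squares of betaY on betaX through the origin with weights
  1/seY^2;
* penalized IVW — IVW with the weight of heterogeneous instruments
  down-scaled via the chi-square tail probability of their contribution to
  Cochran's Q;
* weighted median — the 50%-cumulative-weight point of the ordered theta_j,
  consistent while valid instruments carry half the weight; bootstrap se;
* MR-Egger — weighted regression of betaY on betaX with an intercept whose
  distance from the origin indexes directional pleiotropy.

E-values translate each instrument's implied odds ratio to the minimum
confounder association strength, on the risk-ratio scale, able to explain
it away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cohort import CohortTable
from .ivselect import fit_logit
from .plink import GenotypeMatrix

Z95 = sps.norm.ppf(0.975)


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    p: float
    n_ivs: int

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - Z95 * self.se, self.estimate + Z95 * self.se)


@dataclass
class MRResultSet:
    stats: pd.DataFrame
    results: dict[str, MRResult]
    egger_intercept: MRResult | None = None
    evalue_summary: tuple[float, float, float] | None = None
    verdict: bool | None = None  # significant IVW and Egger intercept CI covering 0
    messages: list[str] = field(default_factory=list)

    @property
    def n_ivs(self) -> int:
        return len(self.stats)


def _normal_p(estimate: float, se: float) -> float:
    if se <= 0 or not np.isfinite(se):
        return np.nan
    return float(2.0 * sps.norm.sf(abs(estimate) / se))


# --------------------------------------------------------------- summaries

def association_stats(g: GenotypeMatrix, cohort: CohortTable) -> pd.DataFrame:
    """Uncovariated per-IV exposure and outcome associations.

    For each variant of ``g``: logistic exposure ~ dosage and outcome ~
    dosage on the retained cohort, complete-case per instrument. Instruments
    with separated or non-finite fits are dropped with a warning. Columns:
    ``iv, beta_x, se_x, beta_y, se_y, n_used``.
    """
    df = cohort.retained
    idx = pd.Index(g.individual_ids).get_indexer(df["iid"])
    if (idx < 0).any():
        raise ValueError("retained cohort contains individuals absent from genotype data")
    exposure = df["exposure"].to_numpy(dtype=float)
    outcome = df["outcome"].to_numpy(dtype=float)
    rows, dropped = [], []
    for j, vid in enumerate(g.variants["id"]):
        d = g.dosages[idx, j]
        mask = ~np.isnan(d)
        dd = d[mask]
        ones = np.ones(mask.sum())
        try:
            fx = fit_logit(exposure[mask], np.column_stack([ones, dd]))
            fy = fit_logit(outcome[mask], np.column_stack([ones, dd]))
            row = {"iv": vid, "beta_x": fx.params[1], "se_x": fx.bse[1],
                   "beta_y": fy.params[1], "se_y": fy.bse[1], "n_used": int(mask.sum())}
        except Exception:
            dropped.append(vid)
            continue
        if not all(np.isfinite(v) for v in (row["beta_x"], row["se_x"], row["beta_y"], row["se_y"])) \
                or row["se_x"] <= 0 or row["se_y"] <= 0 \
                or abs(row["beta_x"]) > 15 or max(row["se_x"], row["se_y"]) > 30:
            dropped.append(vid)
            continue
        rows.append(row)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} IV(s) with separated/non-finite fits: {dropped}",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=["iv", "beta_x", "se_x", "beta_y", "se_y", "n_used"])


def _ratios(stats: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """First-order ratio estimates and their inverse-variance weights."""
    bx = stats["beta_x"].to_numpy(dtype=float)
    if np.any(bx == 0):
        raise ValueError("beta_x of 0 cannot form a ratio estimate; exclude that IV")
    theta = stats["beta_y"].to_numpy(dtype=float) / bx
    se = stats["se_y"].to_numpy(dtype=float) / np.abs(bx)
    return theta, 1.0 / se**2


# -------------------------------------------------------------- estimators

def ivw(stats: pd.DataFrame) -> MRResult:
    """Inverse-variance weighted mean of the per-IV ratio estimates."""
    if len(stats) < 1:
        raise ValueError("IVW needs at least one IV")
    stats = _drop_zero_bx(stats)
    theta, w = _ratios(stats)
    est = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return MRResult("ivw", est, se, _normal_p(est, se), len(stats))


def penalized_ivw(stats: pd.DataFrame, penalty_factor: float = 20.0) -> MRResult:
    """IVW with heterogeneity-penalized weights.

    Each instrument's Q contribution ``Q_j = w_j (theta_j - theta_IVW)^2`` is
    sent through the chi-square(1) upper tail to ``q_j``, and its weight
    scaled by ``min(1, penalty_factor * q_j)``.
    """
    if len(stats) < 3:
        raise ValueError("penalized IVW needs at least three IVs")
    stats = _drop_zero_bx(stats)
    theta, w = _ratios(stats)
    est0 = np.sum(w * theta) / np.sum(w)
    q = sps.chi2.sf(w * (theta - est0) ** 2, df=1)
    w_pen = w * np.minimum(1.0, penalty_factor * q)
    if np.sum(w_pen) <= 0 or not np.isfinite(np.sum(w_pen)):
        raise ValueError("all weights penalized to zero; estimates are too heterogeneous")
    est = float(np.sum(w_pen * theta) / np.sum(w_pen))
    se = float(1.0 / np.sqrt(np.sum(w_pen)))
    return MRResult("penalized_ivw", est, se, _normal_p(est, se), len(stats))


def weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``theta`` (cumulative weight 0.5)."""
    order = np.argsort(theta)
    t, w = np.asarray(theta, dtype=float)[order], np.asarray(weights, dtype=float)[order]
    if np.sum(w) <= 0:
        raise ValueError("degenerate (non-positive) weights")
    w = w / np.sum(w)
    s = np.cumsum(w) - w / 2.0
    if 0.5 <= s[0]:
        return float(t[0])
    if 0.5 >= s[-1]:
        return float(t[-1])
    k = np.searchsorted(s, 0.5) - 1
    return float(t[k] + (t[k + 1] - t[k]) * (0.5 - s[k]) / (s[k + 1] - s[k]))


def weighted_median(stats: pd.DataFrame, n_boot: int = 1000, seed: int | None = 0) -> MRResult:
    """Weighted-median estimator with seeded parametric-bootstrap se."""
    if len(stats) < 3:
        raise ValueError("weighted median needs at least three IVs")
    stats = _drop_zero_bx(stats)
    theta, w = _ratios(stats)
    est = weighted_median_point(theta, w)
    rng = np.random.default_rng(seed)
    bx = stats["beta_x"].to_numpy(dtype=float)
    by = stats["beta_y"].to_numpy(dtype=float)
    sx = stats["se_x"].to_numpy(dtype=float)
    sy = stats["se_y"].to_numpy(dtype=float)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb[bxb == 0] = 1e-300
        tb = byb / bxb
        wb = (np.abs(bxb) / sy) ** 2
        boots[b] = weighted_median_point(tb, wb)
    se = float(np.std(boots, ddof=1))
    return MRResult("weighted_median", est, se, _normal_p(est, se), len(stats))


def mr_egger(stats: pd.DataFrame) -> tuple[MRResult, MRResult]:
    """MR-Egger regression: (slope, intercept).

    Instruments are first oriented so betaX >= 0 (both betas sign-flipped
    where needed), then betaY is regressed on betaX with an intercept and
    weights 1/seY^2. The slope is the causal estimate; an intercept CI
    covering 0 is the "non-distinct from the origin" pleiotropy verdict.
    """
    if len(stats) < 3:
        raise ValueError("MR-Egger needs at least three IVs")
    bx = stats["beta_x"].to_numpy(dtype=float).copy()
    by = stats["beta_y"].to_numpy(dtype=float).copy()
    sy = stats["se_y"].to_numpy(dtype=float)
    flip = bx < 0
    bx[flip], by[flip] = -bx[flip], -by[flip]
    if np.ptp(bx) < 1e-12:
        warnings.warn("near-zero spread in beta_x; MR-Egger fit is unstable", stacklevel=2)
    X = np.column_stack([np.ones_like(bx), bx])
    res = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    slope = MRResult("egger_slope", float(res.params[1]), float(res.bse[1]),
                     _normal_p(res.params[1], res.bse[1]), len(stats))
    intercept = MRResult("egger_intercept", float(res.params[0]), float(res.bse[0]),
                         _normal_p(res.params[0], res.bse[0]), len(stats))
    return slope, intercept


# ----------------------------------------------------------------- E-value

def evalue(rr: float) -> float:
    """E-value for a risk ratio: RR + sqrt(RR * (RR - 1)); RR < 1 inverted."""
    if not (rr > 0):
        raise ValueError("risk ratio must be > 0")
    if rr < 1.0:
        rr = 1.0 / rr
    return float(rr + np.sqrt(rr * (rr - 1.0)))


def evalue_summary(stats: pd.DataFrame, conversion: str = "common_outcome_sqrt") -> tuple[float, float, float]:
    """(average, min, max) E-value over the per-IV ratio estimates.

    Each instrument's odds ratio exp(theta_j) is converted to a risk ratio —
    ``common_outcome_sqrt`` (RR ~ sqrt(OR), appropriate for the common
    survive-past-85 outcome) or ``rare_outcome`` (RR = OR) — before the
    E-value transform.
    """
    if conversion not in ("common_outcome_sqrt", "rare_outcome"):
        raise ValueError("conversion must be 'common_outcome_sqrt' or 'rare_outcome'")
    if len(stats) < 1:
        raise ValueError("E-value summary needs at least one IV")
    stats = _drop_zero_bx(stats)
    theta, _ = _ratios(stats)
    orj = np.exp(theta)
    rr = np.sqrt(orj) if conversion == "common_outcome_sqrt" else orj
    ev = np.array([evalue(r) for r in rr])
    return (float(ev.mean()), float(ev.min()), float(ev.max()))


def _drop_zero_bx(stats: pd.DataFrame) -> pd.DataFrame:
    zero = stats["beta_x"] == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} IV(s) with beta_x = 0", stacklevel=2)
        stats = stats.loc[~zero]
        if len(stats) == 0:
            raise ValueError("no IV left after excluding beta_x = 0")
    return stats.reset_index(drop=True)


# ------------------------------------------------------------------ driver

@dataclass
class MROptions:
    alpha: float = 0.05
    n_boot: int = 1000
    penalty_factor: float = 20.0
    evalue_conversion: str = "common_outcome_sqrt"
    seed: int | None = 0


def run_mr_stats(stats: pd.DataFrame, options: MROptions | None = None) -> MRResultSet:
    """All estimators from a prepared summary-statistics table."""
    opt = options or MROptions()
    if len(stats) < 1:
        raise ValueError("cannot run MR with an empty IV set")
    out = MRResultSet(stats=stats, results={})
    out.results["ivw"] = ivw(stats)
    if len(stats) >= 3:
        out.results["penalized_ivw"] = penalized_ivw(stats, opt.penalty_factor)
        out.results["weighted_median"] = weighted_median(stats, opt.n_boot, opt.seed)
        slope, intercept = mr_egger(stats)
        out.results["egger_slope"] = slope
        out.egger_intercept = intercept
    else:
        out.messages.append("fewer than 3 IVs: weighted median and MR-Egger skipped")
    out.evalue_summary = evalue_summary(stats, opt.evalue_conversion)
    ivw_sig = out.results["ivw"].p < opt.alpha
    if out.egger_intercept is not None:
        lo, hi = out.egger_intercept.ci95
        out.verdict = bool(ivw_sig and lo <= 0.0 <= hi)
    else:
        out.verdict = bool(ivw_sig)
    if not ivw_sig and "penalized_ivw" in out.results:
        out.messages.append("standard IVW not significant; penalized IVW is the reported estimate")
    return out


def run_mr(g: GenotypeMatrix, cohort: CohortTable, options: MROptions | None = None) -> MRResultSet:
    """Summary statistics plus the full estimator suite for qualified IVs."""
    if g.n_variants < 1:
        raise ValueError("cannot run MR with an empty IV set")
    stats = association_stats(g, cohort)
    if len(stats) == 0:
        raise ValueError("no usable IV: all association fits failed")
    return run_mr_stats(stats, options)


def run_mr_stratified(g: GenotypeMatrix, cohort: CohortTable, strata: list[str],
                      options: MROptions | None = None) -> dict[str, MRResultSet]:
    """Run MR within each stratum of the given cohort columns, plus overall."""
    out = {"all": run_mr(g, cohort, options)}
    if not strata:
        return out
    df = cohort.data
    for key, sub in df.groupby(strata, sort=True):
        label = "/".join(f"{c}={v}" for c, v in zip(strata, key if isinstance(key, tuple) else (key,)))
        sub_cohort = CohortTable(sub.reset_index(drop=True), cohort.bmi[cohort.bmi["iid"].isin(sub["iid"])])
        try:
            out[label] = run_mr(g, sub_cohort, options)
        except ValueError as exc:
            empty = MRResultSet(stats=pd.DataFrame(), results={}, messages=[str(exc)])
            out[label] = empty
    return out
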