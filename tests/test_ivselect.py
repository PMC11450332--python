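import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

from compositemr.cohort import derive_variables
from compositemr.ivselect import (f_statistic, identify_confounders, ld_prune,
                                  r2_for_related, r2_for_unrelated, select_ivs)
from compositemr.ivselect import test_assumptions as assumption_screen
from compositemr.simulate import SimulationConfig, simulate_cohort
from compositemr import scenarios

from conftest import make_derived_cohort, make_genotypes


class TestFStatistic:
    def test_printed_arithmetic(self):
        assert f_statistic(0.01, 1001, 1) == pytest.approx(999 * (0.01 / 0.99))
        assert f_statistic(0.0, 100, 1) == 0.0
        assert f_statistic(0.5, 12, 1) == pytest.approx(10.0)

    def test_monotone_in_r2_and_n(self):
        grid_r2 = np.linspace(0.001, 0.9, 25)
        vals = [f_statistic(r, 1000, 1) for r in grid_r2]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        grid_n = range(10, 500, 7)
        vals = [f_statistic(0.1, n, 1) for n in grid_n]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("bad", [dict(r2=1.0, n=100, k=1), dict(r2=-0.1, n=100, k=1),
                                     dict(r2=0.5, n=2, k=1), dict(r2=0.5, n=100, k=0)])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            f_statistic(**bad)


def nagelkerke_oracle(dosage, exposure):
    """Independent max-rescaled R^2: likelihood maximised with scipy only."""
    X = np.column_stack([np.ones_like(dosage), dosage])

    def nll(beta):
        z = X @ beta
        return np.sum(np.logaddexp(0.0, z)) - exposure @ z

    res = optimize.minimize(nll, np.zeros(2), method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 500})
    n = len(exposure)
    p = exposure.mean()
    ll0 = n * (p * np.log(p) + (1 - p) * np.log(1 - p))
    cs = 1.0 - np.exp(2.0 * (ll0 + res.fun) / n)
    return cs / (1.0 - np.exp(2.0 * ll0 / n))


class TestR2Unrelated:
    def test_agrees_with_independent_likelihood_implementation(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.3, 800).astype(float)
        y = (rng.random(800) < 1 / (1 + np.exp(-(-0.3 + 0.4 * d)))).astype(float)
        assert r2_for_unrelated(d, y) == pytest.approx(nagelkerke_oracle(d, y), abs=1e-8)

    def test_perfect_prediction_approaches_one(self):
        y = np.repeat([0.0, 1.0], 50)
        d = 2.0 * y
        assert r2_for_unrelated(d, y) > 0.95

    def test_independent_dosage_gives_negligible_r2(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, 50_000).astype(float)
        y = (rng.random(50_000) < 0.5).astype(float)
        assert r2_for_unrelated(d, y) < 0.001


class TestR2Related:
    def test_null_r2_is_negligible(self):
        rng = np.random.default_rng(2)
        n, fams = 3000, 300
        fam = np.arange(n) % fams
        u = rng.normal(0, 1, fams)[fam]
        y = (rng.random(n) < 1 / (1 + np.exp(-u))).astype(float)
        d = rng.binomial(2, 0.3, n).astype(float)
        assert r2_for_related(d, y, None, fam.astype(str)) < 0.005

    def test_symmetry_of_simple_regression_r2(self):
        # the r2 is the squared correlation, so regressing residuals on the
        # SNP or the SNP on the residuals is the same number
        rng = np.random.default_rng(3)
        resid = rng.normal(0, 1, 500)
        d = rng.binomial(2, 0.4, 500).astype(float)
        b1 = sps.linregress(d, resid)
        b2 = sps.linregress(resid, d)
        assert b1.rvalue**2 == pytest.approx(b2.rvalue**2, abs=1e-12)

    def test_planted_snp_effect_detected_under_family_structure(self):
        rng = np.random.default_rng(4)
        n, fams = 3000, 300
        fam = np.arange(n) % fams
        u = rng.normal(0, 1.0, fams)[fam]
        d = rng.binomial(2, 0.3, n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * d + u)))).astype(float)
        r2 = r2_for_related(d, y, None, fam.astype(str))
        assert f_statistic(r2, n, 1) > 10


class TestLDPrune:
    def test_duplicate_vectors_keep_smaller_p(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.3, 500).astype(float)
        dosages = pd.DataFrame({"a": d, "b": d})
        assert ld_prune(dosages, pd.Series({"a": 0.2, "b": 0.01})) == ["b"]

    def test_independent_variants_all_retained(self):
        rng = np.random.default_rng(6)
        dosages = pd.DataFrame(rng.binomial(2, 0.3, size=(10_000, 5)).astype(float),
                               columns=list("abcde"))
        ps = pd.Series(0.01, index=list("abcde"))
        assert ld_prune(dosages, ps) == list("abcde")

    def test_planted_correlated_triple_matches_brute_force(self):
        rng = np.random.default_rng(7)
        n = 2000
        base = rng.binomial(2, 0.4, n).astype(float)

        def noisy():
            keep = rng.random(n) < 0.9
            return np.where(keep, base, rng.binomial(2, 0.4, n))

        dosages = pd.DataFrame({
            "t1": base, "t2": noisy(), "t3": noisy(),
            "u1": rng.binomial(2, 0.3, n).astype(float),
            "u2": rng.binomial(2, 0.3, n).astype(float),
        })
        ps = pd.Series({"t1": 0.5, "t2": 0.01, "t3": 0.3, "u1": 0.2, "u2": 0.2})
        corr = dosages.corr() ** 2
        best = max(
            (set(sub) for r in range(6) for sub in itertools.combinations(dosages.columns, r)
             if all(corr.loc[a, b] < 0.3 for a, b in itertools.combinations(sub, 2))),
            key=len)
        kept = ld_prune(dosages, ps, 0.3)
        assert len(kept) == len(best)
        sub = corr.loc[kept, kept].to_numpy()
        np.fill_diagonal(sub, 0)
        assert sub.max() < 0.3
        assert "t2" in kept  # survivor of the triple is the most exposure-associated

    def test_empty_input(self):
        assert ld_prune(pd.DataFrame(), pd.Series(dtype=float)) == []


class TestIdentifyConfounders:
    def test_planted_confounder_recovered(self):
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(n_individuals=10_000, theta_true=0.2,
                                   confounder_effects={"smoking": (-2.0, -0.8)}, seed=seed)
            _, cohort = simulate_cohort(cfg)
            found = identify_confounders(derive_variables(cohort), alpha=0.05)
            if "smoking" in found.names:
                hits += 1
        assert hits >= 18

    def test_type_one_error_calibrated_without_planted_confounders(self):
        selected = total = 0
        for seed in range(60):
            _, cohort = simulate_cohort(SimulationConfig(n_individuals=2000, seed=1000 + seed))
            found = identify_confounders(derive_variables(cohort), alpha=0.05)
            selected += len(found.names)
            total += len(found.pvalues)
        rate = selected / total
        assert 0.02 < rate < 0.09  # about 5% of covariates flagged by chance

    def test_empty_covariate_list(self, demo_analysis):
        _, cohort = demo_analysis
        assert identify_confounders(cohort, covariates=[]).names == []


@pytest.fixture(scope="module")
def screening_run():
    g, cohort = simulate_cohort(scenarios.screening_config(10_000, seed=77))
    cohort = derive_variables(cohort)
    confounders = identify_confounders(cohort, covariates=[])
    idx = pd.Index(g.individual_ids).get_indexer(cohort.retained["iid"])
    return g, cohort, confounders, g.dosages[idx, :]


class TestAssumptions:
    def test_valid_instrument_passes(self, screening_run):
        g, cohort, confounders, dos = screening_run
        res = assumption_screen(dos[:, 0], cohort, confounders, variant_id="v")
        assert res.passed, res.failure_reasons
        assert res.p1 < 0.05 and res.p1_cont < 0.05 and res.f_value > 10

    def test_pleiotropic_instrument_fails_exclusion(self, screening_run):
        g, cohort, confounders, dos = screening_run
        res = assumption_screen(dos[:, 10], cohort, confounders)
        assert "exclusion" in res.failure_reasons

    def test_null_variant_fails_relevance(self, screening_run):
        g, cohort, confounders, dos = screening_run
        # a freshly drawn dosage vector has no effect on anything
        null = np.random.default_rng(0).binomial(2, 0.3, dos.shape[0]).astype(float)
        res = assumption_screen(null, cohort, confounders)
        assert "relevance" in res.failure_reasons and not res.passed

    def test_monomorphic_variant_fails_with_reason(self, screening_run):
        g, cohort, confounders, _ = screening_run
        res = assumption_screen(np.zeros(len(cohort.retained)), cohort, confounders)
        assert res.failure_reasons == ["monomorphic"]


class TestSelectIVs:
    def test_audit_counts_partition_candidates(self, demo_analysis):
        g, cohort = demo_analysis
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records, _ = select_ivs(g, cohort)
        stages = pd.Series([r.stage for r in records]).value_counts()
        assert stages.sum() == g.n_variants
        qualified = sum(r.qualified for r in records)
        assert qualified == stages.get("qualified", 0)

    def test_infinite_f_min_rejects_everything(self, demo_analysis):
        g, cohort = demo_analysis
        with pytest.warns(UserWarning, match="no candidate qualified"):
            records, _ = select_ivs(g, cohort, f_min=np.inf)
        assert not any(r.qualified for r in records)

    def test_gwas_mode_prescreens_on_exposure(self, demo_analysis):
        g, cohort = demo_analysis
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records, _ = select_ivs(g, cohort, mode="gwas")
        assert all(np.isfinite(r.gwas_p) or r.stage == "gwas_scan" for r in records)
        failed_scan = [r for r in records if r.stage == "gwas_scan"]
        assert all(not (r.gwas_p < 0.05) for r in failed_scan)


def test_null_relevance_rate_is_about_alpha():
    """With no planted effects each relevance test rejects ~5% of variants;
    requiring both codings can only lower the joint pass rate."""
    cfg = SimulationConfig(n_individuals=5000, n_snps_per_gene=63, beta_main=0.0,
                           maf_range=(0.2, 0.4), seed=13)
    g, cohort = simulate_cohort(cfg)
    cohort = derive_variables(cohort)
    confounders = identify_confounders(cohort, covariates=[])
    idx = pd.Index(g.individual_ids).get_indexer(cohort.retained["iid"])
    dos = g.dosages[idx, :]
    binary_hits = joint = 0
    for j in range(g.n_variants):
        r = assumption_screen(dos[:, j], cohort, confounders, f_min=0.0)
        binary_hits += r.p1 < 0.05
        joint += "relevance" not in r.failure_reasons
    assert binary_hits / g.n_variants == pytest.approx(0.05, abs=0.025)
    assert joint <= binary_hits


def test_strong_continuous_signal_implies_dichotomized_relevance():
    """A variant overwhelming on continuous BMI passes the binary coding too."""
    ok = 0
    for seed in range(10):
        g, cohort = simulate_cohort(scenarios.recovery_config(10_000, 0.2, 300 + seed))
        cohort = derive_variables(cohort)
        confounders = identify_confounders(cohort, covariates=[])
        idx = pd.Index(g.individual_ids).get_indexer(cohort.retained["iid"])
        r = assumption_screen(g.dosages[idx, 0], cohort, confounders, f_min=0.0)
        assert r.p1_cont < 1e-6
        if "relevance" not in r.failure_reasons:
            ok += 1
    assert ok >= 9
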