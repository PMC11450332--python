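"""Synthetic cohort generator for the composite-SNP MR pipeline.

Emulates the structure the analysis assumes: candidate-gene SNP dosages in
Hardy-Weinberg proportions, BMI over ages 75-85 driven by SNP main effects,
optional SNP x SNP interactions, confounders and a family random intercept,
and a binary survive-past-85 outcome driven by overweight status with
optional direct (pleiotropic) SNP effects. All randomness flows from one
``numpy`` Generator consumed in a fixed documented order, so a given config
and seed reproduce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .composite import recode_dosage_sum
from .plink import FAM_COLUMNS, GenotypeMatrix, write_plink
from .cohort import write_phenotypes

#: the eight candidate obesity/BMI genes
CANDIDATE_GENES = ("ADIPOQ", "FTO", "LEP", "LEPR", "INSIG2", "MC4R", "PCSK1", "PPARG")

#: default marginal distributions of the categorical covariates
DEFAULT_COVARIATE_DISTS = {
    "sex": {1: 0.42, 2: 0.58},
    "race": {1: 0.80, 2: 0.15, 3: 0.05},
    "education": {0: 0.20, 1: 0.35, 2: 0.45},
    "smoking": {0: 0.45, 1: 0.55},
    "comorbidity": {0: 0.40, 1: 0.60},
    "field_center": {1: 0.70, 2: 0.30},
}

BMI_BASELINE = 21.75  # kg/m^2, midpoint of the normal range


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``beta_main`` (kg/m^2 per minor allele) may be a scalar applied to every
    SNP or a per-SNP sequence; ``beta_interaction`` acts on the recoded
    dosage of designated SNP pairs (consecutive disjoint pairs in variant
    order unless ``interaction_pairs`` gives explicit index pairs).
    ``confounder_effects`` maps a covariate name to
    ``(effect_on_bmi, effect_on_outcome_log_odds)`` — both paths, which is
    what makes it a confounder; categorical covariates enter linearly in
    their integer codes. ``pleiotropy_effects`` maps SNP index (or id) to a
    direct log-odds effect on the outcome per minor allele.
    """

    n_individuals: int = 2000
    n_snps_per_gene: int = 2
    maf_range: tuple[float, float] = (0.2, 0.4)
    beta_main: float | tuple[float, ...] = 0.4
    beta_interaction: float | tuple[float, ...] = 0.0
    interaction_pairs: tuple[tuple[int, int], ...] | None = None
    theta_true: float = 0.2
    outcome_intercept: float = 0.2
    confounder_effects: dict[str, tuple[float, float]] = dc_field(default_factory=dict)
    covariate_dists: dict[str, dict[int, float]] = dc_field(default_factory=lambda: dict(DEFAULT_COVARIATE_DISTS))
    pleiotropy_effects: dict = dc_field(default_factory=dict)
    n_families: int = 0
    family_effect_sd: float = 0.0
    bmi_noise_sd: float = 2.5
    bmi_measure_noise_sd: float = 0.0
    n_bmi_measures: int = 3
    ld_block_size: int = 1
    ld_block_rho: float = 0.0
    genotype_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_snps_per_gene < 0:
            raise ValueError("n_snps_per_gene must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("family_effect_sd", "bmi_noise_sd", "bmi_measure_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_bmi_measures < 0:
            raise ValueError("n_bmi_measures must be >= 0")
        if not (0.0 <= self.genotype_missing_rate < 1.0):
            raise ValueError("genotype_missing_rate must be in [0, 1)")
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_block_rho <= 1.0):
            raise ValueError("ld_block_rho must be in [0, 1]")
        for cov in self.confounder_effects:
            if cov not in list(DEFAULT_COVARIATE_DISTS) + ["pc1", "pc2"]:
                raise ValueError(f"confounder_effects: unknown covariate {cov!r}")

    @property
    def n_snps(self) -> int:
        return self.n_snps_per_gene * len(CANDIDATE_GENES)

    def resolved_beta_main(self) -> np.ndarray:
        b = np.broadcast_to(np.asarray(self.beta_main, dtype=float), (self.n_snps,))
        return np.array(b)

    def resolved_interactions(self) -> list[tuple[int, int, float]]:
        pairs = self.interaction_pairs
        if pairs is None:
            pairs = tuple((i, i + 1) for i in range(0, self.n_snps - 1, 2))
        betas = np.broadcast_to(np.asarray(self.beta_interaction, dtype=float), (len(pairs),))
        return [(a, b, bb) for (a, b), bb in zip(pairs, betas)]


def _draw_genotypes(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Allele-level binomial draws; optional LD blocks share alleles."""
    n, m = cfg.n_individuals, cfg.n_snps
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    alleles = np.empty((2, n, m), dtype=np.int8)
    for j in range(m):
        block_start = (j // cfg.ld_block_size) * cfg.ld_block_size
        fresh = rng.random((2, n)) < mafs[j]
        if cfg.ld_block_rho > 0 and j != block_start:
            copy = rng.random((2, n)) < cfg.ld_block_rho
            alleles[:, :, j] = np.where(copy, alleles[:, :, block_start], fresh)
        else:
            alleles[:, :, j] = fresh
    dosages = alleles.sum(axis=0).astype(np.float64)
    if cfg.genotype_missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.genotype_missing_rate
        dosages[miss] = np.nan
    return dosages, mafs


def _draw_covariates(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_individuals
    cols = {}
    for name, dist in cfg.covariate_dists.items():
        levels = np.array(sorted(dist))
        probs = np.array([dist[k] for k in levels], dtype=float)
        probs = probs / probs.sum()
        cols[name] = rng.choice(levels, size=n, p=probs)
    cols["pc1"] = rng.normal(0.0, 1.0, size=n)
    cols["pc2"] = rng.normal(0.0, 1.0, size=n)
    return pd.DataFrame(cols)


def simulate_cohort(cfg: SimulationConfig) -> tuple[GenotypeMatrix, CohortTable]:
    """Generate genotypes and phenotypes under the configured model.

    Draw order: genotypes, covariates, family intercepts, BMI noise, BMI
    measurement ages/noise, enrollment ages, outcome, event ages. Mean BMI is
    ``21.75 + sum(beta_main * dosage) + sum(beta_interaction * recoded pair
    dosage) + confounder terms + family intercept + noise``; the outcome is
    Bernoulli with log-odds ``intercept + theta_true * overweight +
    confounder terms + pleiotropy terms``. Individuals with mean BMI outside
    [18.5, 30) are emitted too — filtering is downstream's job.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_snps

    dosages, mafs = _draw_genotypes(cfg, rng)
    genes = [g for g in CANDIDATE_GENES for _ in range(cfg.n_snps_per_gene)]
    snp_ids = [f"{g}_snp{k}" for g in CANDIDATE_GENES for k in range(cfg.n_snps_per_gene)]
    variants = pd.DataFrame({
        "chrom": "1", "id": snp_ids, "cm": 0, "pos": np.arange(1, m + 1) * 1000,
        "a1": "A", "a2": "G", "gene": genes, "maf": mafs,
    })

    covs = _draw_covariates(cfg, rng)

    if cfg.n_families > 0:
        family_id = np.array([f"fam{i % cfg.n_families}" for i in range(n)])
        intercepts = rng.normal(0.0, cfg.family_effect_sd, size=cfg.n_families)
        fam_codes = np.arange(n) % cfg.n_families
        family_term = intercepts[fam_codes]
    else:
        family_id = np.array([f"fam{i}" for i in range(n)])
        family_term = np.zeros(n)

    dos0 = np.nan_to_num(dosages)  # missing dosages contribute 0 to phenotype paths
    mean_bmi = BMI_BASELINE + dos0 @ cfg.resolved_beta_main()
    for a, b, beta in cfg.resolved_interactions():
        if beta != 0.0:
            mean_bmi = mean_bmi + beta * recode_dosage_sum(dos0[:, a] + dos0[:, b])
    conf_bmi = np.zeros(n)
    conf_out = np.zeros(n)
    for cov, (e_bmi, e_out) in cfg.confounder_effects.items():
        x = covs[cov].to_numpy(dtype=float)
        conf_bmi += e_bmi * x
        conf_out += e_out * x
    mean_bmi = mean_bmi + conf_bmi + family_term + rng.normal(0.0, cfg.bmi_noise_sd, size=n)

    ages = rng.uniform(75.0, 85.0, size=(n, cfg.n_bmi_measures))
    meas = mean_bmi[:, None] + rng.normal(0.0, cfg.bmi_measure_noise_sd, size=ages.shape)
    bmi_long = pd.DataFrame({
        "iid": np.repeat([f"ind{i}" for i in range(n)], cfg.n_bmi_measures),
        "age": ages.ravel(), "bmi": meas.ravel(),
    })

    enrollment_age = rng.uniform(70.0, 80.0, size=n)

    overweight = ((mean_bmi >= 25.0) & (mean_bmi < 30.0)).astype(float)
    linpred = cfg.outcome_intercept + cfg.theta_true * overweight + conf_out
    for key, eff in cfg.pleiotropy_effects.items():
        j = snp_ids.index(key) if isinstance(key, str) else int(key)
        linpred = linpred + eff * dos0[:, j]
    outcome = (rng.random(n) < 1.0 / (1.0 + np.exp(-linpred))).astype(int)

    # survivors are censored alive at >= 85; deaths uniform in [76, 85)
    death = np.where(outcome == 1, 0, 1)
    u = rng.random(n)
    death_age = np.maximum(76.0, enrollment_age + 0.5) * (1 - u) + 85.0 * u  # uniform on [max(76, enroll+.5), 85)
    survive_age = 85.0 + 7.0 * rng.random(n)
    event_age = np.where(outcome == 1, survive_age, death_age)

    iids = [f"ind{i}" for i in range(n)]
    fam = pd.DataFrame({
        "fid": family_id, "iid": iids, "pat": "0", "mat": "0",
        "sex": covs["sex"].to_numpy(), "pheno": -9,
    })[FAM_COLUMNS]
    data = pd.DataFrame({"iid": iids, "family_id": family_id})
    for c in covs.columns:
        data[c] = covs[c].to_numpy()
    data["enrollment_age"] = enrollment_age
    data["event_age"] = event_age
    data["death"] = death

    g = GenotypeMatrix(dosages, variants, fam)
    return g, CohortTable(data, bmi_long)


def write_cohort(g: GenotypeMatrix, cohort: CohortTable, path_prefix: str) -> None:
    """Write the PLINK triplet plus phenotype/BMI TSVs under one prefix."""
    if not g.individual_ids.tolist() == cohort.data["iid"].tolist():
        raise ValueError("genotype and cohort individual ids differ")
    write_plink(g, path_prefix)
    write_phenotypes(cohort, path_prefix)
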