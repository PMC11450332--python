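"""Reference study conditions for calibration and validation experiments.

These fix, once, the synthetic-cohort configurations used to characterise
the pipeline's statistical behaviour (estimator calibration, instrument
screening, type-I error). Effect sizes alternate in sign across SNPs so the
candidate-gene burden leaves mean BMI near the normal/overweight boundary
with both exposure groups populated, and per-allele effects are sized so
single-SNP instruments clear the conventional F > 10 bar comfortably
(median F around 20-30 at n = 5,000).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .simulate import SimulationConfig


def alternating_effects(n_snps: int, magnitude: float) -> tuple[float, ...]:
    """Per-SNP BMI effects (kg/m^2 per allele) of alternating sign."""
    return tuple(magnitude * (1.0 if i % 2 == 0 else -1.0) for i in range(n_snps))


def recovery_config(n_individuals: int, theta_true: float, seed: int) -> SimulationConfig:
    """Conditions for estimator calibration: 32 candidate SNPs (4 per gene),
    per-allele |effect| 0.6 kg/m^2, residual BMI sd 2.0, no confounding or
    pleiotropy. The first 30 SNPs serve as the valid instruments."""
    return SimulationConfig(
        n_individuals=n_individuals, n_snps_per_gene=4, maf_range=(0.2, 0.4),
        beta_main=alternating_effects(32, 0.6), theta_true=theta_true,
        outcome_intercept=0.2, bmi_noise_sd=2.0, seed=seed,
    )


N_RECOVERY_IVS = 30


def screening_config(n_individuals: int, seed: int, pleiotropy: float = 0.25) -> SimulationConfig:
    """Conditions for instrument screening: 24 SNPs (3 per gene); SNPs 0-9
    are valid instruments, SNPs 10-19 additionally carry a direct
    (pleiotropic) outcome effect of ``pleiotropy`` log-odds per allele."""
    return SimulationConfig(
        n_individuals=n_individuals, n_snps_per_gene=3, maf_range=(0.2, 0.4),
        beta_main=alternating_effects(24, 0.6), theta_true=0.2,
        outcome_intercept=0.2, bmi_noise_sd=2.0,
        pleiotropy_effects={i: pleiotropy for i in range(10, 20)}, seed=seed,
    )


SCREENING_VALID = list(range(0, 10))
SCREENING_INVALID = list(range(10, 20))


def simulate_summary_stats(rng: np.random.Generator, n_ivs: int, theta: float,
                           pleiotropy: float = 0.0, se_y: float = 0.05,
                           se_x: float = 0.02) -> "pd.DataFrame":
    """Summary-statistic-level instruments: betaX ~ U(0.1, 0.5), betaY =
    theta * betaX + pleiotropy + noise. Used for estimator-only checks."""
    import pandas as pd

    bx = rng.uniform(0.1, 0.5, size=n_ivs)
    by = theta * bx + pleiotropy + rng.normal(0.0, se_y, size=n_ivs)
    return pd.DataFrame({
        "iv": [f"iv{i}" for i in range(n_ivs)],
        "beta_x": bx + rng.normal(0.0, se_x, size=n_ivs),
        "se_x": se_x, "beta_y": by, "se_y": se_y,
        "n_used": 10000,
    })


def ivw_plim(theta_true: float, seed: int = 900, n_individuals: int = 150_000) -> float:
    """Large-sample limit of the IVW estimate under :func:`recovery_config`.

    With a dichotomized exposure the per-IV ratio of marginal logistic
    coefficients converges to roughly ``theta_true * p(1-p)`` (p the
    overweight prevalence among retained individuals), not to ``theta_true``
    itself; this computes the limit by direct simulation at large n.
    """
    from .cohort import derive_variables
    from .mr import association_stats, ivw
    from .simulate import simulate_cohort

    g, cohort = simulate_cohort(recovery_config(n_individuals, theta_true, seed))
    cohort = derive_variables(cohort)
    stats = association_stats(g.subset(variants=np.arange(N_RECOVERY_IVS)), cohort)
    return ivw(stats).estimate


def run_recovery_rep(n_individuals: int, theta_true: float, seed: int):
    """One calibration replicate: simulate, derive, IVW over the 30 IVs."""
    from .cohort import derive_variables
    from .mr import association_stats, ivw
    from .simulate import simulate_cohort

    g, cohort = simulate_cohort(recovery_config(n_individuals, theta_true, seed))
    cohort = derive_variables(cohort)
    stats = association_stats(g.subset(variants=np.arange(N_RECOVERY_IVS)), cohort)
    return ivw(stats)
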