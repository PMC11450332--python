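"""Genotype quality-control filters.

Configurable stand-ins for published genotype QC protocols: per-variant and
per-individual call-rate thresholds, a minor-allele-frequency floor, and a
Hardy-Weinberg exact-test floor. When pedigree information marks founders
(both parental ids ``0`` in the fam table), the HWE test uses founders only,
since transmission within families distorts genotype proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .plink import GenotypeMatrix


@dataclass
class QCThresholds:
    snp_call_rate: float = 0.95
    ind_call_rate: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("snp_call_rate", "ind_call_rate", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QCReport:
    removed_snps_call_rate: int = 0
    removed_individuals_call_rate: int = 0
    removed_snps_maf: int = 0
    removed_snps_hwe: int = 0
    passes: int = 0
    removed_variant_ids: list = field(default_factory=list)
    removed_individual_ids: list = field(default_factory=list)


def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value (Wigginton-style).

    Sums the probabilities of all heterozygote counts, given the observed
    allele counts, that are no more likely than the observed one.
    """
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    rare = 2 * n_hom_minor + n_het
    if rare > n:  # orient so "rare" really is the less frequent allele
        rare = 2 * n - rare
    # log-probability of each feasible heterozygote count, up to a constant
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (hets * np.log(2.0) - gammaln(hets + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_het]
    if len(p_obs) == 0:
        return 1.0
    return float(min(1.0, p[p <= p_obs[0] * (1 + 1e-12)].sum()))


def _hwe_pvalues(dosages: np.ndarray, founder_mask: np.ndarray) -> np.ndarray:
    sub = dosages[founder_mask, :]
    out = np.ones(sub.shape[1])
    for j in range(sub.shape[1]):
        col = sub[:, j]
        col = col[~np.isnan(col)]
        n_hom_minor = int((col == 2).sum())
        n_het = int((col == 1).sum())
        n_hom_major = int((col == 0).sum())
        out[j] = hwe_exact_p(n_het, n_hom_minor, n_hom_major)
    return out


def qc_filter(g: GenotypeMatrix, thresholds: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Remove variants/individuals failing any threshold; report counts.

    Filters are iterated to a fixed point (removing individuals can push a
    variant's call rate below threshold and vice versa), which also makes the
    operation idempotent. Returns the filtered matrix and a removal report;
    emits a warning, not silence, if everything is removed.
    """
    th = thresholds or QCThresholds()
    report = QCReport()
    changed = True
    npass = 0
    while changed and g.n_variants > 0 and g.n_individuals > 0:
        changed = False
        npass += 1

        call = 1.0 - np.isnan(g.dosages).mean(axis=0)
        keep = call >= th.snp_call_rate
        if not keep.all():
            report.removed_snps_call_rate += int((~keep).sum())
            report.removed_variant_ids += g.variants.loc[~keep, "id"].tolist()
            g = g.subset(variants=keep)
            changed = True
        if g.n_variants == 0:
            break

        ind_call = 1.0 - np.isnan(g.dosages).mean(axis=1)
        keep_i = ind_call >= th.ind_call_rate
        if not keep_i.all():
            report.removed_individuals_call_rate += int((~keep_i).sum())
            report.removed_individual_ids += g.fam.loc[~keep_i, "iid"].tolist()
            g = g.subset(individuals=keep_i)
            changed = True
        if g.n_individuals == 0:
            break

        with np.errstate(invalid="ignore"):
            freq = np.nanmean(g.dosages, axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        keep = ~(maf < th.maf_min)  # NaN-frequency (all-missing) columns die to call rate, keep here
        keep &= ~np.isnan(maf) | (th.maf_min == 0)
        if th.maf_min > 0 and not keep.all():
            report.removed_snps_maf += int((~keep).sum())
            report.removed_variant_ids += g.variants.loc[~keep, "id"].tolist()
            g = g.subset(variants=keep)
            changed = True
        if g.n_variants == 0:
            break

        if th.hwe_p_min > 0:
            founders = (g.fam["pat"].astype(str) == "0") & (g.fam["mat"].astype(str) == "0")
            mask = founders.to_numpy() if founders.any() else np.ones(g.n_individuals, dtype=bool)
            pvals = _hwe_pvalues(g.dosages, mask)
            keep = pvals >= th.hwe_p_min
            if not keep.all():
                report.removed_snps_hwe += int((~keep).sum())
                report.removed_variant_ids += g.variants.loc[~keep, "id"].tolist()
                g = g.subset(variants=keep)
                changed = True

    report.passes = npass
    if g.n_variants == 0:
        warnings.warn("QC removed every variant", stacklevel=2)
    if g.n_individuals == 0:
        warnings.warn("QC removed every individual", stacklevel=2)
    return g, report
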