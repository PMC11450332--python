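"""Composite-SNP construction.

A composite SNP is an unordered pair of variants whose minor-allele dosages
are summed (0-4) and recoded to a pseudo-genotype: sum 0 or 1 -> 0, sum 2
-> 1, sum 3 or 4 -> 2. The recoded value is *defined* to be the composite's
minor-allele count, so no frequency-based re-alignment is ever applied to
composite variants.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plink import GenotypeMatrix, write_plink

PAIRING_SCOPES = ("all_pairs", "between_genes", "within_genes")


def recode_dosage_sum(total):
    """Recode summed minor-allele dosages (0-4) to the composite count.

    Accepts scalars or arrays; NaN (missing) propagates.
    """
    t = np.asarray(total, dtype=float)
    if np.any((t < 0) | (t > 4) & ~np.isnan(t)):
        raise ValueError("summed dosage outside 0..4")
    out = np.where(t <= 1, 0.0, np.where(t <= 2, 1.0, 2.0))
    out = np.where(np.isnan(t), np.nan, out)
    return out if out.ndim else float(out) if not np.isnan(t) else float("nan")


def recode_pair(dosage_a, dosage_b):
    """Composite minor-allele count for one pair of constituent dosages.

    Each input must be 0, 1, 2 or NaN; missing in either constituent makes
    the composite missing. Symmetric and monotone in each argument.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    for name, x in (("dosage_a", a), ("dosage_b", b)):
        if np.any(~np.isnan(x) & ~np.isin(x, (0.0, 1.0, 2.0))):
            raise ValueError(f"{name} must be 0, 1, 2 or missing")
    return recode_dosage_sum(a + b)


@dataclass
class CompositeVariant:
    """One composite SNP: its id, constituent pair and recoded dosages."""

    id: str
    constituents: tuple[str, str]
    genes: tuple[str, str]
    dosages: np.ndarray


def _in_scope(gene_a: str, gene_b: str, scope: str) -> bool:
    if scope == "all_pairs":
        return True
    if scope == "between_genes":
        return gene_a != gene_b
    return gene_a == gene_b


def build_composites(g: GenotypeMatrix, pairing_scope: str = "all_pairs") -> list[CompositeVariant]:
    """All unordered in-scope pairs of variants in ``g``, recoded.

    Pairs are enumerated in variant order (i < j), giving a deterministic id
    ``{id_i}__{id_j}`` and ordering; ``all_pairs`` on m variants yields
    C(m, 2) composites. Fewer than 2 variants yields an empty list.
    """
    if pairing_scope not in PAIRING_SCOPES:
        raise ValueError(f"pairing_scope must be one of {PAIRING_SCOPES}")
    ids = g.variants["id"].tolist()
    if len(ids) < 2:
        warnings.warn("fewer than 2 variants: no composite SNP can be formed", stacklevel=2)
        return []
    genes = g.variants["gene"].tolist() if "gene" in g.variants.columns else [""] * len(ids)
    out: list[CompositeVariant] = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        if not _in_scope(genes[i], genes[j], pairing_scope):
            continue
        dos = recode_dosage_sum(g.dosages[:, i] + g.dosages[:, j])
        out.append(CompositeVariant(
            id=f"{ids[i]}__{ids[j]}", constituents=(ids[i], ids[j]),
            genes=(genes[i], genes[j]), dosages=np.asarray(dos, dtype=np.float64),
        ))
    return out


def composites_to_matrix(composites: list[CompositeVariant], fam: pd.DataFrame) -> GenotypeMatrix:
    """Pack composites as a GenotypeMatrix (synthetic chromosome-0 metadata).

    The recoded dosage is the composite's minor-allele count by definition,
    so downstream consumers must not re-align it to the in-sample minor
    allele even where its coded-allele frequency exceeds 0.5.
    """
    ids = [c.id for c in composites]
    if len(set(ids)) != len(ids):
        raise ValueError("composite id collision")
    if not composites:
        raise ValueError("no composites to pack")
    dosages = np.column_stack([c.dosages for c in composites])
    with np.errstate(invalid="ignore"):
        maf = np.nanmean(dosages, axis=0) / 2.0
    variants = pd.DataFrame({
        "chrom": "0", "id": ids, "cm": 0, "pos": np.arange(1, len(ids) + 1),
        "a1": "C", "a2": "N",
        "gene": ["+".join(c.genes) for c in composites], "maf": maf,
    })
    return GenotypeMatrix(dosages, variants, fam.reset_index(drop=True))


def write_composite_plink(composites: list[CompositeVariant], fam: pd.DataFrame, path_prefix: str) -> None:
    """Write composites as a PLINK triplet plus a manifest TSV.

    The manifest (``<prefix>.composites.tsv``) records each composite's
    constituent ids and genes. Read the triplet back with
    ``read_plink(prefix, align_minor=False)``: composite coding is
    definitional, not frequency-based.
    """
    g = composites_to_matrix(composites, fam)
    write_plink(g, path_prefix)
    pd.DataFrame({
        "id": [c.id for c in composites],
        "constituent_a": [c.constituents[0] for c in composites],
        "constituent_b": [c.constituents[1] for c in composites],
        "gene_a": [c.genes[0] for c in composites],
        "gene_b": [c.genes[1] for c in composites],
    }).to_csv(path_prefix + ".composites.tsv", sep="\t", index=False)
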