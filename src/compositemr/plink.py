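"""PLINK 1 binary genotype I/O (bed/bim/fam).

The bed payload is variant-major: for each variant, ``ceil(n/4)`` bytes,
each byte packing four individuals in little-endian 2-bit fields. Field
codes: ``00`` = homozygous A1, ``01`` = missing, ``10`` = heterozygous,
``11`` = homozygous A2. Dosages returned here count the A1 allele, so
``00 -> 2``, ``10 -> 1``, ``11 -> 0`` and missing is ``NaN``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MAGIC = bytes([0x6C, 0x1B, 0x01])

# byte value -> dosages of the four packed individuals
_DECODE = np.empty((256, 4), dtype=np.float32)
for _b in range(256):
    for _i in range(4):
        code = (_b >> (2 * _i)) & 0b11
        _DECODE[_b, _i] = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}[code]

_ENCODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}

BIM_COLUMNS = ["chrom", "id", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "pat", "mat", "sex", "pheno"]


@dataclass
class GenotypeMatrix:
    """Individuals x variants minor-allele dosage matrix with metadata.

    ``dosages`` is float with values in {0, 1, 2} and NaN for missing;
    after minor-allele alignment the coded (A1) allele frequency of every
    variant is <= 0.5 in-sample. ``variants`` carries the bim columns plus
    ``gene`` and ``maf``; ``fam`` the six fam columns.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    fam: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=FAM_COLUMNS))

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.variants) != m:
            raise ValueError(f"variant metadata rows ({len(self.variants)}) != dosage columns ({m})")
        if len(self.fam) != n:
            raise ValueError(f"fam rows ({len(self.fam)}) != dosage rows ({n})")
        if self.variants["id"].duplicated().any():
            dup = self.variants["id"][self.variants["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        if self.fam["iid"].duplicated().any():
            dup = self.fam["iid"][self.fam["iid"].duplicated()].iloc[0]
            raise ValueError(f"duplicate individual id {dup!r}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def individual_ids(self) -> pd.Series:
        return self.fam["iid"]

    def coded_allele_frequency(self) -> np.ndarray:
        """In-sample frequency of the coded (A1) allele per variant."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, *, individuals: np.ndarray | None = None, variants: np.ndarray | None = None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer index."""
        dos = self.dosages
        fam, var = self.fam, self.variants
        if individuals is not None:
            dos = dos[individuals, :]
            fam = fam.iloc[np.arange(len(fam))[individuals]] if getattr(individuals, "dtype", None) == bool else fam.iloc[individuals]
            fam = fam.reset_index(drop=True)
        if variants is not None:
            dos = dos[:, variants]
            var = var.iloc[np.arange(len(var))[variants]] if getattr(variants, "dtype", None) == bool else var.iloc[variants]
            var = var.reset_index(drop=True)
        return GenotypeMatrix(dos.copy(), var.copy(), fam.copy())


def _align_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Flip dosages 0<->2 (and swap alleles) where the coded allele is major."""
    freq = g.coded_allele_frequency()
    flip = freq > 0.5
    if flip.any():
        dos = g.dosages.copy()
        dos[:, flip] = 2.0 - dos[:, flip]
        var = g.variants.copy()
        a1 = var.loc[flip, "a1"].copy()
        var.loc[flip, "a1"] = var.loc[flip, "a2"].values
        var.loc[flip, "a2"] = a1.values
        g = replace(g, dosages=dos, variants=var)
    with np.errstate(invalid="ignore"):
        maf = np.nanmean(g.dosages, axis=0) / 2.0
    var = g.variants.copy()
    var["maf"] = maf
    return replace(g, variants=var)


def read_plink(path_prefix: str | os.PathLike, *, align_minor: bool = True) -> GenotypeMatrix:
    """Read a bed/bim/fam triplet into a :class:`GenotypeMatrix`.

    With ``align_minor`` (the default) dosages are flipped so the coded
    allele is the in-sample minor allele; pass ``False`` for files whose
    coding is definitional (composite variants) rather than frequency-based.
    """
    prefix = os.fspath(path_prefix)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None, names=BIM_COLUMNS,
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, names=FAM_COLUMNS,
                      dtype={"fid": str, "iid": str, "pat": str, "mat": str})
    with open(prefix + ".bed", "rb") as fh:
        header = fh.read(3)
        payload = fh.read()
    if header != MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes {header!r} (expected PLINK bed, variant-major)")
    n, m = len(fam), len(bim)
    bytes_per_variant = (n + 3) // 4
    if len(payload) != bytes_per_variant * m:
        raise ValueError(
            f"{prefix}.bed: payload is {len(payload)} bytes, expected "
            f"{bytes_per_variant * m} for {n} individuals x {m} variants"
        )
    if m == 0 or n == 0:
        dosages = np.empty((n, m), dtype=np.float64)
    else:
        raw = np.frombuffer(payload, dtype=np.uint8).reshape(m, bytes_per_variant)
        dosages = _DECODE[raw].reshape(m, bytes_per_variant * 4)[:, :n].T.astype(np.float64)
    if "gene" not in bim.columns:
        bim["gene"] = ""
    g = GenotypeMatrix(dosages, bim, fam)
    if align_minor:
        g = _align_minor(g)
    else:
        with np.errstate(invalid="ignore"):
            g.variants["maf"] = np.nanmean(g.dosages, axis=0) / 2.0 if n else np.nan
    return g


def write_plink(g: GenotypeMatrix, path_prefix: str | os.PathLike) -> None:
    """Write ``g`` as a bed/bim/fam triplet (variant-major bed)."""
    prefix = os.fspath(path_prefix)
    n, m = g.dosages.shape
    bad = ~(np.isnan(g.dosages) | np.isin(g.dosages, (0.0, 1.0, 2.0)))
    if bad.any():
        raise ValueError("dosages must be 0, 1, 2 or NaN to encode as PLINK bed")
    g.variants[BIM_COLUMNS].to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    g.fam[FAM_COLUMNS].to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    bytes_per_variant = (n + 3) // 4
    out = np.zeros((m, bytes_per_variant), dtype=np.uint8)
    codes = np.full((m, bytes_per_variant * 4), 0b01, dtype=np.uint8)  # pad = missing code
    dt = g.dosages.T
    for value, code in _ENCODE.items():
        codes[:, :n][dt == value] = code
    # padding beyond n must be zero bits per the format
    codes[:, :n][np.isnan(dt)] = 0b01
    codes[:, n:] = 0b00
    for i in range(4):
        out |= codes[:, i::4] << (2 * i)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(MAGIC)
        fh.write(out.tobytes())
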