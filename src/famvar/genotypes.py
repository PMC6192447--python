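"""Genotype dosage container and PLINK 1 bed/bim/fam input/output.

Dosages count copies of allele A1 (0, 1, 2) with -1 marking missing calls.
The binary .bed codec follows the PLINK 1 specification: magic bytes
0x6C 0x1B, mode byte 0x01 (SNP-major), then one byte per four individuals
and SNP with 2-bit codes 00 = hom A1, 10 = het, 11 = hom A2, 01 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# dosage of A1 -> 2-bit code and back
_DOSAGE_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix (int8; -1 = missing)."""

    dosages: np.ndarray
    ids: list[str]
    snp_ids: list[str]
    sex: np.ndarray | None = None  # 0 = female, 1 = male; optional, kept for .fam
    family: list[str] | None = None
    _id_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.snp_ids)} SNPs"
            )
        bad = ~np.isin(self.dosages, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or -1 for missing")
        self._id_index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def as_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing calls."""
        x = self.dosages.astype(float)
        x[self.dosages == -1] = np.nan
        return x

    # -- per-SNP / per-individual summaries ------------------------------

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return (self.dosages >= 0).mean(axis=0)

    def indiv_missing_rate(self) -> np.ndarray:
        return (self.dosages == -1).mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """In-sample frequency of allele A1 per SNP (missing excluded)."""
        x = self.as_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(x, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self) -> np.ndarray:
        """Per-SNP counts of (hom A1, het, hom A2), shape (m, 3)."""
        d = self.dosages
        return np.stack([(d == 2).sum(0), (d == 1).sum(0), (d == 0).sum(0)], axis=1)

    def subset(self, indiv_mask=None, snp_mask=None) -> "GenotypeMatrix":
        im = np.ones(self.n_individuals, bool) if indiv_mask is None else np.asarray(indiv_mask)
        sm = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        return GenotypeMatrix(
            self.dosages[np.ix_(im, sm)],
            [i for i, k in zip(self.ids, im) if k],
            [s for s, k in zip(self.snp_ids, sm) if k],
            sex=None if self.sex is None else np.asarray(self.sex)[im],
            family=None if self.family is None else [f for f, k in zip(self.family, im) if k],
        )


# ---------------------------------------------------------------------------
# PLINK 1 binary IO
# ---------------------------------------------------------------------------


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a PLINK 1 .bed/.bim/.fam fileset (SNP-major)."""
    prefix = Path(prefix)
    n, m = geno.n_individuals, geno.n_snps
    fam = pd.DataFrame(
        {
            "fid": geno.family if geno.family is not None else geno.ids,
            "iid": geno.ids,
            "father": "0",
            "mother": "0",
            # PLINK sex code: 1 = male, 2 = female, 0 = unknown
            "sex": [0] * n
            if geno.sex is None
            else [1 if s == 1 else 2 for s in geno.sex],
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": 1,
            "snp": geno.snp_ids,
            "cm": 0,
            "pos": np.arange(1, m + 1),
            "a1": "A",
            "a2": "B",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    codes = np.empty_like(geno.dosages, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[geno.dosages == dosage] = code
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for offset in range(4):
        block = codes[offset::4, :].T  # (m, ceil)
        packed[:, : block.shape[1]] |= block << (2 * offset)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 .bed/.bim/.fam fileset into a GenotypeMatrix."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"snp": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK 1 bed)")
    body = raw[3:]
    n_bytes = (n + 3) // 4
    if body.size != m * n_bytes:
        raise ValueError(
            f"{prefix}.bed: expected {m * n_bytes} data bytes for "
            f"{n} individuals x {m} SNPs, found {body.size}"
        )
    body = body.reshape(m, n_bytes)
    dosages = np.empty((n, m), dtype=np.int8)
    for offset in range(4):
        codes = (body >> (2 * offset)) & 0b11
        idx = np.arange(offset, n, 4)
        dosages[idx, :] = _CODE_TO_DOSAGE[codes[:, : len(idx)]].T
    sex = np.where(fam["sex"].to_numpy() == 1, 1, 0) if (fam["sex"] > 0).any() else None
    return GenotypeMatrix(
        dosages,
        list(fam["iid"]),
        list(bim["snp"]),
        sex=sex,
        family=list(fam["fid"]),
    )
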