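"""Variance-structure matrices: G, K, F, S, C.

G is the genomic relationship matrix from standardized SNP dosages
(GCTA-style estimator, in-sample allele frequencies); K is G with
off-diagonals below a relatedness threshold zeroed, so it tags genetic
sharing among close relatives only; F, S and C are binary indicator
matrices for nuclear-family membership, full siblingship and couple
relationships. All five are carried in a single container and can be
written to / read from the GCTA binary GRM triplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

KINDS = ("G", "K", "F", "S", "C")
_ENV_KIND = {"family": "F", "sibling": "S", "couple": "C"}


@dataclass
class RelationshipMatrix:
    """Symmetric N x N similarity matrix with an individual-ID index."""

    values: np.ndarray
    ids: list[str]
    kind: str
    n_snps_used: int | None = None
    _id_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in relationship matrix")
        self._id_index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def align(self, ids: list[str]) -> np.ndarray:
        """Values re-ordered/subset to ``ids``; raises if any id is absent."""
        missing = [i for i in ids if i not in self._id_index]
        if missing:
            raise KeyError(
                f"{len(missing)} requested ids absent from {self.kind} matrix "
                f"(first few: {missing[:5]})"
            )
        idx = np.array([self._id_index[i] for i in ids])
        return self.values[np.ix_(idx, idx)]


def compute_grm(geno: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix G = Z Z' / m.

    Z holds dosages centered by 2p and scaled by sqrt(2p(1-p)) with
    allele frequencies estimated in-sample; missing genotypes are
    mean-imputed per SNP before standardization (contributing zero to the
    numerator for the pairs involved).
    """
    x = geno.as_float()
    p = np.nanmean(x, axis=0) / 2.0
    mono = (p <= 0.0) | (p >= 1.0) | np.isnan(p)
    if mono.any():
        raise ValueError(
            f"{int(mono.sum())} monomorphic or all-missing SNPs present; "
            "run quality control (MAF filter) before computing the GRM"
        )
    x = np.where(np.isnan(x), 2 * p, x)
    Z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    G = (Z @ Z.T) / geno.n_snps
    return RelationshipMatrix(G, list(geno.ids), "G", n_snps_used=geno.n_snps)


def threshold_grm(G: RelationshipMatrix, t: float = 0.05) -> RelationshipMatrix:
    """K: zero off-diagonal entries of G strictly below ``t``; keep the diagonal."""
    K = G.values.copy()
    off = ~np.eye(G.n, dtype=bool)
    K[off & (K < t)] = 0.0
    return RelationshipMatrix(K, list(G.ids), "K", n_snps_used=G.n_snps_used)


def build_environment_matrix(ped: Pedigree, kind: str) -> RelationshipMatrix:
    """Binary shared-environment indicator matrix.

    ``family``: 1 for pairs in the same nuclear-family unit (the two
    parents plus their common offspring; childless couples form a
    two-member unit; individuals who are offspring in one unit and parent
    in another link to members of both). ``sibling``: both parents
    shared. ``couple``: mutual spouse pairs. Diagonal is 1.
    """
    if kind not in _ENV_KIND:
        raise ValueError(f"unknown kind {kind!r}; expected one of {sorted(_ENV_KIND)}")
    n = ped.n
    idx = {i: k for k, i in enumerate(ped.ids)}
    M = np.eye(n)
    if kind == "family":
        groups = [list(u[:2]) + list(u[2]) for u in ped.nuclear_units()]
    elif kind == "sibling":
        groups = [g for g in ped.sibships() if len(g) >= 2]
    else:
        groups = [list(c) for c in ped.couples()]
    for g in groups:
        ii = [idx[i] for i in g]
        M[np.ix_(ii, ii)] = 1.0
    return RelationshipMatrix(M, ped.ids, _ENV_KIND[kind])


# ---------------------------------------------------------------------------
# GCTA binary GRM triplet
# ---------------------------------------------------------------------------


def write_grm(rm: RelationshipMatrix, prefix: str | Path) -> None:
    """Write ``prefix``.grm.bin / .grm.N.bin / .grm.id (GCTA binary format).

    The lower triangle including the diagonal is stored row-wise as
    float32; .grm.N.bin holds the per-pair SNP count; .grm.id has
    family-ID and individual-ID columns (family ID repeats the
    individual ID here).
    """
    prefix = Path(prefix)
    n = rm.n
    tril = np.tril_indices(n)
    vals = rm.values[tril].astype("<f4")
    vals.tofile(f"{prefix}.grm.bin")
    n_snps = rm.n_snps_used if rm.n_snps_used is not None else 0
    np.full(vals.shape, n_snps, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    pd.DataFrame({"fid": rm.ids, "iid": rm.ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm(prefix: str | Path, kind: str = "G") -> RelationshipMatrix:
    """Read a GCTA binary GRM triplet written by :func:`write_grm` or GCTA."""
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None,
                      names=["fid", "iid"], dtype=str)
    n = len(ids)
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    expected = n * (n + 1) // 2
    if vals.size != expected:
        raise ValueError(
            f"{prefix}.grm.bin holds {vals.size} entries but .grm.id lists "
            f"{n} individuals (expected {expected})"
        )
    M = np.zeros((n, n))
    tril = np.tril_indices(n)
    M[tril] = vals
    M = M + M.T - np.diag(np.diag(M))
    n_path = Path(f"{prefix}.grm.N.bin")
    n_snps = None
    if n_path.exists():
        counts = np.fromfile(n_path, dtype="<f4")
        if counts.size:
            n_snps = int(counts[0])
    return RelationshipMatrix(M, list(ids["iid"]), kind, n_snps_used=n_snps)
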