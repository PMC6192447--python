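"""Genotype quality control and multidimensional-scaling ancestry axes.

SNP/individual inclusion thresholds follow the usual array-QC defaults:
SNP call rate >= 98%, per-individual missingness <= 2%, Hardy-Weinberg
exact p > 1e-6, minor allele frequency > 1%. MDS components are classical
principal-coordinate axes of an identity-by-state similarity matrix
computed within the cohort, used downstream as fixed-effect covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeMatrix


@dataclass
class QCThresholds:
    snp_call_rate_min: float = 0.98
    indiv_missing_max: float = 0.02
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class QCReport:
    snps_input: int
    individuals_input: int
    snps_dropped_by_rule: dict[str, int]
    individuals_dropped: int
    snps_retained: int
    individuals_retained: int

    def __post_init__(self) -> None:
        assert self.snps_retained + sum(self.snps_dropped_by_rule.values()) == self.snps_input
        assert self.individuals_retained + self.individuals_dropped == self.individuals_input

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg equilibrium.

    Enumerates the distribution of the heterozygote count conditional on
    the observed allele counts and sums the probabilities of all outcomes
    no more probable than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    # heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr  # common homozygotes
    # log P(n_Aa = h | allele counts) up to a common constant
    logp = (
        gammaln(n + 1)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hets == n_Aa]
    if obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    return float(min(1.0, p[p <= obs[0] * (1 + 1e-12)].sum()))


def apply_qc(geno: GenotypeMatrix, thr: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Filter SNPs and individuals.

    Order of application: SNP call rate, then individual missingness, then
    per-SNP statistics are recomputed on the retained individuals before
    the HWE and MAF rules.
    """
    thr = thr or QCThresholds()
    thr.validate()
    dropped: dict[str, int] = {}

    keep_snp = geno.call_rate() >= thr.snp_call_rate_min
    dropped["call_rate"] = int((~keep_snp).sum())
    g1 = geno.subset(snp_mask=keep_snp)

    keep_ind = g1.indiv_missing_rate() <= thr.indiv_missing_max
    n_ind_dropped = int((~keep_ind).sum())
    g2 = g1.subset(indiv_mask=keep_ind)
    if g2.n_individuals == 0:
        raise ValueError("quality control removed every individual")

    counts = g2.genotype_counts()
    hwe_p = np.array([
        hwe_exact_test(int(a), int(b), int(c)) if (a + b + c) > 0 else 0.0
        for a, b, c in counts
    ])
    keep_hwe = hwe_p > thr.hwe_p_min
    dropped["hwe"] = int((~keep_hwe).sum())

    maf = g2.maf()
    keep_maf = np.nan_to_num(maf, nan=0.0) > thr.maf_min
    dropped["maf"] = int((keep_hwe & ~keep_maf).sum())

    g3 = g2.subset(snp_mask=keep_hwe & keep_maf)
    if g3.n_snps == 0:
        raise ValueError("quality control removed every SNP")

    report = QCReport(
        snps_input=geno.n_snps,
        individuals_input=geno.n_individuals,
        snps_dropped_by_rule=dropped,
        individuals_dropped=n_ind_dropped,
        snps_retained=g3.n_snps,
        individuals_retained=g3.n_individuals,
    )
    return g3, report


def ibs_similarity(geno: GenotypeMatrix) -> np.ndarray:
    """Pairwise identity-by-state similarity in [0, 1].

    ``1 - mean(|d_j - d_k|) / 2`` over SNPs where both calls are present.
    """
    X = geno.as_float()
    W = (~np.isnan(X)).astype(float)
    Xf = np.nan_to_num(X)
    sq = Xf**2
    cross = Xf @ Xf.T
    m2 = (sq * W) @ W.T + W @ (sq * W).T - 2 * cross
    hom0 = (Xf == 0) * W
    hom2 = (Xf == 2) * W
    far = hom0 @ hom2.T
    abs_sum = m2 - 2 * (far + far.T)
    denom = W @ W.T
    if (denom == 0).any():
        raise ValueError("some individual pairs share no genotyped SNPs")
    return 1.0 - abs_sum / denom / 2.0


def compute_mds(
    geno: GenotypeMatrix,
    n_components: int = 4,
    founders: np.ndarray | None = None,
) -> pd.DataFrame:
    """Classical MDS (principal coordinates) of the IBS distance matrix.

    Axes are eigenvectors of the double-centered squared-distance matrix,
    ordered by eigenvalue and scaled by sqrt(eigenvalue); each axis is
    zero-centered by construction. ``founders`` (a boolean mask) restricts
    the computation to that subset — useful to avoid family structure
    dominating the axes — in which case components are returned for the
    subset only.
    """
    n = geno.n_individuals
    if n_components > n - 1:
        raise ValueError(f"n_components={n_components} exceeds N-1={n - 1}")
    if founders is not None:
        geno_fit = geno.subset(indiv_mask=founders)
        sim = ibs_similarity(geno_fit)
        ids = geno_fit.ids
    else:
        sim = ibs_similarity(geno)
        ids = geno.ids
    D2 = (1.0 - sim) ** 2
    m = D2.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    comps = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    out = pd.DataFrame(comps, columns=[f"MDS{k + 1}" for k in range(n_components)])
    out.insert(0, "id", ids)
    return out
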