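"""Synthetic family cohort with known ground-truth variance structure.

Generates multi-generation pedigrees of nuclear families, gene-dropped
common-SNP genotypes, phenotypes built additively from genomic (G),
pedigree-associated genetic (K), nuclear-family (F), sibling (S) and
couple (C) components plus fixed effects and noise, and Likert-item
questionnaire responses consistent with the latent trait scores. Every
downstream stage of the variance-decomposition pipeline can therefore be
exercised against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, write_plink
from .pedigree import MISSING_PARENT, Pedigree

__all__ = [
    "PedigreeSpec",
    "VarianceSpec",
    "BivariateSpec",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_bivariate_phenotypes",
    "simulate_items",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass
class PedigreeSpec:
    """Shape of the simulated cohort.

    ``offspring_dist`` is either a fixed integer number of offspring per
    couple or ``("poisson_plus", lam, k)`` meaning ``k + Poisson(lam)``.
    ``n_generations`` = 1 gives founder couples plus their offspring;
    deeper values pair ``couple_fraction`` of each non-final offspring
    generation into new couples (across families, opposite sexes) who
    reproduce in turn, so a depth-2 cohort spans grandparents to
    grandchildren.
    """

    n_families: int = 250
    offspring_dist: int | tuple = 2
    n_generations: int = 1
    couple_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not 0.0 <= self.couple_fraction <= 1.0:
            raise ValueError("couple_fraction must be in [0, 1]")
        if isinstance(self.offspring_dist, tuple):
            tag, lam, k = self.offspring_dist
            if tag != "poisson_plus" or lam < 0 or k < 0:
                raise ValueError("offspring_dist tuple must be ('poisson_plus', lam>=0, k>=0)")
        elif int(self.offspring_dist) < 0:
            raise ValueError("offspring_dist must be >= 0")


@dataclass
class VarianceSpec:
    """Ground-truth variance fractions for one trait.

    h2_g: variance tagged by common-SNP genetic scores (G);
    h2_p: additional pedigree-associated genetic variance (K);
    e2_f / e2_s / e2_c: nuclear-family / full-sibling / couple shared
    environment. The residual fraction is 1 minus their sum.
    """

    h2_g: float = 0.0
    h2_p: float = 0.0
    e2_f: float = 0.0
    e2_s: float = 0.0
    e2_c: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    total_var: float = 1.0

    @property
    def fractions(self) -> dict[str, float]:
        return {"G": self.h2_g, "K": self.h2_p, "F": self.e2_f, "S": self.e2_s, "C": self.e2_c}

    @property
    def residual(self) -> float:
        return 1.0 - sum(self.fractions.values())

    def validate(self) -> None:
        for name, v in self.fractions.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"variance fraction for {name} must be in [0, 1], got {v}")
        if sum(self.fractions.values()) > 1.0 + 1e-12:
            raise ValueError("variance fractions sum above 1")
        if self.total_var <= 0:
            raise ValueError("total_var must be positive")


@dataclass
class BivariateSpec:
    """Two traits with per-component cross-trait correlations."""

    trait1: VarianceSpec
    trait2: VarianceSpec
    r_G: float = 0.0
    r_K: float = 0.0
    r_E: float = 0.0

    def validate(self) -> None:
        self.trait1.validate()
        self.trait2.validate()
        for name, r in (("r_G", self.r_G), ("r_K", self.r_K), ("r_E", self.r_E)):
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1]")


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------


def _draw_offspring_counts(dist, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(dist, tuple):
        _, lam, k = dist
        return rng.poisson(lam, size=n) + int(k)
    return np.full(n, int(dist))


def simulate_pedigree(spec: PedigreeSpec) -> Pedigree:
    """Simulate nuclear families, optionally chained over generations."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"I{counter[0]:06d}"

    # founder couples
    current_couples: list[tuple[str, str, str]] = []  # (father, mother, family)
    for f in range(spec.n_families):
        fam = f"FAM{f + 1:05d}"
        fa, mo = new_id(), new_id()
        rows.append({"id": fa, "father": MISSING_PARENT, "mother": MISSING_PARENT,
                     "sex": 1, "spouse": mo, "family": fam})
        rows.append({"id": mo, "father": MISSING_PARENT, "mother": MISSING_PARENT,
                     "sex": 0, "spouse": fa, "family": fam})
        current_couples.append((fa, mo, fam))

    for gen in range(1, spec.n_generations + 1):
        counts = _draw_offspring_counts(spec.offspring_dist, len(current_couples), rng)
        children: list[tuple[str, int, str]] = []  # (id, sex, family)
        for (fa, mo, fam), k in zip(current_couples, counts):
            for _ in range(int(k)):
                cid = new_id()
                sex = int(rng.integers(0, 2))
                rows.append({"id": cid, "father": fa, "mother": mo,
                             "sex": sex, "spouse": MISSING_PARENT, "family": fam})
                children.append((cid, sex, fam))
        if gen == spec.n_generations:
            break
        # pair a fraction of this generation's offspring into new couples,
        # opposite sexes, never within the same founding family
        n_pair = int(round(spec.couple_fraction * len(children)))
        males = [c for c in children if c[1] == 1]
        females = [c for c in children if c[1] == 0]
        rng.shuffle(males)
        rng.shuffle(females)
        next_couples: list[tuple[str, str, str]] = []
        by_id = {r["id"]: r for r in rows}
        for m, f in zip(males, females):
            if len(next_couples) * 2 >= n_pair:
                break
            if m[2] == f[2]:  # same founding family: skip this pairing
                continue
            by_id[m[0]]["spouse"] = f[0]
            by_id[f[0]]["spouse"] = m[0]
            next_couples.append((m[0], f[0], m[2]))
        current_couples = next_couples

    return Pedigree(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Genotype simulation (gene dropping)
# ---------------------------------------------------------------------------


def simulate_genotypes(
    ped: Pedigree,
    n_snps: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Founders drawn in Hardy-Weinberg equilibrium; offspring receive one
    allele from each parent (Mendelian gene dropping). Missing calls are
    masked uniformly at ``missing_rate`` after transmission, so the
    underlying inheritance is always Mendelian-consistent.
    """
    if not 0 < maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = ped.n
    mafs = rng.uniform(maf_low, maf_high, size=n_snps)

    t = ped.table
    idx = {i: k for k, i in enumerate(t["id"])}
    fa = np.array([idx.get(x, -1) for x in t["father"]])
    founder = fa < 0

    # store the two allele copies separately so transmission is exact
    a1 = np.zeros((n, n_snps), dtype=np.int8)
    a2 = np.zeros((n, n_snps), dtype=np.int8)
    nf = int(founder.sum())
    a1[founder] = rng.random((nf, n_snps)) < mafs
    a2[founder] = rng.random((nf, n_snps)) < mafs
    for i in np.flatnonzero(~founder):
        f, m = idx[t["father"].iat[i]], idx[t["mother"].iat[i]]
        pick_f = rng.integers(0, 2, size=n_snps, dtype=np.int8)
        pick_m = rng.integers(0, 2, size=n_snps, dtype=np.int8)
        a1[i] = np.where(pick_f == 0, a1[f], a2[f])
        a2[i] = np.where(pick_m == 0, a1[m], a2[m])

    dosages = (a1 + a2).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = -1
    snp_ids = [f"snp{j + 1:06d}" for j in range(n_snps)]
    return GenotypeMatrix(dosages, ped.ids, snp_ids,
                          sex=t["sex"].to_numpy(), family=list(t["family"]))


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------


def _standardized_dosages(geno: GenotypeMatrix, snp_idx: np.ndarray) -> np.ndarray:
    x = geno.as_float()[:, snp_idx]
    p = np.nanmean(x, axis=0) / 2.0
    x = np.where(np.isnan(x), 2 * p, x)
    return (x - 2 * p) / np.sqrt(2 * p * (1 - p))


def _scale_to_variance(v: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale a draw so its realized sample variance is exactly target_var."""
    sd = v.std()
    if sd == 0:
        return v if target_var == 0 else np.full_like(v, np.nan)
    return v * np.sqrt(target_var) / sd


def _family_effect_assignment(ped: Pedigree) -> tuple[list[tuple], np.ndarray]:
    """Unit list and per-individual unit index for the nuclear-family effect.

    Individuals belonging to two units (offspring in one, parent in
    another) take the draw of the unit in which they are offspring — the
    early environment the F component represents.
    """
    units = ped.nuclear_units()
    idx = {i: k for k, i in enumerate(ped.ids)}
    assign = np.full(ped.n, -1, dtype=int)
    for u, (fa, mo, kids) in enumerate(units):
        for member in (fa, mo):
            if assign[idx[member]] < 0:
                assign[idx[member]] = u
        for kid in kids:
            assign[idx[kid]] = u  # offspring unit wins
    return units, assign


def _draw_shared(groups: list, assign_idx: dict, n: int, var: float,
                 rng: np.random.Generator) -> np.ndarray:
    """One N(0, var) draw per group; ungrouped individuals draw independently."""
    draws = rng.normal(0.0, np.sqrt(var), size=len(groups))
    v = rng.normal(0.0, np.sqrt(var), size=n)
    for g, members in enumerate(groups):
        for m in members:
            v[assign_idx[m]] = draws[g]
    return v


def _simulate_components(
    ped: Pedigree,
    geno: GenotypeMatrix,
    spec: VarianceSpec,
    n_causal: int,
    rng: np.random.Generator,
    snp_idx: np.ndarray | None = None,
    snp_effects: np.ndarray | None = None,
    chol_A: np.ndarray | None = None,
    k_white: np.ndarray | None = None,
    shared_white: dict | None = None,
    resid_white: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Component vectors for one trait, each scaled to its exact variance.

    The optional *white* arguments supply pre-correlated standard-normal
    draws so that the bivariate generator can impose cross-trait
    correlations per component.
    """
    n = ped.n
    tv = spec.total_var
    out: dict[str, np.ndarray] = {}

    # G: additive score over standardized causal SNPs (polymorphic only)
    if snp_idx is None:
        poly = np.flatnonzero(geno.maf() > 0)
        if len(poly) < n_causal:
            raise ValueError("not enough polymorphic SNPs for the requested n_causal")
        snp_idx = rng.choice(poly, size=n_causal, replace=False)
    if snp_effects is None:
        snp_effects = rng.normal(size=n_causal)
    if spec.h2_g > 0:
        Z = _standardized_dosages(geno, snp_idx)
        g = Z @ snp_effects
        out["g"] = _scale_to_variance(g, spec.h2_g * tv)
    else:
        out["g"] = np.zeros(n)

    # K: pedigree-associated genetic effect, MVN with covariance ~ A_ped
    if spec.h2_p > 0:
        if chol_A is None:
            A = ped.additive_relationship()
            chol_A = np.linalg.cholesky(A + 1e-8 * np.eye(n))
        white = k_white if k_white is not None else rng.normal(size=n)
        out["k"] = _scale_to_variance(chol_A @ white, spec.h2_p * tv)
    else:
        out["k"] = np.zeros(n)

    # F / S / C: one draw per unit, scaled to exact variance
    idx = {i: k for k, i in enumerate(ped.ids)}
    shared_white = shared_white or {}

    def shared(groups: list[list[str]], frac: float, key: str) -> np.ndarray:
        if frac <= 0:
            return np.zeros(n)
        if key in shared_white:
            v = shared_white[key]
        else:
            v = _draw_shared(groups, idx, n, 1.0, rng)
        return _scale_to_variance(v, frac * tv)

    units, f_assign = _family_effect_assignment(ped)
    f_groups = [[] for _ in units]
    for i, u in enumerate(f_assign):
        if u >= 0:
            f_groups[u].append(ped.ids[i])
    out["f"] = shared(f_groups, spec.e2_f, "f")
    out["s"] = shared([g for g in ped.sibships() if len(g) >= 2], spec.e2_s, "s")
    out["c"] = shared([list(c) for c in ped.couples()], spec.e2_c, "c")

    resid_frac = spec.residual
    if resid_frac > 0:
        e = resid_white if resid_white is not None else rng.normal(size=n)
        out["e"] = _scale_to_variance(e, resid_frac * tv)
    else:
        out["e"] = np.zeros(n)
    return out


def _base_covariates(ped: Pedigree, rng: np.random.Generator) -> pd.DataFrame:
    age = rng.uniform(18.0, 90.0, size=ped.n)
    return pd.DataFrame({
        "id": ped.ids,
        "age": age,
        "sex": ped.table["sex"].to_numpy(),
    })


def _assemble(df: pd.DataFrame, comps: dict[str, np.ndarray], spec: VarianceSpec,
              trait: str) -> None:
    y = (spec.beta_age * df["age"].to_numpy()
         + spec.beta_sex * df["sex"].to_numpy()
         + comps["g"] + comps["k"] + comps["f"] + comps["s"] + comps["c"] + comps["e"])
    df[trait] = y
    for key, v in comps.items():
        df[f"{trait}__{key}"] = v
    total = sum(comps[k].var() for k in ("g", "k", "f", "s", "c", "e"))
    realized = {k: (comps[k].var() / total if total > 0 else 0.0)
                for k in ("g", "k", "f", "s", "c", "e")}
    df.attrs.setdefault("realized_fractions", {})[trait] = realized


def simulate_phenotypes(
    ped: Pedigree,
    geno: GenotypeMatrix,
    spec: VarianceSpec,
    n_causal: int = 500,
    seed: int = 0,
    trait: str = "trait",
) -> pd.DataFrame:
    """Simulate one trait: y = b_age*age + b_sex*sex + g + k + f + s + c + e.

    Each component vector is rescaled so its realized sample variance
    equals its specified share of ``total_var`` exactly; realized
    fractions (after scaling, relative to the realized total) are stored
    in ``df.attrs["realized_fractions"]``. Component columns
    ``<trait>__g`` ... ``<trait>__e`` are kept for diagnostics.
    """
    spec.validate()
    if n_causal > geno.n_snps:
        raise ValueError("n_causal exceeds the number of simulated SNPs")
    rng = np.random.default_rng(seed)
    df = _base_covariates(ped, rng)
    comps = _simulate_components(ped, geno, spec, n_causal, rng)
    _assemble(df, comps, spec, trait)
    return df


def simulate_bivariate_phenotypes(
    ped: Pedigree,
    geno: GenotypeMatrix,
    spec: BivariateSpec,
    n_causal: int = 500,
    seed: int = 0,
    traits: tuple[str, str] = ("trait1", "trait2"),
) -> pd.DataFrame:
    """Two traits over shared causal SNPs with per-component correlations.

    SNP effect sizes are drawn from a bivariate normal with correlation
    ``r_G``; the pedigree-genetic and residual white noises are likewise
    correlated at ``r_K`` and ``r_E``. Shared-environment draws are
    independent between traits.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = ped.n

    def corr_pairs(r: float, size: int) -> tuple[np.ndarray, np.ndarray]:
        cov = np.array([[1.0, r], [r, 1.0]])
        draw = rng.multivariate_normal([0.0, 0.0], cov, size=size,
                                       method="cholesky" if abs(r) < 1 else "eigh")
        return draw[:, 0], draw[:, 1]

    poly = np.flatnonzero(geno.maf() > 0)
    if len(poly) < n_causal:
        raise ValueError("not enough polymorphic SNPs for the requested n_causal")
    snp_idx = rng.choice(poly, size=n_causal, replace=False)
    eff1, eff2 = corr_pairs(spec.r_G, n_causal)
    kw1, kw2 = corr_pairs(spec.r_K, n)
    ew1, ew2 = corr_pairs(spec.r_E, n)

    need_A = spec.trait1.h2_p > 0 or spec.trait2.h2_p > 0
    chol_A = None
    if need_A:
        chol_A = np.linalg.cholesky(ped.additive_relationship() + 1e-8 * np.eye(n))

    df = _base_covariates(ped, rng)
    for t_name, t_spec, eff, kw, ew in (
        (traits[0], spec.trait1, eff1, kw1, ew1),
        (traits[1], spec.trait2, eff2, kw2, ew2),
    ):
        comps = _simulate_components(
            ped, geno, t_spec, n_causal, rng,
            snp_idx=snp_idx, snp_effects=eff, chol_A=chol_A,
            k_white=kw, resid_white=ew,
        )
        _assemble(df, comps, t_spec, t_name)
    return df


# ---------------------------------------------------------------------------
# Questionnaire items
# ---------------------------------------------------------------------------

# Latent-to-item loading and item noise SD, chosen so that simulated
# 6-item scales show internal consistency (Cronbach's alpha) in the
# mid-0.8s after 5-point discretisation.
DEFAULT_ITEM_LOADING = 1.1
DEFAULT_ITEM_NOISE = 0.9

_CISS_SUBSCALES = {"ToC": range(1, 17), "EoC": range(17, 33), "AoC": range(33, 49)}


def simulate_items(
    latent: pd.DataFrame,
    instrument: str,
    seed: int = 0,
    noise_sd: float = DEFAULT_ITEM_NOISE,
    loading: float = DEFAULT_ITEM_LOADING,
    trait_map: dict[str, str] | None = None,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Likert item responses (1-5) driven by latent trait scores.

    BRS: 6 items keyed to the ``resilience`` column, even-numbered items
    reverse-keyed (high resilience -> low raw response). CISS: 48 items in
    three fixed 16-item blocks keyed to ``ToC``, ``EoC``, ``AoC``. Raw
    responses are ``round(3 + loading*z + noise)`` clipped to [1, 5] where
    z is the standardized latent score. ``missing_rate`` masks item
    responses uniformly at random, so downstream prorated scoring yields
    the per-trait sample-size variation questionnaire data shows.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame({"id": latent["id"]})

    def z(col: str) -> np.ndarray:
        v = latent[col].to_numpy(dtype=float)
        return (v - v.mean()) / (v.std() or 1.0)

    def item(latent_z: np.ndarray, reverse: bool) -> np.ndarray:
        signal = -latent_z if reverse else latent_z
        cont = 3.0 + loading * signal + rng.normal(0.0, noise_sd, size=len(latent_z))
        return np.clip(np.rint(cont), 1, 5).astype(int)

    if instrument == "BRS":
        tmap = trait_map or {"resilience": "resilience"}
        lz = z(tmap["resilience"])
        for j in range(1, 7):
            out[f"item{j:02d}"] = item(lz, reverse=j % 2 == 0)
    elif instrument == "CISS":
        tmap = trait_map or {k: k for k in _CISS_SUBSCALES}
        for sub, rng_items in _CISS_SUBSCALES.items():
            lz = z(tmap[sub])
            for j in rng_items:
                out[f"item{j:02d}"] = item(lz, reverse=False)
    else:
        raise ValueError(f"unknown instrument {instrument!r}; expected 'BRS' or 'CISS'")
    if missing_rate > 0:
        cols = [c for c in out.columns if c.startswith("item")]
        vals = out[cols].to_numpy(dtype=float)
        vals[rng.random(vals.shape) < missing_rate] = np.nan
        out[cols] = vals
    return out


# ---------------------------------------------------------------------------
# Cohort writer
# ---------------------------------------------------------------------------


def write_cohort(
    outdir: str | Path,
    ped: Pedigree,
    geno: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    specs: dict | None = None,
) -> None:
    """Persist a simulated cohort: PLINK bed/bim/fam, pedigree and
    phenotype TSVs, and the ground-truth spec as a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plink(geno, outdir / "cohort")
    ped.to_tsv(outdir / "pedigree.tsv")
    phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    if specs is not None:
        payload = {
            k: asdict(v) if hasattr(v, "__dataclass_fields__") else v
            for k, v in specs.items()
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=2, default=str))
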