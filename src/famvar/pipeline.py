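"""End-to-end study replica on a synthetic cohort.

simulate -> genotype QC + MDS -> relationship matrices -> questionnaire
items and scoring -> adjusted phenotypic correlations -> univariate
variance decompositions (GK, full GKFSC, backward-selected) -> bivariate
genetic correlations -> report files.

Every stage persists its output in a standard format (PLINK fileset,
GCTA GRM triplet, TSV/JSON) so external tools can cross-validate any
intermediate, and a manifest records the seed and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    BivariateSpec,
    PedigreeSpec,
    VarianceSpec,
    simulate_genotypes,
    simulate_items,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_bivariate_phenotypes,
    write_cohort,
)
from .bivariate import bivariate_fit, lrt_correlation
from .genotypes import read_plink
from .matrices import build_environment_matrix, compute_grm, threshold_grm, write_grm
from .pedigree import Pedigree
from .qc import QCThresholds, apply_qc, compute_mds
from .reml import ModelSpec, backward_select, lrt_component, reml_fit, report_table
from .scoring import adjusted_pearson, score_brs, score_ciss

log = logging.getLogger("famvar")

# Trait regimes for the default demo: variance fractions follow the
# backward-selection estimates this pipeline is designed to recover
# (resilience: G/F; ToC and AoC: G/S/C; EoC: G/F/C).
DEFAULT_TRAIT_SPECS = {
    "resilience": VarianceSpec(h2_g=0.06, e2_f=0.05),
    "ToC": VarianceSpec(h2_g=0.14, e2_s=0.10, e2_c=0.18),
    "EoC": VarianceSpec(h2_g=0.15, e2_f=0.05, e2_c=0.14),
    "AoC": VarianceSpec(h2_g=0.15, e2_s=0.07, e2_c=0.18),
}


@dataclass
class RunConfig:
    """Configuration for one synthetic-study run."""

    outdir: str = "famvar_run"
    seed: int = 0
    # simulation block (used when no input paths are given)
    pedigree_spec: PedigreeSpec = field(default_factory=lambda: PedigreeSpec(n_families=250))
    trait_specs: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_SPECS))
    bivariate_pairs: tuple = (("resilience", "EoC", -0.8),)
    n_snps: int = 5000
    n_causal: int = 500
    genotype_missing_rate: float = 0.005
    # real-input paths (mutually exclusive with the simulation block)
    plink_prefix: str | None = None
    pedigree_path: str | None = None
    phenotype_path: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    n_mds: int = 4
    traits: tuple = ("resilience", "ToC", "EoC", "AoC")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "pedigree_spec" in d and isinstance(d["pedigree_spec"], dict):
            ps = dict(d["pedigree_spec"])
            if isinstance(ps.get("offspring_dist"), list):
                ps["offspring_dist"] = tuple(ps["offspring_dist"])
            d["pedigree_spec"] = PedigreeSpec(**ps)
        if "trait_specs" in d:
            d["trait_specs"] = {
                k: VarianceSpec(**v) if isinstance(v, dict) else v
                for k, v in d["trait_specs"].items()
            }
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCThresholds(**d["qc"])
        if "bivariate_pairs" in d:
            d["bivariate_pairs"] = tuple(tuple(p) for p in d["bivariate_pairs"])
        return cls(**d)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _simulate_cohort(config: RunConfig, outdir: Path):
    spec = config.pedigree_spec
    spec.seed = config.seed
    ped = simulate_pedigree(spec)
    geno = simulate_genotypes(
        ped, config.n_snps, missing_rate=config.genotype_missing_rate,
        seed=config.seed + 1,
    )
    # traits: bivariate pairs share causal SNPs with the configured r_G,
    # remaining traits are simulated independently
    pheno = None
    done = set()
    offset = 10
    for t1, t2, r_g in config.bivariate_pairs:
        bspec = BivariateSpec(config.trait_specs[t1], config.trait_specs[t2], r_G=r_g)
        df = simulate_bivariate_phenotypes(
            ped, geno, bspec, n_causal=config.n_causal,
            seed=config.seed + offset, traits=(t1, t2),
        )
        offset += 10
        pheno = df if pheno is None else _merge_traits(pheno, df)
        done.update((t1, t2))
    for t in config.traits:
        if t in done:
            continue
        df = simulate_phenotypes(
            ped, geno, config.trait_specs[t], n_causal=config.n_causal,
            seed=config.seed + offset, trait=t,
        )
        offset += 10
        pheno = df if pheno is None else _merge_traits(pheno, df)
    write_cohort(outdir / "cohort", ped, geno, pheno,
                 specs={"pedigree": spec, **config.trait_specs})
    return ped, geno, pheno


def _merge_traits(base: pd.DataFrame, extra: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in extra.columns if c not in ("id", "age", "sex")]
    out = base.merge(extra[["id"] + cols], on="id", validate="1:1")
    out.attrs["realized_fractions"] = {
        **base.attrs.get("realized_fractions", {}),
        **extra.attrs.get("realized_fractions", {}),
    }
    return out


def run_study(config: RunConfig) -> dict:
    """Run the full pipeline; returns a result bundle (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if config.plink_prefix is not None:
            geno = read_plink(config.plink_prefix)
            ped = Pedigree.from_tsv(config.pedigree_path)
            pheno = pd.read_csv(config.phenotype_path, sep="\t", dtype={"id": str})
        else:
            ped, geno, pheno = _simulate_cohort(config, outdir)
        log.info("cohort: %d individuals, %d SNPs", geno.n_individuals, geno.n_snps)

        stage = "qc"
        geno_qc, qc_report = apply_qc(geno, config.qc)
        qc_report.to_json(outdir / "qc_report.json")
        mds = compute_mds(geno_qc, n_components=config.n_mds)
        # analysis set = individuals surviving genotype QC, in genotype order
        attrs = dict(pheno.attrs)
        pheno = pheno.set_index("id").loc[geno_qc.ids].reset_index()
        pheno.attrs.update(attrs)
        analysis_ids = list(pheno["id"])

        stage = "matrices"
        G = compute_grm(geno_qc)
        K = threshold_grm(G)
        F = build_environment_matrix(ped, "family")
        S = build_environment_matrix(ped, "sibling")
        C = build_environment_matrix(ped, "couple")
        for rm, name in ((G, "G"), (K, "K"), (F, "F"), (S, "S"), (C, "C")):
            write_grm(rm, outdir / f"matrix_{name}")
        matrices = {"G": G, "K": K, "F": F, "S": S, "C": C}

        stage = "scoring"
        # emulate the questionnaire round-trip: latent traits -> items -> scores
        scored = pd.DataFrame({"id": pheno["id"]})
        if "resilience" in pheno.columns:
            items_brs = simulate_items(pheno, "BRS", seed=config.seed + 100)
            items_brs.to_csv(outdir / "items_brs.tsv", sep="\t", index=False)
            scored["resilience_scored"] = score_brs(items_brs).to_numpy()
        if {"ToC", "EoC", "AoC"} <= set(pheno.columns):
            items_ciss = simulate_items(pheno, "CISS", seed=config.seed + 101)
            items_ciss.to_csv(outdir / "items_ciss.tsv", sep="\t", index=False)
            scored = scored.join(score_ciss(items_ciss).reset_index(drop=True))

        stage = "table1"
        covars = pheno[["age", "sex"]]
        t1_rows = {}
        for i, a in enumerate(config.traits):
            for b in config.traits[i + 1:]:
                r, se = adjusted_pearson(pheno[a], pheno[b], covars)
                t1_rows[f"{a}~{b}"] = {"r": round(r, 4), "se": round(se, 4)}
        table1 = pd.DataFrame.from_dict(t1_rows, orient="index")
        table1.to_csv(outdir / "table1.tsv", sep="\t")

        stage = "univariate"
        X = _design(pheno, mds)
        table2, fits = {}, {}
        for t in config.traits:
            y = pheno[t].to_numpy()
            fit_gk = reml_fit(y, X, [G, K], ids=analysis_ids)
            fit_full = reml_fit(y, X, [G, K, F, S, C], ids=analysis_ids)
            sel_spec, sel_fit, trace = backward_select(y, X, matrices, ids=analysis_ids)
            fits[t] = {"GK": fit_gk, "GKFSC": fit_full, f"sel:{sel_spec.components}": sel_fit}
            df = report_table(fits[t])
            table2[t] = df
            df.attrs["raw"]["selection_trace"] = trace
        pd.concat(table2, names=["trait", "model"]).to_csv(outdir / "table2.tsv", sep="\t")

        stage = "bivariate"
        covar_df = pd.DataFrame(
            np.column_stack([pheno[["age", "sex"]].to_numpy(), mds_aligned(mds, pheno)]),
            index=pheno["id"],
            columns=["age", "sex"] + [f"MDS{k+1}" for k in range(config.n_mds)],
        )
        table3 = {}
        for t1, t2, r_true in config.bivariate_pairs:
            y1 = pd.Series(pheno[t1].to_numpy(), index=pheno["id"])
            y2 = pd.Series(pheno[t2].to_numpy(), index=pheno["id"])
            bfit = bivariate_fit(y1, y2, covar_df, G, K)
            rec = {"r_G_true": r_true}
            for comp in ("G", "K"):
                est = bfit.correlations.get(comp)
                if est is None:
                    rec[f"r_{comp}"] = None
                else:
                    lrt = lrt_correlation(bfit, comp, y1, y2, covar_df, G, K)
                    rec[f"r_{comp}"] = {"value": round(est[0], 4), "se": round(est[1], 4),
                                        "p": round(lrt.p, 5)}
            table3[f"{t1}~{t2}"] = rec
        (outdir / "table3.json").write_text(json.dumps(table3, indent=2))

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "famvar_version": __version__,
            "config_hash": _config_hash(config),
            "config": json.loads(json.dumps(asdict(config), default=str)),
            "qc": {"snps_retained": qc_report.snps_retained,
                   "individuals_retained": qc_report.individuals_retained},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as err:  # noqa: BLE001 - stage context is part of the contract
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    return {
        "pedigree": ped,
        "qc_report": qc_report,
        "mds": mds,
        "matrices": matrices,
        "phenotypes": pheno,
        "scored": scored,
        "table1": table1,
        "table2": table2,
        "table3": table3,
        "fits": fits,
        "manifest": manifest,
    }


def plot_variance_fractions(fits: dict, path=None):
    """Stacked-bar chart of variance fractions per trait.

    ``fits`` maps a trait label to a FitResult (typically the backward-
    selected model). Components are stacked bottom-up in G, K, F, S, C
    order with the residual on top. Returns the matplotlib figure;
    writes to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = ["G", "K", "F", "S", "C", "residual"]
    colors = {"G": "#4c72b0", "K": "#55a868", "F": "#c44e52",
              "S": "#8172b2", "C": "#ccb974", "residual": "#cccccc"}
    labels = list(fits)
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(labels), 4))
    bottoms = np.zeros(len(labels))
    for comp in order:
        vals = np.array([fits[t].fractions.get(comp, 0.0) for t in labels])
        if (vals > 0).any():
            ax.bar(labels, vals, bottom=bottoms, color=colors[comp], label=comp)
        bottoms += vals
    ax.set_ylabel("fraction of phenotypic variance")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def mds_aligned(mds: pd.DataFrame, pheno: pd.DataFrame) -> np.ndarray:
    m = mds.set_index("id").loc[pheno["id"]]
    return m.to_numpy(dtype=float)


def _design(pheno: pd.DataFrame, mds: pd.DataFrame) -> np.ndarray:
    return np.column_stack([
        pheno["age"].to_numpy(dtype=float),
        pheno["sex"].to_numpy(dtype=float),
        mds_aligned(mds, pheno),
    ])
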