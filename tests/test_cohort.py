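"""Phenotype and item simulators: variance structure and determinism."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import famvar as fv


@pytest.fixture(scope="module")
def couple_cohort():
    """500 couples with one offspring each (to keep couples phenotyped)."""
    return fv.simulate_pedigree(fv.PedigreeSpec(n_families=500, offspring_dist=1, seed=11))


class TestSimulatePhenotypes:
    def test_null_spec_gives_iid_noise(self, family_cohort):
        """All fractions zero: sibling phenotype correlation is null."""
        ped, geno, _ = family_cohort
        spec = fv.VarianceSpec(beta_age=0.02, beta_sex=0.5)
        ph = fv.simulate_phenotypes(ped, geno, spec, n_causal=100, seed=1, trait="y")
        resid = ph["y"] - 0.02 * ph["age"] - 0.5 * ph["sex"]
        idx = {i: k for k, i in enumerate(ph["id"])}
        pairs = ped.sib_pairs()
        a = np.array([resid.iloc[idx[p[0]]] for p in pairs])
        b = np.array([resid.iloc[idx[p[1]]] for p in pairs])
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(pairs))

    def test_pure_genetic_trait_equals_score(self, family_cohort):
        """h2_g = 1 with all SNPs causal: the trait minus fixed effects is
        exactly the genetic score (zero residual)."""
        ped, geno, _ = family_cohort
        spec = fv.VarianceSpec(h2_g=1.0)
        ph = fv.simulate_phenotypes(ped, geno, spec, n_causal=geno.n_snps, seed=2, trait="y")
        np.testing.assert_allclose(ph["y"], ph["y__g"], atol=1e-12)
        assert ph["y__e"].abs().max() == 0

    def test_couple_sharing_variance(self, couple_cohort):
        """e2_c = 0.5 only: phenotype correlation across couples near 0.5."""
        ped = couple_cohort
        geno = fv.simulate_genotypes(ped, 50, maf_low=0.3, seed=12)
        spec = fv.VarianceSpec(e2_c=0.5)
        ph = fv.simulate_phenotypes(ped, geno, spec, n_causal=10, seed=13, trait="y")
        idx = {i: k for k, i in enumerate(ph["id"])}
        couples = ped.couples()
        a = np.array([ph["y"].iloc[idx[c[0]]] for c in couples])
        b = np.array([ph["y"].iloc[idx[c[1]]] for c in couples])
        r = np.corrcoef(a, b)[0, 1]
        se = (1 - 0.5**2) / np.sqrt(len(couples))
        assert r == pytest.approx(0.5, abs=3 * se)

    def test_realized_fractions_match_spec(self, family_cohort):
        """Component vectors are rescaled to their exact variance shares."""
        ped, geno, _ = family_cohort
        spec = fv.VarianceSpec(h2_g=0.2, e2_s=0.1, e2_c=0.15)
        ph = fv.simulate_phenotypes(ped, geno, spec, n_causal=200, seed=3, trait="y")
        realized = ph.attrs["realized_fractions"]["y"]
        assert realized["g"] == pytest.approx(0.2, abs=1e-9)
        assert realized["s"] == pytest.approx(0.1, abs=1e-9)
        assert realized["c"] == pytest.approx(0.15, abs=1e-9)
        assert realized["e"] == pytest.approx(0.55, abs=1e-9)

    def test_overfull_spec_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            fv.VarianceSpec(h2_g=0.6, e2_f=0.6).validate()

    def test_deterministic(self, family_cohort):
        ped, geno, _ = family_cohort
        spec = fv.VarianceSpec(h2_g=0.3)
        a = fv.simulate_phenotypes(ped, geno, spec, n_causal=50, seed=9, trait="y")
        b = fv.simulate_phenotypes(ped, geno, spec, n_causal=50, seed=9, trait="y")
        pd.testing.assert_frame_equal(a, b)


class TestSimulateBivariate:
    def test_perfect_correlation_duplicates_trait(self, family_cohort):
        ped, geno, _ = family_cohort
        spec = fv.BivariateSpec(
            fv.VarianceSpec(h2_g=0.4), fv.VarianceSpec(h2_g=0.4), r_G=1.0, r_E=1.0
        )
        ph = fv.simulate_bivariate_phenotypes(ped, geno, spec, n_causal=100, seed=4)
        np.testing.assert_allclose(ph["trait1"], ph["trait2"], atol=1e-9)

    def test_zero_genetic_correlation(self, family_cohort):
        ped, geno, _ = family_cohort
        spec = fv.BivariateSpec(
            fv.VarianceSpec(h2_g=0.5), fv.VarianceSpec(h2_g=0.5), r_G=0.0
        )
        ph = fv.simulate_bivariate_phenotypes(ped, geno, spec, n_causal=200, seed=5)
        r = np.corrcoef(ph["trait1__g"], ph["trait2__g"])[0, 1]
        assert abs(r) < 3 / np.sqrt(ped.n)

    def test_strong_negative_genetic_correlation(self):
        """r_G = -0.8: sample correlation of the simulated genetic-value
        vectors within 3 SE of the target at N = 2000."""
        ped = fv.simulate_pedigree(fv.PedigreeSpec(n_families=500, offspring_dist=2, seed=6))
        geno = fv.simulate_genotypes(ped, 800, maf_low=0.1, seed=7)
        spec = fv.BivariateSpec(
            fv.VarianceSpec(h2_g=0.3), fv.VarianceSpec(h2_g=0.3), r_G=-0.8
        )
        ph = fv.simulate_bivariate_phenotypes(ped, geno, spec, n_causal=300, seed=8)
        r = np.corrcoef(ph["trait1__g"], ph["trait2__g"])[0, 1]
        se = (1 - 0.8**2) / np.sqrt(ped.n)
        assert r == pytest.approx(-0.8, abs=3 * se)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError, match="r_G"):
            fv.BivariateSpec(fv.VarianceSpec(), fv.VarianceSpec(), r_G=1.5).validate()


@pytest.fixture(scope="module")
def latent():
    rng = np.random.default_rng(20)
    n = 1000
    return pd.DataFrame({
        "id": [f"i{k}" for k in range(n)],
        "resilience": rng.normal(size=n),
        "ToC": rng.normal(size=n),
        "EoC": rng.normal(size=n),
        "AoC": rng.normal(size=n),
    })


class TestSimulateItems:

    def test_zero_noise_score_is_monotone_in_latent(self, latent):
        """Without item noise the scored scale is a monotone transform of
        the latent trait: no discordant pairs (ties allowed by the 5-point
        discretization)."""
        items = fv.simulate_items(latent, "BRS", seed=1, noise_sd=0.0)
        score = fv.score_brs(items).to_numpy()
        order = np.argsort(latent["resilience"].to_numpy())
        assert (np.diff(score[order]) >= -1e-12).all()

    def test_extreme_latent_keying(self, latent):
        """A latent maximum yields odd items 5 / even items 1 -> score 5."""
        items = fv.simulate_items(latent, "BRS", seed=2, noise_sd=0.0, loading=50.0)
        top = int(np.argmax(latent["resilience"].to_numpy()))
        row = items.iloc[top]
        assert all(row[f"item{j:02d}"] == (5 if j % 2 else 1) for j in range(1, 7))
        assert fv.score_brs(items).iloc[top] == 5.0

    def test_default_noise_recovers_rank_order(self, latent):
        items = fv.simulate_items(latent, "BRS", seed=3)
        rho = spearmanr(latent["resilience"], fv.score_brs(items)).statistic
        assert rho > 0.9

    def test_brs_internal_consistency_band(self, latent):
        """Cronbach's alpha of the six simulated items falls in the
        0.80-0.91 band the generator is calibrated to."""
        items = fv.simulate_items(latent, "BRS", seed=4)
        x = items[[f"item{j:02d}" for j in range(1, 7)]].to_numpy(float)
        x[:, 1::2] = 6 - x[:, 1::2]
        k = x.shape[1]
        alpha = k / (k - 1) * (1 - x.var(0, ddof=1).sum() / x.sum(1).var(ddof=1))
        assert 0.80 <= alpha <= 0.91

    def test_ciss_blocks_track_their_traits(self, latent):
        items = fv.simulate_items(latent, "CISS", seed=5)
        scores = fv.score_ciss(items)
        for sub in ("ToC", "EoC", "AoC"):
            rho = spearmanr(latent[sub], scores[sub]).statistic
            assert rho > 0.9
        # cross-trait: no leakage between blocks
        rho_x = abs(spearmanr(latent["ToC"], scores["EoC"]).statistic)
        assert rho_x < 0.15

    def test_unknown_instrument_rejected(self, latent):
        with pytest.raises(ValueError, match="instrument"):
            fv.simulate_items(latent, "GHQ", seed=0)

    def test_item_missingness_propagates_to_scores(self, latent):
        """Item missingness yields missing scores exactly where more than
        half a scale's items are absent (prorated otherwise)."""
        items = fv.simulate_items(latent, "BRS", seed=6, missing_rate=0.3)
        x = items[[f"item{j:02d}" for j in range(1, 7)]].to_numpy(float)
        assert np.isnan(x).mean() == pytest.approx(0.3, abs=0.03)
        scores = fv.score_brs(items)
        n_missing_items = np.isnan(x).sum(axis=1)
        assert np.isnan(scores.to_numpy()[n_missing_items > 3]).all()
        assert (~np.isnan(scores.to_numpy()[n_missing_items == 0])).all()


class TestCohortWriter:
    def test_writes_complete_fileset(self, family_cohort, tmp_path):
        ped, geno, _ = family_cohort
        spec = fv.VarianceSpec(h2_g=0.3)
        ph = fv.simulate_phenotypes(ped, geno, spec, n_causal=100, seed=1, trait="y")
        fv.write_cohort(tmp_path / "c", ped, geno, ph, specs={"y": spec})
        for name in ("cohort.bed", "cohort.bim", "cohort.fam",
                     "pedigree.tsv", "phenotypes.tsv", "truth.json"):
            assert (tmp_path / "c" / name).exists()
        truth = json.loads((tmp_path / "c" / "truth.json").read_text())
        assert truth["y"]["h2_g"] == 0.3
        back = fv.read_plink(tmp_path / "c" / "cohort")
        assert np.array_equal(back.dosages, geno.dosages)
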