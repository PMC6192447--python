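"""REML estimator: closed-form and grid-search oracles, LRT, selection."""

import numpy as np
import pytest
from scipy.stats import chi2

import famvar as fv
def grid_search_reml(y, X, mats, step=0.01):
    """Independent oracle: evaluate the restricted likelihood directly on
    a dense grid over variance-fraction space.

    For a fixed fraction vector f the covariance is V = s2 * R(f) with
    R(f) = sum f_c M_c + (1 - sum f) I; the overall scale s2 maximizes
    the restricted likelihood in closed form at y'P_R y / (n - p), so
    only the fractions are gridded.
    """
    from scipy import linalg as sla

    y = np.asarray(y, float)
    if X is None:
        X = np.ones((len(y), 1))
    n, p = X.shape
    k = len(mats)
    fracs = np.arange(0.0, 1.0 + 1e-9, step)
    best = (-np.inf, None, None)
    import itertools

    for combo in itertools.product(fracs, repeat=k):
        if sum(combo) > 1.0 - step / 2:  # leave residual variance positive
            continue
        R = (1.0 - sum(combo)) * np.eye(n)
        for f, M in zip(combo, mats):
            R = R + f * M
        try:
            c = sla.cho_factor(R, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            continue
        logdet_R = 2 * np.sum(np.log(np.diag(c[0])))
        Riy = sla.cho_solve(c, y, check_finite=False)
        RiX = sla.cho_solve(c, X, check_finite=False)
        XtRiX = X.T @ RiX
        cx = sla.cho_factor(XtRiX, lower=True, check_finite=False)
        logdet_X = 2 * np.sum(np.log(np.diag(cx[0])))
        beta = sla.cho_solve(cx, X.T @ Riy, check_finite=False)
        yPy = float(y @ Riy) - float((X.T @ Riy) @ beta)
        if yPy <= 0:
            continue
        s2 = yPy / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(s2) + logdet_R + logdet_X + (n - p)
            + (n - p) * np.log(2 * np.pi)
        )
        if ll > best[0]:
            best = (ll, combo, s2)
    return best


class TestRemlFitOracles:
    def test_no_matrices_equals_ols(self):
        rng = np.random.default_rng(0)
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 2.0] + rng.normal(0, 1.5, n)
        fit = fv.reml_fit(y, X, [])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.variances["residual"] == pytest.approx(resid @ resid / (n - 2), rel=1e-12)

    def test_identity_component_flagged_unidentifiable(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=40)
        I_mat = fv.RelationshipMatrix(np.eye(40), [f"i{k}" for k in range(40)], "S")
        fit = fv.reml_fit(y, None, [I_mat])
        assert not fit.identifiable

    def test_balanced_sib_anova_closed_form(self, sib_design):
        """Balanced one-way design: REML equals the ANOVA method-of-moments
        components sigma2_s = (MSB - MSW)/2, sigma2_e = MSW to 1e-6."""
        y, S, fam = sib_design
        a = fam.max() + 1
        fit = fv.reml_fit(y, None, [S], tol=1e-12)
        gm = y.reshape(a, 2).mean(axis=1)
        MSB = 2 * ((gm - y.mean()) ** 2).sum() / (a - 1)
        MSW = ((y.reshape(a, 2) - gm[:, None]) ** 2).sum() / a
        assert fit.variances["S"] == pytest.approx((MSB - MSW) / 2, abs=1e-6)
        assert fit.variances["residual"] == pytest.approx(MSW, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_component_grid_search_oracle(self, seed):
        """N = 50 toy with sibling + couple structure: the AI-REML optimum
        matches a dense direct grid search of the restricted likelihood
        within grid resolution."""
        rng = np.random.default_rng(seed)
        ped = fv.simulate_pedigree(fv.PedigreeSpec(n_families=10, offspring_dist=3, seed=seed))
        S = fv.build_environment_matrix(ped, "sibling")
        C = fv.build_environment_matrix(ped, "couple")
        n = ped.n
        idx = {i: k for k, i in enumerate(ped.ids)}
        s_eff = np.zeros(n)
        for g, sib in enumerate(ped.sibships()):
            val = rng.normal(0, np.sqrt(0.35))
            for m in sib:
                s_eff[idx[m]] = val
        c_eff = np.zeros(n)
        for a, b in ped.couples():
            val = rng.normal(0, np.sqrt(0.3))
            c_eff[idx[a]] = c_eff[idx[b]] = val
        y = s_eff + c_eff + rng.normal(0, np.sqrt(0.35), n)
        fit = fv.reml_fit(y, None, [S, C], ids=ped.ids, tol=1e-10)
        ll_grid, combo, total = grid_search_reml(y, None, [S.align(ped.ids), C.align(ped.ids)])
        assert fit.logL >= ll_grid - 1e-6
        total_hat = sum(fit.variances.values())
        assert fit.fractions["S"] == pytest.approx(combo[0], abs=0.011)
        assert fit.fractions["C"] == pytest.approx(combo[1], abs=0.011)

    def test_permutation_invariance(self, family_cohort):
        ped, geno, mats = family_cohort
        spec = fv.VarianceSpec(h2_g=0.3, e2_s=0.2)
        ph = fv.simulate_phenotypes(ped, geno, spec, n_causal=100, seed=5, trait="y")
        ids = list(ph["id"])
        y = ph["y"].to_numpy()
        fit = fv.reml_fit(y, None, [mats["G"], mats["S"]], ids=ids, tol=1e-9)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        fit_p = fv.reml_fit(y[perm], None, [mats["G"], mats["S"]],
                            ids=[ids[i] for i in perm], tol=1e-9)
        for key in fit.fractions:
            assert fit_p.fractions[key] == pytest.approx(fit.fractions[key], abs=1e-5)
        assert fit_p.logL == pytest.approx(fit.logL, abs=1e-5)

    def test_full_model_dominates_nested(self, family_cohort):
        ped, geno, mats = family_cohort
        spec = fv.VarianceSpec(h2_g=0.25, e2_c=0.2)
        ph = fv.simulate_phenotypes(ped, geno, spec, n_causal=100, seed=6, trait="y")
        ids = list(ph["id"])
        y = ph["y"].to_numpy()
        full = fv.reml_fit(y, None, [mats["G"], mats["S"], mats["C"]], ids=ids)
        for drop in ("G", "S", "C"):
            keep = [mats[c] for c in ("G", "S", "C") if c != drop]
            red = fv.reml_fit(y, None, keep, ids=ids)
            assert full.logL >= red.logL - 1e-4

    def test_misaligned_ids_rejected(self, family_cohort):
        _, _, mats = family_cohort
        y = np.random.default_rng(0).normal(size=10)
        with pytest.raises(KeyError, match="absent"):
            fv.reml_fit(y, None, [mats["G"]], ids=[f"missing{k}" for k in range(10)])

    def test_singular_design_rejected(self):
        y = np.random.default_rng(0).normal(size=20)
        X = np.ones((20, 2))
        with pytest.raises(ValueError, match="singular"):
            fv.reml_fit(y, X, [])

    def test_fraction_sum_and_bounds(self, family_cohort):
        ped, geno, mats = family_cohort
        ph = fv.simulate_phenotypes(ped, geno, fv.VarianceSpec(h2_g=0.3),
                                    n_causal=100, seed=7, trait="y")
        fit = fv.reml_fit(ph["y"].to_numpy(), None,
                          [mats["G"], mats["K"], mats["C"]], ids=list(ph["id"]))
        assert all(v >= 0 for v in fit.fractions.values())
        assert sum(fit.fractions.values()) == pytest.approx(1.0, abs=1e-9)


class TestLrt:
    def test_equal_loglik_gives_half(self):
        f1 = _fake_fit(("G", "S"), -100.0)
        f0 = _fake_fit(("G",), -100.0)
        res = fv.lrt_component(f1, f0)
        assert res.statistic == 0.0
        assert res.p == 0.5

    def test_chi_square_tail_value(self):
        """Statistic 3.84 -> p = 0.5 * P(chi2_1 > 3.84) ~ 0.0250."""
        f1 = _fake_fit(("G", "S"), -98.08)
        f0 = _fake_fit(("G",), -100.0)
        res = fv.lrt_component(f1, f0)
        assert res.statistic == pytest.approx(3.84)
        assert res.p == pytest.approx(0.5 * chi2.sf(3.84, 1), rel=1e-9)
        assert res.p == pytest.approx(0.0250, abs=2e-4)

    def test_non_nested_rejected(self):
        f1 = _fake_fit(("G", "S"), -10.0)
        f0 = _fake_fit(("C",), -11.0)
        with pytest.raises(ValueError, match="drop exactly one"):
            fv.lrt_component(f1, f0)
        f2 = _fake_fit(("G",), -11.0)
        with pytest.raises(ValueError):
            fv.lrt_component(_fake_fit(("G", "S", "C"), -10.0), f2)


def _fake_fit(components, logL):
    return fv.FitResult(
        components=components,
        variances={}, fractions={c: 0.1 for c in components}, ses={},
        logL=logL, n_used=100, converged=True,
    )


class TestBackwardSelect:
    def test_couple_only_model_selected(self):
        """Generating model with only a couple effect: C is retained and
        the trace shrinks strictly."""
        ped = fv.simulate_pedigree(fv.PedigreeSpec(n_families=300, offspring_dist=1, seed=30))
        geno = fv.simulate_genotypes(ped, 700, maf_low=0.1, seed=31)
        G = fv.compute_grm(geno)
        mats = {
            "G": G,
            "S": fv.build_environment_matrix(ped, "sibling"),
            "C": fv.build_environment_matrix(ped, "couple"),
        }
        ph = fv.simulate_phenotypes(ped, geno, fv.VarianceSpec(e2_c=0.3),
                                    n_causal=100, seed=32, trait="y")
        spec, fit, trace = fv.backward_select(ph["y"].to_numpy(), None, mats,
                                              ids=list(ph["id"]))
        assert "C" in spec.components
        assert len(trace) <= len(mats) + 1
        sizes = [len(r["components"]) for r in trace]
        assert sizes == sorted(sizes, reverse=True)
        assert len(set(sizes)) == len(sizes)

    def test_all_null_usually_empties(self, family_cohort):
        """Pure-noise trait: selection ends empty (or with a single
        alpha-level false positive)."""
        ped, geno, mats = family_cohort
        rng = np.random.default_rng(33)
        y = rng.normal(size=ped.n)
        spec, fit, trace = fv.backward_select(y, None, mats, ids=ped.ids)
        assert len(spec.components) <= 1

    def test_trace_records_decisions(self, family_cohort):
        ped, geno, mats = family_cohort
        ph = fv.simulate_phenotypes(ped, geno, fv.VarianceSpec(h2_g=0.4),
                                    n_causal=100, seed=34, trait="y")
        _, _, trace = fv.backward_select(
            ph["y"].to_numpy(), None, {"G": mats["G"], "S": mats["S"]}, ids=ped.ids
        )
        for r in trace:
            assert set(r) >= {"components", "logL", "p_values", "removed"}


class TestReportTable:
    def test_empty_map(self):
        df = fv.report_table({})
        assert len(df) == 0

    def test_cell_formatting(self):
        fit = fv.FitResult(
            components=("G",), variances={"G": 0.14, "residual": 0.86},
            fractions={"G": 0.14, "residual": 0.86}, ses={"G": 0.03, "residual": 0.05},
            logL=-12.5, n_used=100, converged=True,
        )
        df = fv.report_table({"G": fit})
        assert df.loc["G", "G"] == "0.14 (0.03)"

    def test_three_row_structure(self, family_cohort):
        """GK / full / selected rows mirror the reporting layout."""
        ped, geno, mats = family_cohort
        ph = fv.simulate_phenotypes(ped, geno, fv.VarianceSpec(h2_g=0.35, e2_c=0.25),
                                    n_causal=100, seed=35, trait="y")
        y = ph["y"].to_numpy()
        gk = fv.reml_fit(y, None, [mats["G"], mats["K"]], ids=ped.ids)
        full = fv.reml_fit(y, None, [mats[c] for c in "GKFSC"], ids=ped.ids)
        spec, sel, _ = fv.backward_select(y, None, mats, ids=ped.ids)
        df = fv.report_table({"GK": gk, "GKFSC": full, f"sel:{spec.components}": sel})
        assert list(df.index) == ["GK", "GKFSC", f"sel:{spec.components}"]
        assert df.loc["GK", "F"] == ""
        assert "raw" in df.attrs
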