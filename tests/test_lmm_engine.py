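import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tpemet import lmm_engine as lmm
from tpemet.lmm_engine import (
    ModelSpec,
    RandomTerm,
    fit_blues,
    fit_gibbs,
    fit_reml,
    heritability,
    model_template,
    phenotypic_variance,
)


def one_way(g=8, n=6, sd_g=1.0, sd_e=0.7, seed=3):
    rng = np.random.default_rng(seed)
    eff = rng.normal(0, sd_g, g)
    rows = [
        {"grp": f"g{i}", "y": 2.0 + eff[i] + rng.normal(0, sd_e)}
        for i in range(g)
        for _ in range(n)
    ]
    return pd.DataFrame(rows)


ONE_WAY_SPEC = ModelSpec(response="y", fixed=(), random=(RandomTerm("G", ("grp",)),))


class TestFitREML:
    def test_balanced_one_way_equals_anova(self):
        g, n = 8, 6
        df = one_way(g, n)
        vc = fit_reml(df, ONE_WAY_SPEC)
        means = df.groupby("grp")["y"].mean()
        msw = df.groupby("grp")["y"].var(ddof=1).mean()
        msb = n * means.var(ddof=1)
        assert vc.components["G"] == pytest.approx((msb - msw) / n, abs=1e-5)
        assert vc.residual == pytest.approx(msw, abs=1e-5)

    def test_within_group_constant_degenerate(self):
        df = one_way()
        means = df.groupby("grp")["y"].mean()
        df["y"] = df["grp"].map(means)
        vc = fit_reml(df, ONE_WAY_SPEC)
        assert vc.residual == 0.0
        assert vc.components["G"] == pytest.approx(means.var(ddof=1), rel=1e-10)

    def test_three_by_two_by_two_grid_oracle(self):
        """REML equals a brute-force restricted-likelihood maximizer to 1e-4."""
        rng = np.random.default_rng(7)
        rows = [
            {
                "geno": f"g{gi}",
                "site": f"s{s}",
                "y": 4.0 + 0.3 * gi + rng.normal(0, 0.5),
            }
            for gi in range(3)
            for s in range(2)
            for _ in range(2)
        ]
        df = pd.DataFrame(rows)
        spec = ModelSpec(
            response="y",
            fixed=("site",),
            random=(RandomTerm("G", ("geno",)), RandomTerm("GE", ("geno", "site"))),
        )
        vc = fit_reml(df, spec)

        # independent dense-V restricted likelihood, refined grid search
        y = df["y"].to_numpy()
        X = np.column_stack([np.ones(12), (df["site"] == "s1").astype(float)])
        Zg = pd.get_dummies(df["geno"]).to_numpy(float)
        Zge = pd.get_dummies(df["geno"] + df["site"]).to_numpy(float)

        def neg2lr(vg, vge, ve):
            V = vg * Zg @ Zg.T + vge * Zge @ Zge.T + ve * np.eye(12)
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
            return (
                np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1] + y @ P @ y
            )

        center = np.array([0.1, 0.1, 0.1])
        width = 0.1
        for _ in range(12):  # zooming grid search
            axes = [np.clip(np.linspace(c - width, c + width, 11), 1e-8, None) for c in center]
            best, best_val = None, np.inf
            for a in axes[0]:
                for b in axes[1]:
                    for c in axes[2]:
                        val = neg2lr(a, b, c)
                        if val < best_val:
                            best, best_val = (a, b, c), val
            center, width = np.array(best), width / 4
        assert vc.components["G"] == pytest.approx(center[0], abs=1e-4)
        assert vc.components["GE"] == pytest.approx(center[1], abs=1e-4)
        assert vc.residual == pytest.approx(center[2], abs=1e-4)

    def test_invariant_to_fixed_reparameterization(self):
        df = one_way()
        df["grp2"] = df["grp"]  # site-style fixed factor
        rng = np.random.default_rng(1)
        df["site"] = np.tile(["a", "b", "c"], len(df) // 3)
        df["y"] = df["y"] + (df["site"] == "b") * 0.5
        spec1 = ModelSpec(response="y", fixed=("site",), random=(RandomTerm("G", ("grp",)),))
        vc1 = fit_reml(df, spec1)
        # relabel fixed levels (different reference) -> same REML estimates
        df2 = df.assign(site=df["site"].map({"a": "z_last", "b": "m", "c": "k"}))
        vc2 = fit_reml(df2, spec1)
        assert vc1.components["G"] == pytest.approx(vc2.components["G"], rel=1e-4)
        assert vc1.residual == pytest.approx(vc2.residual, rel=1e-4)
        assert vc1.loglik == pytest.approx(vc2.loglik, abs=1e-4)

    def test_zero_variance_term_leaves_likelihood_unchanged(self):
        df = one_way()
        vc1 = fit_reml(df, ONE_WAY_SPEC)
        rng = np.random.default_rng(0)
        df["noise_factor"] = rng.permutation(np.repeat(np.arange(8), 6)).astype(str)
        spec2 = ModelSpec(
            response="y",
            fixed=(),
            random=(RandomTerm("G", ("grp",)), RandomTerm("N", ("noise_factor",))),
        )
        vc2 = fit_reml(df, spec2)
        assert vc2.loglik >= vc1.loglik - 1e-6

    def test_single_level_random_term_dropped_with_warning(self):
        df = one_way()
        df["const"] = "only"
        spec = ModelSpec(
            response="y",
            fixed=(),
            random=(RandomTerm("G", ("grp",)), RandomTerm("C", ("const",))),
        )
        with pytest.warns(UserWarning, match="<2 levels"):
            vc = fit_reml(df, spec)
        assert "C" not in vc.components

    def test_missing_response_rows_ignored(self):
        df = one_way()
        df.loc[:4, "y"] = np.nan
        vc = fit_reml(df, ONE_WAY_SPEC)
        assert vc.n_obs == len(df) - 5

    def test_collapsed_workspace_matches_plain(self):
        from tpemet.lmm_engine import (
            _CollapsedWorkspace,
            _REMLWorkspace,
            _fixed_design,
            _random_designs,
        )

        rng = np.random.default_rng(11)
        rows = [
            {
                "geno": f"g{g}",
                "site": f"s{s}",
                "rep": r,
                "y": rng.normal(4, 1),
            }
            for g in range(12)
            for s in range(6)
            for r in (1, 2)
        ]
        df = pd.DataFrame(rows)
        spec = ModelSpec(
            response="y",
            fixed=("site",),
            random=(RandomTerm("G", ("geno",)), RandomTerm("GE", ("geno", "site"))),
        )
        y = df["y"].to_numpy()
        X, _ = _fixed_design(df, spec.fixed)
        _, Zs, _ = _random_designs(df, spec.random)
        plain = _REMLWorkspace(y, X, Zs)
        collapsed = _CollapsedWorkspace(y, X, Zs, 1)
        for lam in (np.array([0.1, 0.5]), np.array([2.0, 0.0]), np.array([0.0, 1.3])):
            assert collapsed.deviance(lam) == pytest.approx(plain.deviance(lam), abs=1e-7)


class TestTemplates:
    def test_eq4_terms_as_printed(self):
        spec = model_template("eq4")
        assert spec.fixed == ("group_label",)
        assert [t.name for t in spec.random] == [
            "G",
            "G*TPE",
            "G*E(TPE)",
            "E(TPE)",
            "R(E)",
            "SB(E*R)",
        ]

    def test_unknown_template(self):
        with pytest.raises(KeyError, match="unknown model template"):
            model_template("eq99")

    def test_eq7_fit_on_station_trial(self):
        rng = np.random.default_rng(13)
        rows = [
            {
                "cycle_year": 2010,
                "site_id": "OBR",
                "group_label": "B5IR",
                "group_kind": "SE",
                "replicate": r,
                "sub_block": sb,
                "genotype_id": f"G{g}",
                "is_local_check": False,
                "grain_yield": 7.0 + rng.normal(0, 0.5),
            }
            for r in (1, 2)
            for sb in (1, 2)
            for g in range(10)
        ]
        vc = fit_reml(pd.DataFrame(rows), "eq7")
        assert set(vc.components) == {"R", "SB(R)", "G"}
        assert all(v >= 0 for v in vc.components.values())


class TestBlues:
    def test_ols_limit_balanced(self):
        df = one_way(g=4, n=3)
        spec = ModelSpec(response="y", fixed=(), random=())
        blues = fit_blues(df, spec, genotype_col="grp")
        means = df.groupby("grp")["y"].mean()
        np.testing.assert_allclose(blues.series().sort_index(), means.sort_index(), atol=1e-9)

    def test_known_shift_recovered(self):
        rng = np.random.default_rng(9)
        rows = []
        for s in range(6):
            site_eff = rng.normal(0, 0.4)
            for g, d in (("g1", 0.0), ("g2", 0.5)):
                for _ in range(2):
                    rows.append({"geno": g, "site": f"s{s}", "y": 4 + site_eff + d + rng.normal(0, 0.1)})
        df = pd.DataFrame(rows)
        spec = ModelSpec(
            response="y",
            fixed=(),
            random=(RandomTerm("E", ("site",)), RandomTerm("G", ("geno",))),
        )
        s = fit_blues(df, spec, genotype_col="geno").series()
        assert s["g2"] - s["g1"] == pytest.approx(0.5, abs=0.12)

    def test_absent_genotype_not_zero_filled(self):
        df = one_way(g=3, n=4)
        blues = fit_blues(df, ModelSpec(response="y", fixed=(), random=()), genotype_col="grp")
        assert set(blues.df["genotype_id"]) == {"g0", "g1", "g2"}
        assert "g9" not in blues.series().index


class TestHeritability:
    def test_plugin_published_average_row(self):
        h2 = heritability("plugin", V_g_total=0.0311 + 0.0118, V_z=0.06)
        assert round(h2, 2) == 0.72

    def test_noiseless_limit(self):
        assert heritability("across_env", V_g=0.3, V_ge=0.0, V_r=0.0, ne=5, nr=2) == 1.0

    def test_across_env_arithmetic(self):
        h2 = heritability("across_env", V_g=0.05, V_ge=0.16, V_r=0.20, ne=14, nr=2)
        assert h2 == pytest.approx(0.7292, abs=1e-4)

    def test_across_tpe_adds_gxtpe(self):
        h2 = heritability(
            "across_tpe", V_g=0.05, V_ge=0.16, V_r=0.20, ne=14, nr=2, V_g_tpe=0.02
        )
        vz = phenotypic_variance(
            "across_tpe", V_g=0.05, V_ge=0.16, V_r=0.20, ne=14, nr=2, V_g_tpe=0.02
        )
        assert h2 == pytest.approx(0.07 / vz)

    def test_zero_vz_missing(self):
        assert np.isnan(heritability("plugin", V_g_total=0.0, V_z=0.0))

    def test_invalid_ne(self):
        with pytest.raises(ValueError):
            heritability("across_env", V_g=0.1, V_ge=0.1, V_r=0.1, ne=0, nr=2)

    @given(
        st.floats(0.01, 1.0),
        st.floats(0.0, 1.0),
        st.floats(0.01, 1.0),
        st.integers(1, 30),
        st.integers(1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ne_nr(self, vg, vge, vr, ne, nr):
        h = heritability("across_env", V_g=vg, V_ge=vge, V_r=vr, ne=ne, nr=nr)
        h_up = heritability("across_env", V_g=vg, V_ge=vge, V_r=vr, ne=ne + 1, nr=nr)
        h_upr = heritability("across_env", V_g=vg, V_ge=vge, V_r=vr, ne=ne, nr=nr + 1)
        assert h_up >= h - 1e-12
        assert h_upr >= h - 1e-12
        assert 0.0 <= h <= 1.0


class TestGibbsCrossCheck:
    def test_gibbs_close_to_reml_on_one_way(self):
        df = one_way(g=30, n=8, sd_g=1.0, sd_e=0.5, seed=21)
        vc = fit_reml(df, ONE_WAY_SPEC)
        post = fit_gibbs(df, ONE_WAY_SPEC, n_iter=2000, burn_in=500, seed=4)
        assert post.components["G"] == pytest.approx(vc.components["G"], rel=0.35)
        assert post.residual == pytest.approx(vc.residual, rel=0.15)

    def test_gibbs_deterministic_under_seed(self, small_trials):
        df = one_way()
        p1 = fit_gibbs(df, ONE_WAY_SPEC, n_iter=400, burn_in=100, seed=9)
        p2 = fit_gibbs(df, ONE_WAY_SPEC, n_iter=400, burn_in=100, seed=9)
        assert p1.components == p2.components
        assert p1.residual == p2.residual
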