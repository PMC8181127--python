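import numpy as np
import pandas as pd
import pytest

from tpemet import synthetic_data as sd
from tpemet.pedigree_kinship import build_A
from tpemet.reaction_norm import (
    KernelError,
    KernelSet,
    build_kernels,
    fit_gibbs,
    gblup_solve,
    predictive_correlation,
    pvt,
)


def eye_A(n):
    lines = [f"L{i}" for i in range(n)]
    return pd.DataFrame(np.eye(n), index=lines, columns=lines), lines


class TestBuildKernels:
    def test_identity_A_one_record_per_line(self):
        A, lines = eye_A(6)
        recs = pd.DataFrame({"line": lines, "env": ["E1"] * 6})
        ks = build_kernels(A, recs, model="AE")
        np.testing.assert_array_equal(ks["a"], np.eye(6))

    def test_same_line_different_envs(self):
        ped = pd.DataFrame(
            [("X", "0", "0")], columns=["id", "parent1", "parent2"]
        )
        A = build_A(ped)
        recs = pd.DataFrame({"line": ["X", "X"], "env": ["E1", "E2"]})
        ks = build_kernels(A, recs, model="AE-AxE")
        assert ks["aE"][0, 1] == 0.0  # indicator orthogonality
        assert ks["a"][0, 1] == 1.0  # diagonal of A

    def test_four_record_hand_hadamard(self):
        # 2 full-sib lines (a=0.5), 2 environments, one record each combo
        ped = pd.DataFrame(
            [("P1", "0", "0"), ("P2", "0", "0"), ("S1", "P1", "P2"), ("S2", "P1", "P2")],
            columns=["id", "parent1", "parent2"],
        )
        A = build_A(ped)
        recs = pd.DataFrame(
            {"line": ["S1", "S1", "S2", "S2"], "env": ["E1", "E2", "E1", "E2"]}
        )
        ks = build_kernels(A, recs, model="AE-AxE")
        K_a_hand = np.array(
            [
                [1.0, 1.0, 0.5, 0.5],
                [1.0, 1.0, 0.5, 0.5],
                [0.5, 0.5, 1.0, 1.0],
                [0.5, 0.5, 1.0, 1.0],
            ]
        )
        K_E_hand = np.array(
            [
                [1.0, 0.0, 1.0, 0.0],
                [0.0, 1.0, 0.0, 1.0],
                [1.0, 0.0, 1.0, 0.0],
                [0.0, 1.0, 0.0, 1.0],
            ]
        )
        np.testing.assert_array_equal(ks["a"], K_a_hand)
        np.testing.assert_array_equal(ks["aE"], K_a_hand * K_E_hand)

    def test_missing_line_named(self):
        A, lines = eye_A(3)
        recs = pd.DataFrame({"line": ["L0", "GHOST"], "env": ["E1", "E1"]})
        with pytest.raises(KernelError, match="GHOST"):
            build_kernels(A, recs, model="AE")

    def test_covariate_model_requires_W(self):
        A, lines = eye_A(3)
        recs = pd.DataFrame({"line": lines, "env": ["E1", "E1", "E2"]})
        with pytest.raises(KernelError, match="covariate"):
            build_kernels(A, recs, model="AE-AxE-W-AxW")

    def test_kernels_psd_on_build(self):
        rng = np.random.default_rng(3)
        spec = sd.SimulationSpec(seed=3, n_env_covariates=4)
        ped = sd.simulate_pedigree(sd.SimulationSpec(n_cycles=1, lines_per_cycle=10, n_founders=6, seed=3))
        recs, W, _ = sd.simulate_reaction_norm(spec, pedigree=ped, n_envs=5)
        A = build_A(ped, ordered=True)
        ks = build_kernels(A, recs, W=W, model="AE-AxE-W-AxW")
        for name, K in ks.kernels.items():
            w = np.linalg.eigvalsh((K + K.T) / 2)
            assert w.min() > -1e-8 * max(1.0, w.max()), name


class TestGblupSolve:
    def test_matches_kernel_ridge_oracle(self):
        rng = np.random.default_rng(5)
        n = 20
        A, lines = eye_A(n)
        M = rng.normal(size=(n, n))
        K = M @ M.T / n
        y = rng.normal(size=n)
        s2a, s2e = 0.5, 0.2
        pred = gblup_solve({"a": K}, {"a": s2a}, s2e, y, mu=0.0)
        oracle = K @ np.linalg.solve(K + (s2e / s2a) * np.eye(n), y)
        np.testing.assert_allclose(pred, oracle, atol=1e-10)

    def test_holdout_prediction_via_cross_covariance(self):
        rng = np.random.default_rng(6)
        n = 15
        M = rng.normal(size=(n, n))
        K = M @ M.T / n
        y = rng.normal(size=n)
        train = np.ones(n, dtype=bool)
        train[-3:] = False
        y_masked = np.where(train, y, np.nan)
        pred = gblup_solve({"a": K}, {"a": 1.0}, 0.3, y_masked, mu=0.0)
        Ktt = K[np.ix_(train, train)]
        alpha = np.linalg.solve(Ktt + 0.3 * np.eye(train.sum()), y[train])
        oracle = K[~train][:, train] @ alpha
        np.testing.assert_allclose(pred[~train], oracle, atol=1e-10)


class TestFitGibbs:
    def make_simple(self, seed=0, n_lines=15, n_envs=4):
        spec = sd.SimulationSpec(seed=seed, n_env_covariates=3)
        ped = sd.simulate_pedigree(
            sd.SimulationSpec(n_cycles=1, lines_per_cycle=n_lines, n_founders=8, seed=seed)
        )
        recs, W, truth = sd.simulate_reaction_norm(spec, pedigree=ped, n_envs=n_envs, n_reps=2)
        A = build_A(ped, ordered=True)
        return recs, W, truth, A

    def test_fixed_variances_equal_closed_form(self):
        recs, W, truth, A = self.make_simple()
        ks = build_kernels(A, recs, model="AE")
        y = recs["y"].to_numpy()
        summ = fit_gibbs(
            y, ks, fixed_variances={"a": 0.3, "E": 0.8}, fixed_resid=0.2, seed=1
        )
        assert summ.analytic
        oracle = gblup_solve(ks, {"a": 0.3, "E": 0.8}, 0.2, y)
        np.testing.assert_allclose(summ.fitted.to_numpy(), oracle, atol=1e-8)

    def test_seeded_chains_bit_reproducible(self):
        recs, W, truth, A = self.make_simple()
        ks = build_kernels(A, recs, model="AE-AxE")
        s1 = fit_gibbs(recs["y"], ks, n_iter=600, burn_in=100, thin=1, n_chains=2, seed=7)
        s2 = fit_gibbs(recs["y"], ks, n_iter=600, burn_in=100, thin=1, n_chains=2, seed=7)
        assert s1.post_mean == s2.post_mean
        pd.testing.assert_frame_equal(s1.samples, s2.samples)

    def test_constant_response_degenerates(self):
        recs, W, truth, A = self.make_simple()
        ks = build_kernels(A, recs, model="AE")
        y = np.full(len(recs), 3.0)
        summ = fit_gibbs(
            y, ks, n_iter=800, burn_in=200, thin=1, seed=2, prior_df=2.0, prior_scale=1e-4
        )
        assert summ.post_mean["a"] < 0.01
        assert summ.post_mean["E"] < 0.01
        assert summ.fitted.std() < 0.05

    def test_too_few_samples_rejected(self):
        recs, W, truth, A = self.make_simple()
        ks = build_kernels(A, recs, model="AE")
        with pytest.raises(ValueError, match="100 post-burn-in"):
            fit_gibbs(recs["y"], ks, n_iter=200, burn_in=100, thin=5)

    def test_holdout_predictions_present_for_every_record(self):
        recs, W, truth, A = self.make_simple()
        ks = build_kernels(A, recs, model="AE-AxE")
        y = recs["y"].copy()
        y.iloc[-10:] = np.nan
        summ = fit_gibbs(y, ks, n_iter=600, burn_in=100, thin=1, seed=3)
        assert len(summ.predictions) == 10
        assert summ.predictions.notna().all()

    def test_relabeling_invariance_of_predictions(self):
        recs, W, truth, A = self.make_simple()
        ks = build_kernels(A, recs, model="AE")
        y = recs["y"].to_numpy()
        fitted1 = gblup_solve(ks, {"a": 0.2, "E": 0.5}, 0.3, y)
        perm = np.random.default_rng(0).permutation(len(recs))
        recs2 = recs.iloc[perm].reset_index(drop=True)
        ks2 = build_kernels(A, recs2, model="AE")
        fitted2 = gblup_solve(ks2, {"a": 0.2, "E": 0.5}, 0.3, y[perm])
        np.testing.assert_allclose(fitted2, fitted1[perm], atol=1e-9)


class TestPvt:
    def test_equal_components(self):
        out = pvt({"a": 0.2, "E": 0.2, "residual": 0.2})
        assert out.to_numpy() == pytest.approx(100 / 3)

    def test_arithmetic_example(self):
        out = pvt({"V_A": 0.06, "V_E": 1.49, "V_r": 0.07})
        np.testing.assert_allclose(out.round(1).to_numpy(), [3.7, 92.0, 4.3])

    def test_single_component(self):
        assert pvt({"only": 0.4}).iloc[0] == 100.0

    def test_all_zero_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            pvt({"a": 0.0, "b": 0.0})

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            pvt({"a": -0.1, "b": 0.2})

    def test_sums_to_100(self):
        out = pvt({"a": 0.123, "b": 0.456, "c": 0.789})
        assert out.sum() == pytest.approx(100.0)


class TestPredictiveCorrelation:
    def test_perfect_prediction(self):
        p = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert predictive_correlation(p, p) == pytest.approx(1.0)

    def test_negated_prediction(self):
        p = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert predictive_correlation(p, -p) == pytest.approx(-1.0)

    def test_zero_variance_missing(self):
        p = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        o = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert np.isnan(predictive_correlation(p, o))

    def test_per_group(self):
        p = pd.Series([1.0, 2.0, 3.0, 3.0, 2.0, 1.0], index=list("abcdef"))
        o = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=list("abcdef"))
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=list("abcdef"))
        out = predictive_correlation(p, o, groups)
        assert out["g1"] == pytest.approx(1.0)
        assert out["g2"] == pytest.approx(-1.0)


class TestCovariateModelHelps:
    def test_covariate_model_beats_ae_on_average(self):
        """With true covariate variance, AE-AxE-W-AxW predicts held-out
        environments at least as well as AE on average over seeds."""
        diffs = []
        for seed in range(10):
            spec = sd.SimulationSpec(
                seed=seed,
                n_env_covariates=3,
                rn_components={"a": 0.05, "E": 0.3, "aE": 0.05, "W": 0.6, "aW": 0.02, "residual": 0.2},
            )
            ped = sd.simulate_pedigree(
                sd.SimulationSpec(n_cycles=1, lines_per_cycle=15, n_founders=8, seed=seed)
            )
            recs, W, truth = sd.simulate_reaction_norm(spec, pedigree=ped, n_envs=10)
            A = build_A(ped, ordered=True)
            y = recs["y"].copy()
            held = recs["env"].isin(["ENV09", "ENV10"])
            y[held] = np.nan
            observed = pd.Series(
                recs.loc[held, "y"].to_numpy(),
                index=(recs.loc[held, "line"] + "|" + recs.loc[held, "env"]),
            )
            rs = {}
            for model in ("AE", "AE-AxE-W-AxW"):
                ks = build_kernels(A, recs, W=W, model=model)
                summ = fit_gibbs(
                    y, ks, n_iter=800, burn_in=200, thin=2, n_chains=1, seed=seed,
                    prior_df=2.0, prior_scale=0.05,
                )
                rs[model] = predictive_correlation(summ, observed)
            diffs.append(rs["AE-AxE-W-AxW"] - rs["AE"])
        assert np.mean(diffs) > 0
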