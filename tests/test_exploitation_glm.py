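import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from foragekit.errors import (ConfigurationError, FittingError, InputDataError,
                              InsufficientDataError, SeparationError)
from foragekit.exploitation_glm import (BootstrapEnsemble, bic,
                                        build_covariates, coefficient_test,
                                        compare_likelihood, cv_lambda,
                                        encounter_sample, fit_ridge,
                                        fit_soft_logistic, model_select,
                                        predict_surface, shuffle_null,
                                        simulate_first_exploit,
                                        soft_log_likelihood, strain_compare,
                                        worm_bootstrap)
from foragekit.synthetic_world import generate_covariate_dataset

ACCL = 10.0


def encounter_table(rows):
    defaults = dict(worm_id=0, density=5.0, q=0.0, p_sense=1.0)
    recs = []
    for r in rows:
        rec = dict(defaults)
        rec.update(r)
        recs.append(rec)
    return pd.DataFrame(recs)


class TestBuildCovariates:
    def test_first_encounter_initialization(self):
        df = encounter_table([dict(entry_s=100.0, exit_s=200.0, q=0.0)])
        out = build_covariates(df, ACCL)
        row = out.iloc[0]
        assert row["rho_h"] == pytest.approx(math.log(ACCL))
        assert row["rho_e"] == pytest.approx(math.log(ACCL))
        assert row["tau_s"] == pytest.approx(100.0 / 3600.0)

    def test_homogeneous_history(self):
        df = encounter_table([
            dict(entry_s=t, exit_s=t + 50.0, density=ACCL, q=1.0)
            for t in (100.0, 400.0, 800.0)])
        out = build_covariates(df, ACCL)
        np.testing.assert_allclose(out["rho_k"], math.log(ACCL))
        np.testing.assert_allclose(out["rho_h"], math.log(ACCL))
        np.testing.assert_allclose(out["rho_e"], math.log(ACCL))

    def test_hand_computed_three_encounter_timeline(self):
        df = encounter_table([
            dict(entry_s=100.0, exit_s=200.0, density=2.0, q=0.0),
            dict(entry_s=400.0, exit_s=700.0, density=8.0, q=1.0),  # exploit
            dict(entry_s=1000.0, exit_s=1100.0, density=3.0, q=0.0)])
        out = build_covariates(df, ACCL)
        # tau_s: cumulative off-patch time since last realized exploit
        assert out.loc[0, "tau_s"] == pytest.approx(100.0 / 3600.0)
        assert out.loc[1, "tau_s"] == pytest.approx((100.0 + 200.0) / 3600.0)
        assert out.loc[2, "tau_s"] == pytest.approx(300.0 / 3600.0)  # since exit 700
        assert out.loc[2, "rho_h"] == pytest.approx(math.log(8.0))
        assert out.loc[2, "rho_e"] == pytest.approx(math.log(8.0))
        assert out.loc[1, "rho_e"] == pytest.approx(math.log(ACCL))

    def test_zero_density_dropped_by_default(self):
        df = encounter_table([
            dict(entry_s=100.0, exit_s=200.0, density=0.0),
            dict(entry_s=400.0, exit_s=500.0, density=5.0)])
        out = build_covariates(df, ACCL)
        assert len(out) == 1
        assert out.loc[0, "density"] == 5.0

    def test_zero_density_error_mode(self):
        df = encounter_table([dict(entry_s=100.0, exit_s=200.0, density=0.0)])
        with pytest.raises(InputDataError):
            build_covariates(df, ACCL, on_zero_density="error")

    def test_pseudo_density_mode(self):
        df = encounter_table([dict(entry_s=100.0, exit_s=200.0, density=0.0)])
        out = build_covariates(df, ACCL, on_zero_density="pseudo",
                               pseudo_density=0.01)
        assert out.loc[0, "rho_k"] == pytest.approx(math.log(0.01))

    def test_tau_t_is_time_since_transfer(self):
        df = encounter_table([dict(entry_s=7200.0, exit_s=7300.0)])
        out = build_covariates(df, ACCL, include_tau_t=True)
        assert out.loc[0, "tau_t"] == pytest.approx(2.0)


class TestEncounterSample:
    def _ten_encounters(self, p_sense):
        return encounter_table([
            dict(worm_id=0, entry_s=100.0 * (k + 1) + 50.0 * k,
                 exit_s=100.0 * (k + 1) + 50.0 * (k + 1),
                 density=5.0, q=float(k == 4), p_sense=p_sense[k])
            for k in range(10)])

    def test_certain_inclusion_reproduces_input(self):
        df = self._ten_encounters([1.0] * 10)
        reps = encounter_sample(df, ACCL, n_sets=3, seed=1)
        expect = build_covariates(df, ACCL)
        for rep in reps:
            pd.testing.assert_frame_equal(
                rep.reset_index(drop=True), expect, check_like=True)

    def test_certain_exclusion_yields_empty_then_fit_errors(self):
        df = self._ten_encounters([0.0] * 10)
        reps = encounter_sample(df, ACCL, n_sets=2, seed=1)
        assert all(len(r) == 0 for r in reps)
        with pytest.raises(InsufficientDataError):
            fit_soft_logistic(reps[0], ("rho_k",))

    def test_worked_example_reindexes_and_rebuilds(self):
        # non-responses at k1, k3, k6, k8 (1-based); six retained encounters
        p = [1.0] * 10
        for k in (0, 2, 5, 7):
            p[k] = 0.0
        df = self._ten_encounters(p)
        rep = encounter_sample(df, ACCL, n_sets=1, seed=1)[0]
        assert len(rep) == 6
        np.testing.assert_array_equal(rep["encounter"], np.arange(6))
        # covariates equal a fresh build on the retained subsequence; the
        # dropped encounters' dwell counts as off-patch search time
        keep = df.iloc[[1, 3, 4, 6, 8, 9]]
        pd.testing.assert_frame_equal(rep.reset_index(drop=True),
                                      build_covariates(keep, ACCL),
                                      check_like=True)
        assert rep.loc[0, "tau_s"] == pytest.approx(250.0 / 3600.0)

    def test_missing_p_sense_rejected(self):
        df = self._ten_encounters([1.0] * 10).drop(columns="p_sense")
        with pytest.raises(InputDataError):
            encounter_sample(df, ACCL, n_sets=1, seed=1)


class TestWormBootstrap:
    def test_single_worm_replicates_identical(self):
        df = encounter_table([dict(entry_s=1.0, exit_s=2.0)] * 4)
        with pytest.warns(UserWarning):
            reps = worm_bootstrap(df, n_sets=3, seed=1)
        for rep in reps:
            assert len(rep) == 4

    def test_unique_worm_fraction_632(self):
        df = pd.DataFrame({"worm_id": np.arange(443), "x": 0.0})
        reps = worm_bootstrap(df, n_sets=200, seed=2)
        fracs = [rep["worm_id"].nunique() / 443 for rep in reps]
        assert np.mean(fracs) == pytest.approx(1 - 1 / math.e, abs=0.01)

    def test_duplicated_worms_contribute_duplicate_rows(self):
        df = pd.DataFrame({"worm_id": [0, 0, 1], "x": [1.0, 2.0, 3.0]})
        reps = worm_bootstrap(df, n_sets=20, seed=3)
        for rep in reps:
            assert rep["boot_worm"].nunique() == 2
            assert len(rep) in (2, 3, 4)


def bernoulli_mle_oracle(X, y):
    """Independent numerical MLE of the Bernoulli logistic likelihood."""
    def nll(b):
        eta = X @ b
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    def grad(b):
        p = 1.0 / (1.0 + np.exp(-(X @ b)))
        return X.T @ (p - y)

    res = optimize.minimize(nll, np.zeros(X.shape[1]), jac=grad,
                            method="L-BFGS-B",
                            options={"gtol": 1e-12, "ftol": 1e-15,
                                     "maxiter": 2000})
    return res.x


def random_dataset(rng, n=200, p=4, beta=None):
    X = rng.normal(size=(n, p))
    beta = np.r_[0.3, rng.normal(size=p)] if beta is None else beta
    eta = beta[0] + X @ beta[1:]
    q = 1.0 / (1.0 + np.exp(-eta))
    cols = {f"c{i}": X[:, i] for i in range(p)}
    cols["q"] = q
    cols["worm_id"] = np.repeat(np.arange(n // 10), 10)
    return pd.DataFrame(cols), beta


class TestFitSoftLogistic:
    def test_all_half_labels_intercept_zero(self):
        df = pd.DataFrame({"q": np.full(50, 0.5), "worm_id": 0})
        fit = fit_soft_logistic(df, ())
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(1)
        q = rng.uniform(0.05, 0.95, 300)
        m = q.mean()
        fit = fit_soft_logistic(pd.DataFrame({"q": q, "worm_id": 0}), ())
        assert fit.beta[0] == pytest.approx(math.log(m / (1 - m)), abs=1e-8)

    def test_binary_labels_match_bernoulli_mle_oracle(self):
        rng = np.random.default_rng(2)
        df, beta = random_dataset(rng, n=300)
        y = (rng.uniform(size=len(df)) < df["q"]).astype(float)
        df["q"] = y
        fit = fit_soft_logistic(df, ("c0", "c1", "c2", "c3"))
        X = np.column_stack([np.ones(len(df)),
                             df[["c0", "c1", "c2", "c3"]].to_numpy()])
        oracle = bernoulli_mle_oracle(X, y)
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-6)

    def test_kl_divergence_equivalence(self):
        # soft NLL and sum of KL divergences differ by a beta-free constant
        rng = np.random.default_rng(3)
        df, _ = random_dataset(rng, n=150, p=2)
        X = np.column_stack([np.ones(len(df)), df[["c0", "c1"]].to_numpy()])
        q = np.clip(df["q"].to_numpy(), 1e-9, 1 - 1e-9)
        ent = float(np.sum(q * np.log(q) + (1 - q) * np.log(1 - q)))
        diffs = []
        for _ in range(10):
            b = rng.normal(size=3)
            p = 1.0 / (1.0 + np.exp(-(X @ b)))
            kl = float(np.sum(q * np.log(q / p) +
                              (1 - q) * np.log((1 - q) / (1 - p))))
            diffs.append(kl + soft_log_likelihood(b, X, q) - ent)
        assert np.std(diffs) < 1e-9

    def test_worm_order_invariance(self):
        rng = np.random.default_rng(4)
        df, _ = random_dataset(rng, n=200, p=3)
        fit1 = fit_soft_logistic(df, ("c0", "c1", "c2"))
        fit2 = fit_soft_logistic(df.sample(frac=1.0, random_state=0),
                                 ("c0", "c1", "c2"))
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-8)

    def test_affine_rescaling_equivariance(self):
        rng = np.random.default_rng(5)
        df, _ = random_dataset(rng, n=200, p=2)
        fit1 = fit_soft_logistic(df, ("c0", "c1"))
        df2 = df.copy()
        df2["c0"] = 10.0 * df2["c0"] + 3.0
        fit2 = fit_soft_logistic(df2, ("c0", "c1"))
        assert fit2.beta[1] == pytest.approx(fit1.beta[1] / 10.0, rel=1e-6)
        assert fit2.beta[0] == pytest.approx(
            fit1.beta[0] - 3.0 * fit1.beta[1] / 10.0, rel=1e-6)

    def test_separation_detected(self):
        x = np.r_[np.linspace(-2, -1, 50), np.linspace(1, 2, 50)]
        df = pd.DataFrame({"c0": x, "q": (x > 0).astype(float), "worm_id": 0})
        with pytest.raises(SeparationError):
            fit_soft_logistic(df, ("c0",))

    def test_rank_deficiency_detected(self):
        rng = np.random.default_rng(6)
        df, _ = random_dataset(rng, n=100, p=2)
        df["c2"] = df["c0"]
        with pytest.raises(FittingError):
            fit_soft_logistic(df, ("c0", "c1", "c2"))

    def test_log_likelihood_nonpositive(self):
        rng = np.random.default_rng(7)
        df, _ = random_dataset(rng, n=100, p=2)
        fit = fit_soft_logistic(df, ("c0", "c1"))
        assert fit.log_likelihood <= 0.0


class TestModelSelection:
    def test_bic_penalty_arithmetic(self):
        from foragekit.exploitation_glm import GLMFit
        a = GLMFit(np.zeros(2), ("c0",), -100.0, 500)
        b = GLMFit(np.zeros(3), ("c0", "c1"), -100.0, 500)
        assert bic(b) - bic(a) == pytest.approx(math.log(500))

    def test_single_spec_ranked_first(self):
        rng = np.random.default_rng(8)
        df, _ = random_dataset(rng, n=100, p=2)
        out = model_select(df, [("c0", "c1")])
        assert out.loc[0, "rank"] == 1

    def test_active_covariates_selected(self):
        data, _ = generate_covariate_dataset(
            (-2.0, 1.0, 0.5, -0.5, -0.5), 100, 20, (1.0, 5.0, 10.0), seed=9)
        out = model_select(data, [("rho_k", "tau_s", "rho_h", "rho_e"),
                                  ("rho_k",), ()])
        assert out.loc[0, "spec"] == ("rho_k", "tau_s", "rho_h", "rho_e")


class TestNullAndTests:
    def test_shuffle_null_centers_near_zero(self):
        rng = np.random.default_rng(10)
        df, _ = random_dataset(rng, n=300, p=2)
        ens = shuffle_null(df, ("c0", "c1"), n_shuffles=100, seed=1)
        assert abs(ens.mean[1]) < 3 * ens.sd[1] / math.sqrt(100) * 5

    def test_one_sided_ensemble_floored_p(self):
        betas = np.abs(np.random.default_rng(11).normal(size=(200, 2))) + 0.1
        ens = BootstrapEnsemble(betas, ("intercept", "c0"), [])
        out = coefficient_test(ens, adjust="none")
        np.testing.assert_allclose(out["p_raw"], 2 / 200)
        assert out["at_resolution_floor"].all()

    def test_symmetric_ensemble_p_near_one(self):
        rng = np.random.default_rng(12)
        b = rng.normal(size=(2000, 1))
        ens = BootstrapEnsemble(b, ("intercept",), [])
        out = coefficient_test(ens, adjust="none")
        assert out.loc[0, "p_raw"] > 0.9


class TestRidge:
    def test_lambda_zero_equals_plain_fit(self):
        rng = np.random.default_rng(13)
        df, _ = random_dataset(rng, n=200, p=3)
        a = fit_soft_logistic(df, ("c0", "c1", "c2"))
        b = fit_ridge(df, ("c0", "c1", "c2"), 0.0)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-9)

    def test_coefficient_norm_monotone_in_lambda(self):
        rng = np.random.default_rng(14)
        df, _ = random_dataset(rng, n=150, p=3)
        norms = []
        for lam in (0.0, 0.1, 1.0, 10.0, 100.0):
            fit = fit_ridge(df, ("c0", "c1", "c2"), lam)
            norms.append(np.linalg.norm(fit.beta[1:]))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_cv_lambda_from_grid_with_tie_rule(self):
        rng = np.random.default_rng(15)
        df, _ = random_dataset(rng, n=120, p=2)
        lam, table = cv_lambda(df, ("c0", "c1"), [0.0, 0.01, 0.1], seed=1)
        assert lam in (0.0, 0.01, 0.1)
        assert len(table) == 3

    def test_ridge_resolves_separation(self):
        x = np.r_[np.linspace(-2, -1, 50), np.linspace(1, 2, 50)]
        df = pd.DataFrame({"c0": x, "q": (x > 0).astype(float), "worm_id": 0})
        fit = fit_ridge(df, ("c0",), 0.5)
        assert np.isfinite(fit.beta).all()


def two_point_ensemble(mean, sd, n, names=("intercept", "rho_k")):
    rng = np.random.default_rng(99)
    b = rng.standard_normal((n, len(names)))
    b = (b - b.mean(axis=0)) / b.std(axis=0, ddof=1)
    return BootstrapEnsemble(b * sd + mean, tuple(names), [])


class TestStrainCompare:
    def test_identical_ensembles_z_zero(self):
        a = two_point_ensemble(np.array([0.5, 1.0]), np.array([0.2, 0.3]), 500)
        out = strain_compare(a, a).table
        np.testing.assert_allclose(out["Z"], 0.0, atol=1e-12)
        assert out.loc[out.coefficient == "rho_k", "p"].iloc[0] == \
            pytest.approx(0.5)

    def test_unit_negative_shift(self):
        from scipy.stats import norm
        s = 1.0 / math.sqrt(2.0)
        wt = two_point_ensemble(np.array([0.0, 1.0]), np.array([s, s]), 400)
        mut = two_point_ensemble(np.array([0.0, 0.0]), np.array([s, s]), 400)
        out = strain_compare(mut, wt).table
        row = out[out.coefficient == "rho_k"].iloc[0]
        assert row["Z"] == pytest.approx(-1.0, abs=1e-9)
        assert row["p"] == pytest.approx(norm.cdf(-1.0), abs=1e-9)
        assert row["tail"] == "left"

    def test_two_tailed_literal_variant(self):
        wt = two_point_ensemble(np.array([0.0, 1.0]), np.array([1.0, 1.0]), 300)
        mut = two_point_ensemble(np.array([2.0, 1.0]), np.array([1.0, 1.0]), 300)
        lit = strain_compare(mut, wt, two_tailed_literal=True).table
        std = strain_compare(mut, wt).table
        i = int(np.nonzero((std.coefficient == "intercept").to_numpy())[0][0])
        assert std.loc[i, "p"] == pytest.approx(2 * lit.loc[i, "p"])

    def test_mismatched_specs_rejected(self):
        a = two_point_ensemble(np.zeros(2), np.ones(2), 100)
        b = two_point_ensemble(np.zeros(2), np.ones(2), 100,
                               names=("intercept", "tau_s"))
        with pytest.raises(ConfigurationError):
            strain_compare(a, b)

    def test_bh_fdr_calibration(self):
        # same-beta ensembles: BH-adjusted rejections stay near nominal FDR
        rng = np.random.default_rng(16)
        rejections = 0
        n_pairs = 100
        for i in range(n_pairs):
            base = rng.normal(size=(200, 3)) * 0.3
            a = BootstrapEnsemble(base + rng.normal(0, 0.02, 3),
                                  ("intercept", "rho_k", "tau_s"), [])
            b = BootstrapEnsemble(rng.normal(size=(200, 3)) * 0.3
                                  + rng.normal(0, 0.02, 3),
                                  ("intercept", "rho_k", "tau_s"), [])
            out = strain_compare(a, b).table
            rejections += int((out["p_bh"] < 0.05).any())
        assert rejections / n_pairs <= 0.12


class TestFirstExploit:
    def test_certain_success_first_encounter(self):
        pmf, cens = simulate_first_exploit([np.ones(5)], 1000, seed=1)
        assert pmf[0] == 1.0
        assert cens == 0.0

    def test_impossible_success_all_censored(self):
        pmf, cens = simulate_first_exploit([np.zeros(5)], 1000, seed=1)
        assert pmf.sum() == 0.0
        assert cens == 1.0

    def test_geometric_closed_form(self):
        p = 0.5
        n = 20_000
        pmf, _ = simulate_first_exploit([np.full(30, p)], n, seed=2)
        for k in range(6):
            expect = p * (1 - p) ** k
            se = math.sqrt(expect * (1 - expect) / n)
            assert abs(pmf[k] - expect) < 3 * se

    def test_empty_sequences_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            pmf, _ = simulate_first_exploit([np.array([]), np.ones(3)],
                                            100, seed=3)
        assert pmf[0] == 1.0

    def test_all_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            simulate_first_exploit([np.array([])], 10, seed=1)


class TestPredictSurface:
    def _fit(self, beta, spec):
        from foragekit.exploitation_glm import GLMFit
        return GLMFit(np.asarray(beta, dtype=float), tuple(spec), -1.0, 100,
                      names=("intercept", *spec))

    def test_all_zero_beta_gives_half(self):
        fit = self._fit([0.0, 0.0, 0.0], ("rho_k", "rho_h"))
        grid = predict_surface(fit, "rho_h", np.linspace(0, 2, 5),
                               np.linspace(0, 2, 4))
        np.testing.assert_allclose(grid, 0.5)

    def test_negative_history_coefficient_monotone_decreasing(self):
        fit = self._fit([0.0, 1.0, -0.8], ("rho_k", "rho_h"))
        grid = predict_surface(fit, "rho_h", np.linspace(0, 3, 7),
                               np.linspace(0, 3, 5))
        assert np.all(np.diff(grid, axis=1) < 0)

    def test_spec_without_history_constant_along_axis(self):
        fit = self._fit([0.2, 1.0], ("rho_k",))
        grid = predict_surface(fit, "rho_e", np.linspace(0, 3, 7),
                               np.linspace(0, 3, 5))
        np.testing.assert_allclose(np.diff(grid, axis=1), 0.0, atol=1e-12)

    def test_positive_density_coefficient_monotone_in_rho_k(self):
        fit = self._fit([0.0, 1.5], ("rho_k",))
        grid = predict_surface(fit, "rho_h", np.linspace(0, 3, 4),
                               np.linspace(0, 3, 6))
        assert np.all(np.diff(grid, axis=0) > 0)

    def test_missing_fixed_value_rejected(self):
        fit = self._fit([0.0, 1.0, 0.5, -0.5], ("rho_k", "tau_s", "rho_h"))
        with pytest.raises(ConfigurationError):
            predict_surface(fit, "rho_h", np.linspace(0, 1, 3),
                            np.linspace(0, 1, 3))

    def test_unknown_fixed_name_rejected(self):
        fit = self._fit([0.0, 1.0], ("rho_k",))
        with pytest.raises(ConfigurationError):
            predict_surface(fit, "rho_h", np.linspace(0, 1, 3),
                            np.linspace(0, 1, 3), {"bogus": 1.0})


class TestCompareLikelihood:
    def test_identical_specs_statistic_zero(self):
        rng = np.random.default_rng(17)
        df, _ = random_dataset(rng, n=100, p=2)
        fit = fit_soft_logistic(df, ("c0", "c1"))
        out = compare_likelihood(fit, fit)
        assert out.statistic == 0.0
        assert out.p_value == 1.0

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(18)
        df, _ = random_dataset(rng, n=100, p=3)
        full = fit_soft_logistic(df, ("c0", "c1"))
        other = fit_soft_logistic(df, ("c2",))
        with pytest.raises(ConfigurationError):
            compare_likelihood(full, other)

    def test_out_of_sample_evaluation(self):
        rng = np.random.default_rng(19)
        train, _ = random_dataset(rng, n=300, p=2)
        hold, _ = random_dataset(rng, n=150, p=2)
        full = fit_soft_logistic(train, ("c0", "c1"))
        red = fit_soft_logistic(train, ("c0",))
        out = compare_likelihood(full, red, holdout=hold)
        assert out.df == 1
        assert np.isfinite(out.statistic)
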