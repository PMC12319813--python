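"""GP normative models: exact-GP oracle agreement, calibration of deviation
z-scores, cross-validation fold contracts."""

import numpy as np
import pandas as pd
import pytest

from qmrinorm import NormativeModel, deviation_z, fit_gpr, predict, zscore_apply, zscore_crossval


def gp_oracle(model, ages):
    """Dense-matrix GP posterior using the model's fitted hyperparameters."""
    hp = model.kernel_hyperparams
    xs = (model.train_ages - model.age_mean) / model.age_sd
    ys = (model.train_values - model.value_mean) / model.value_sd
    xt = (np.asarray(ages, dtype=float) - model.age_mean) / model.age_sd

    def k(a, b):
        d = a[:, None] - b[None, :]
        rbf = hp["signal_variance"] * np.exp(-(d**2) / (2 * hp["length_scale"] ** 2))
        lin = hp["linear_variance"] * (np.outer(a, b) + 1e-20)
        return rbf + lin

    n = len(xs)
    K = k(xs, xs) + (hp["noise_variance"] + 1e-10) * np.eye(n)  # 1e-10: solver jitter
    Ks = k(xt, xs)
    kss = hp["signal_variance"] + hp["linear_variance"] * (xt**2 + 1e-20) + hp["noise_variance"]
    alpha = np.linalg.solve(K, ys)
    mean = Ks @ alpha
    var = kss - np.einsum("ij,ji->i", Ks, np.linalg.solve(K, Ks.T))
    return mean * model.value_sd + model.value_mean, np.sqrt(var) * model.value_sd


def _linear_data(n=60, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(18, 79, n)
    vals = 0.5 + 0.01 * ages + (rng.normal(0, noise, n) if noise else 0.0)
    return ages, vals


class TestFitPredict:
    def test_noiseless_linear_interpolation(self):
        ages, vals = _linear_data(60, seed=1)
        model = fit_gpr(ages, vals, seed=0, n_restarts=2)
        pred = predict(model, ages)
        rmse = np.sqrt(np.mean((pred.mean - vals) ** 2))
        assert rmse < 1e-3 * vals.std()
        # noise variance collapses toward its lower bound
        assert model.kernel_hyperparams["noise_variance"] < 1e-6

    def test_permutation_invariance_of_marginal_likelihood(self):
        ages, vals = _linear_data(40, seed=2, noise=0.05)
        m1 = fit_gpr(ages, vals, seed=0, n_restarts=1)
        perm = np.random.default_rng(0).permutation(40)
        m2 = fit_gpr(ages[perm], vals[perm], seed=0, n_restarts=1)
        assert m1.gp.log_marginal_likelihood_value_ == pytest.approx(
            m2.gp.log_marginal_likelihood_value_, abs=1e-6
        )

    def test_seeded_determinism(self):
        ages, vals = _linear_data(40, seed=3, noise=0.05)
        a = fit_gpr(ages, vals, seed=5)
        b = fit_gpr(ages, vals, seed=5)
        assert a.kernel_hyperparams == b.kernel_hyperparams

    def test_exact_gp_oracle_agreement(self):
        rng = np.random.default_rng(4)
        ages = rng.uniform(18, 79, 50)
        vals = 0.7 + 0.004 * ages - 4e-5 * ages**2 + rng.normal(0, 0.02, 50)
        model = fit_gpr(ages, vals, seed=0, n_restarts=2)
        grid = np.linspace(10, 90, 60)
        pred = predict(model, grid)
        mean_o, sd_o = gp_oracle(model, grid)
        assert np.allclose(pred.mean, mean_o, atol=1e-8)
        assert np.allclose(pred.sd, sd_o, atol=1e-8)

    def test_sd_positive_and_grows_beyond_data(self):
        ages, vals = _linear_data(50, seed=5, noise=0.05)
        model = fit_gpr(ages, vals, seed=0, n_restarts=1)
        far = np.array([90.0, 120.0, 200.0, 400.0])
        pred = predict(model, far)
        assert np.all(pred.sd > 0)
        assert np.all(np.diff(pred.sd) >= -1e-12)  # non-decreasing beyond the data
        assert pred.extrapolated.all()
        inside = predict(model, np.array([50.0]))
        assert not inside.extrapolated.any()

    def test_zscore_affine_invariance(self):
        ages, vals = _linear_data(60, seed=6, noise=0.05)
        m1 = fit_gpr(ages, vals, seed=0, n_restarts=1)
        m2 = fit_gpr(ages, 100.0 * vals + 7.0, seed=0, n_restarts=1)
        test_a = np.linspace(20, 75, 30)
        test_v = 0.5 + 0.01 * test_a + 0.03
        z1 = deviation_z(m1, test_a, test_v)
        z2 = deviation_z(m2, test_a, 100.0 * test_v + 7.0)
        assert np.allclose(z1, z2, atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            fit_gpr(np.arange(10.0) + 20, np.ones(10) + np.arange(10) * 0.1, seed=0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_gpr(np.linspace(20, 70, 25), np.full(25, 1.0), seed=0)


def _cohort_frame(n_subjects, seed, noise=0.05):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(18, 79, n_subjects)
    rows = []
    for i, a in enumerate(ages):
        for h in ("L", "R"):
            rows.append(
                {
                    "subject_id": f"s{i:04d}",
                    "age": a,
                    "hemisphere": h,
                    "roi": "Pu", "metric": "R1", "statistic": "median",
                    "value": 0.74 + 0.0045 * a - 4.5e-5 * a**2 + rng.normal(0, noise),
                }
            )
    return pd.DataFrame(rows)


class TestCrossval:
    def test_hemispheres_share_folds_and_sizes_valid(self):
        df = _cohort_frame(40, seed=7)
        out = zscore_crossval(df, k=4, seed=0, n_restarts=0)
        per_subj = out.groupby("subject_id")["fold"].nunique()
        assert (per_subj == 1).all()
        sizes = out.groupby("fold")["subject_id"].nunique()
        assert sizes.min() >= 2 and len(sizes) == 4
        assert out["z"].notna().all()
        assert (out["source"] == "crossval").all()

    def test_calibration_on_generative_model(self):
        # scaled-down version of the large-n calibration: ~95% within +-1.96
        df = _cohort_frame(200, seed=8, noise=0.02)
        out = zscore_crossval(df, k=10, seed=0, n_restarts=1)
        frac = (out["z"].abs() <= 1.96).mean()
        assert 0.93 <= frac <= 0.97
        assert abs(out["z"].mean()) < 0.1

    def test_too_few_subjects_rejected(self):
        df = _cohort_frame(12, seed=9)
        with pytest.raises(ValueError, match="subjects"):
            zscore_crossval(df, k=10, seed=0)


class TestApply:
    def _model(self):
        rng = np.random.default_rng(10)
        ages = rng.uniform(18, 79, 120)
        vals = 20.0 + 0.1 * ages + rng.normal(0, 1.0, 120)
        return fit_gpr(ages, vals, seed=0, n_restarts=1)

    def test_on_mean_gives_zero_and_definitional_z(self):
        model = self._model()
        pred = predict(model, np.array([50.0]))
        rows = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "age": [50.0, 50.0],
                "value": [pred.mean[0], pred.mean[0] + 1.96 * pred.sd[0]],
            }
        )
        out = zscore_apply(model, rows, corrected=True)
        assert out["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["z"].iloc[1] == pytest.approx(1.96, abs=1e-12)
        assert (out["source"] == "applied").all()

    def test_uncorrected_input_refused(self):
        model = self._model()
        rows = pd.DataFrame({"subject_id": ["a"], "age": [50.0], "value": [20.0]})
        with pytest.raises(ValueError, match="corrected"):
            zscore_apply(model, rows)

    def test_healthy_cohort_median_z_near_zero(self):
        # the GP's own fit error shifts all applied scores coherently, so the
        # calibration property concerns the median averaged over repetitions
        rng = np.random.default_rng(11)
        medians = []
        for rep in range(5):
            ages = rng.uniform(18, 79, 200)
            vals = 20.0 + 0.1 * ages + rng.normal(0, 1.0, 200)
            model = fit_gpr(ages, vals, seed=rep, n_restarts=1)
            a2 = rng.uniform(18, 79, 300)
            v2 = 20.0 + 0.1 * a2 + rng.normal(0, 1.0, 300)
            rows = pd.DataFrame({"subject_id": [f"n{i}" for i in range(300)],
                                 "age": a2, "value": v2})
            medians.append(zscore_apply(model, rows, corrected=True)["z"].median())
        assert abs(np.mean(medians)) <= 0.15

    def test_serialization_round_trip(self, tmp_path):
        model = self._model()
        path = tmp_path / "model.json"
        model.to_json(path)
        clone = NormativeModel.from_json(path)
        grid = np.linspace(18, 79, 40)
        a, b = predict(model, grid), predict(clone, grid)
        assert np.allclose(a.mean, b.mean, atol=1e-12)
        assert np.allclose(a.sd, b.sd, atol=1e-12)
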