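import numpy as np
import pytest

import zeitzeiger as zz
from zeitzeiger import Prediction, TimeStampedMatrix, ZeitZeiger


class TestTraining:
    def test_sumabsv_one_isolates_the_two_oscillating_features(self, two_sinusoid_data):
        ds = two_sinusoid_data
        model = ZeitZeiger(sumabsv=1.0, n_spc=2).fit(
            ds.data.values, ds.data.times, feature_ids=ds.data.feature_ids
        )
        selected = {ds.data.feature_ids[j] for j in model.predictor_features_}
        assert selected == {"signal_000", "signal_001"}

    def test_training_is_deterministic(self, two_sinusoid_data):
        ds = two_sinusoid_data
        a = ZeitZeiger(sumabsv=2.0, n_spc=2).fit(ds.data.values, ds.data.times)
        b = ZeitZeiger(sumabsv=2.0, n_spc=2).fit(ds.data.values, ds.data.times)
        np.testing.assert_array_equal(a.loadings_, b.loadings_)
        for da, db in zip(a.spc_densities_, b.spc_densities_):
            np.testing.assert_array_equal(da.mean_curve.coef, db.mean_curve.coef)
            assert da.variance == db.variance

    def test_n_spc_above_m_rejected_upfront(self):
        with pytest.raises(ValueError, match="n_spc"):
            ZeitZeiger(n_spc=13, m=12).fit(np.zeros((4, 3)), np.zeros(4))

    def test_period_rescaling(self, two_sinusoid_data):
        ds = two_sinusoid_data
        a = ZeitZeiger(sumabsv=2.0, n_spc=2, period=1.0).fit(ds.data.values, ds.data.times)
        b = ZeitZeiger(sumabsv=2.0, n_spc=2, period=24.0).fit(
            ds.data.values, ds.data.times * 24.0
        )
        np.testing.assert_allclose(a.loadings_, b.loadings_)

    def test_missing_training_values_tolerated(self):
        ds = zz.simulate(
            zz.SimulationConfig(
                n_signal_features=5, n_noise_features=45, n_timepoints_per_cycle=12,
                n_replicates=4, n_groups=1, amplitudes=2.0,
                phases=np.arange(5) / 5, noise_sd=0.3, missing_rate=0.1, seed=4,
            )
        )
        model = ZeitZeiger(sumabsv=2.0, n_spc=2).fit(ds.data.values, ds.data.times)
        assert np.all(np.isfinite(model.x_tilde_))


class TestProjection:
    def test_zero_vector_projects_to_zero(self, benchmark_model):
        scores = benchmark_model.project(np.zeros((1, 500)))
        np.testing.assert_array_equal(scores, 0.0)

    def test_one_hot_returns_loading_row(self, benchmark_model):
        j = int(benchmark_model.predictor_features_[0])
        w = np.zeros(500)
        w[j] = 1.0
        np.testing.assert_array_equal(
            benchmark_model.project(w[None, :])[0], benchmark_model.loadings_[j]
        )

    def test_training_projection_consistency(self, benchmark, benchmark_model):
        np.testing.assert_array_equal(
            benchmark_model.project(benchmark.data.values), benchmark_model.x_tilde_
        )

    def test_missing_predictor_feature_rejected_with_names(self, benchmark, benchmark_model):
        w = benchmark.data.values[0].copy()
        j = int(benchmark_model.predictor_features_[0])
        w[j] = np.nan
        with pytest.raises(ValueError, match="missing measurements") as exc:
            benchmark_model.predict_one(w)
        assert benchmark.data.feature_ids[j] in str(exc.value)


class TestLogLikelihood:
    def test_zero_at_mean_with_unit_density(self, benchmark_model):
        import copy

        model = copy.deepcopy(benchmark_model)
        model.n_spc = 1
        model.spc_densities_[0].variance = 1.0 / (2.0 * np.pi)
        t = 0.37
        w_tilde = np.array([float(model.spc_densities_[0].mean_curve.evaluate(t))])
        assert model.log_likelihood(w_tilde, t) == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_decay_off_the_mean(self, benchmark_model):
        t = 0.1
        mu = np.array(
            [float(d.mean_curve.evaluate(t)) for d in benchmark_model.spc_densities_]
        )
        base = benchmark_model.log_likelihood(mu, t)
        delta = 0.7
        shifted = mu.copy()
        shifted[0] += delta
        drop = base - benchmark_model.log_likelihood(shifted, t)
        s2 = benchmark_model.spc_densities_[0].variance
        assert drop == pytest.approx(delta**2 / (2 * s2), rel=1e-10)

    def test_additivity_over_components(self, benchmark_model):
        import copy

        w_tilde = np.array([0.3, -0.8])
        t = 0.42
        both = benchmark_model.log_likelihood(w_tilde, t)
        parts = []
        for k in range(2):
            single = copy.deepcopy(benchmark_model)
            single.n_spc = 1
            single.spc_densities_ = [benchmark_model.spc_densities_[k]]
            parts.append(single.log_likelihood(w_tilde[k : k + 1], t))
        assert both == pytest.approx(sum(parts), rel=1e-12)

    def test_likelihood_is_periodic(self, benchmark_model):
        w_tilde = np.array([1.0, -0.5])
        for t in [0.0, 0.123, 0.5, 0.9]:
            a = benchmark_model.log_likelihood(w_tilde, t)
            b = benchmark_model.log_likelihood(w_tilde, np.mod(t + 1.0, 1.0))
            c = benchmark_model.log_likelihood(w_tilde, np.mod(t - 1.0, 1.0))
            assert a == pytest.approx(b, abs=1e-8)
            assert a == pytest.approx(c, abs=1e-8)


class TestPrediction:
    def test_noiseless_observation_recovers_time(self, benchmark, benchmark_model):
        t0 = 0.3
        w = np.array(
            [d.mean_curve.evaluate(t0) for d in benchmark_model.feature_densities_]
        )
        pred = benchmark_model.predict_one(w)
        assert abs(pred.time_hat - t0) < 0.01

    def test_prediction_matches_brute_force_grid(self, benchmark):
        """Grid + local refinement must agree with a dense 10k-point argmax."""
        rng = np.random.default_rng(0)
        fine = np.arange(10_000) / 10_000
        worst = 0.0
        model = zz.ZeitZeiger(sumabsv=2.0, n_spc=2).fit(
            benchmark.data.values, benchmark.data.times
        )
        for _ in range(20):
            w = rng.normal(size=500)
            pred = model.predict_one(w)
            ll = model.log_likelihood(model.project(w[None, :])[0], fine)
            t_star = fine[int(np.argmax(ll))]
            err = min(abs(pred.time_hat - t_star), 1 - abs(pred.time_hat - t_star))
            worst = max(worst, err)
        assert worst < 2e-4

    def test_symmetric_likelihood_tie_breaks_to_smaller_t(self, benchmark_model):
        import copy

        model = copy.deepcopy(benchmark_model)
        model.n_spc = 1
        # a symmetric pure-cosine mean curve: equal maxima at +/- t
        from zeitzeiger.periodic import PeriodicCurve, TimeDensity

        coef = np.zeros(8)
        curve = PeriodicCurve(coef=coef, n_knots=8)
        curve._spline = None
        curve.evaluate = lambda t: np.cos(2 * np.pi * np.mod(np.asarray(t, dtype=float), 1.0))
        model.spc_densities_ = [TimeDensity(mean_curve=curve, variance=0.1, n_used=10)]
        pred = model._argmax_likelihood(np.array([-1.0]))  # score at the trough
        assert pred.time_hat == pytest.approx(0.5, abs=1e-6)

    def test_curve_max_matches_reported_likelihood(self, benchmark, benchmark_model):
        pred = benchmark_model.predict_one(benchmark.data.values[3], keep_curve=True)
        assert pred.log_likelihood >= pred.curve[:, 1].max() - 1e-9

    def test_zeroing_non_predictor_features_changes_nothing(self, benchmark, benchmark_model):
        w = benchmark.data.values[10].copy()
        w_sparse = np.zeros_like(w)
        w_sparse[benchmark_model.predictor_features_] = w[
            benchmark_model.predictor_features_
        ]
        a = benchmark_model.predict_one(w)
        b = benchmark_model.predict_one(w_sparse)
        assert a.time_hat == b.time_hat
        assert a.log_likelihood == b.log_likelihood


class TestPredictBatch:
    def test_empty_matrix_gives_empty_list(self, benchmark_model):
        assert benchmark_model.predict_batch(np.empty((0, 500))) == []

    def test_single_row_equals_predict_one(self, benchmark, benchmark_model):
        row = benchmark.data.values[5]
        single = benchmark_model.predict_one(row)
        batch = benchmark_model.predict_batch(row[None, :])
        assert len(batch) == 1
        assert batch[0].time_hat == single.time_hat

    def test_row_permutation_permutes_predictions(self, benchmark, benchmark_model):
        rows = benchmark.data.values[:6]
        perm = [4, 2, 0, 5, 1, 3]
        direct = benchmark_model.predict_batch(rows)
        permuted = benchmark_model.predict_batch(rows[perm])
        for i, j in enumerate(perm):
            assert permuted[i].time_hat == direct[j].time_hat

    def test_predict_returns_native_units(self, benchmark):
        model = ZeitZeiger(sumabsv=3.0, n_spc=2, period=24.0).fit(
            benchmark.data.values, benchmark.data.times * 24.0
        )
        t_hat = model.predict(benchmark.data.values[:5])
        assert np.all((0 <= t_hat) & (t_hat < 24.0))

    def test_sklearn_param_interface(self):
        model = ZeitZeiger(sumabsv=1.5)
        assert model.get_params()["sumabsv"] == 1.5
        model.set_params(n_spc=3)
        assert model.n_spc == 3


def test_function_surface_mirrors_estimator(two_sinusoid_data):
    ds = two_sinusoid_data
    model = zz.train(ds.data, sumabsv=1.0, n_spc=2)
    scores = zz.project(model, ds.data.values[:3])
    assert scores.shape == (3, 12)
    pred = zz.predict(model, ds.data.values[0])
    assert isinstance(pred, Prediction)
    assert 0 <= pred.time_hat < 1
    assert zz.log_likelihood(model, scores[0], pred.time_hat) == pytest.approx(
        model.log_likelihood(scores[0], pred.time_hat)
    )
    batch = zz.predict_batch(model, ds.data.values[:3])
    assert [p.time_hat for p in batch][0] == pred.time_hat
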