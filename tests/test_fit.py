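"""Smoothing, forward prediction and least-squares parameter recovery."""

import numpy as np
import pytest

from camppka.fit import (
    FitSpec,
    fit_report,
    fit_timeseries,
    model_prediction,
    smooth_blackman,
)
from camppka.io import TimeSeries
from camppka.model import CampPkaModel
from camppka.params import load_parameter_fixture
from camppka.synthetic import NoiseModel, experimental_grid, generate_dataset, noiseless_curve


@pytest.fixture(scope="module")
def sigma_wt():
    return load_parameter_fixture("sigma1278b_wt")


@pytest.fixture(scope="module")
def sigma_data(sigma_wt):
    cfg, scale = sigma_wt
    times = experimental_grid()
    return TimeSeries(
        times=times, values=noiseless_curve(cfg, scale, times), strain="sigma1278b"
    )


class TestBlackmanSmoother:
    def test_constant_series_unchanged(self):
        ts = TimeSeries(times=np.arange(9.0), values=np.full(9, 3.5))
        out = smooth_blackman(ts, 5)
        assert np.allclose(out.values, 3.5)

    def test_window_one_is_identity(self):
        ts = TimeSeries(times=np.arange(5.0), values=np.array([1.0, 4.0, 2.0, 5.0, 3.0]))
        assert np.array_equal(smooth_blackman(ts, 1).values, ts.values)

    def test_impulse_response_is_normalized_kernel(self):
        """Hand evaluation of the cosine kernel at L=5:
        raw weights (0, .34, 1, .34, 0), sum 1.68."""
        values = np.zeros(11)
        values[5] = 1.0
        ts = TimeSeries(times=np.arange(11.0), values=values)
        out = smooth_blackman(ts, 5)
        expected = np.array([0.0, 0.34, 1.0, 0.34, 0.0]) / 1.68
        assert np.allclose(out.values[3:8], expected, atol=1e-12)
        assert np.allclose(out.values[:3], 0.0) and np.allclose(out.values[8:], 0.0)

    def test_linear_in_the_data(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 10, 15)
        b = rng.uniform(0, 10, 15)
        t = np.arange(15.0)
        sa = smooth_blackman(TimeSeries(times=t, values=a), 7).values
        sb = smooth_blackman(TimeSeries(times=t, values=b), 7).values
        sab = smooth_blackman(TimeSeries(times=t, values=a + 2 * b), 7).values
        assert np.allclose(sab, sa + 2 * sb, atol=1e-12)

    def test_mean_preserved_under_reflection_padding(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(1, 5, 21)
        ts = TimeSeries(times=np.arange(21.0), values=vals)
        out = smooth_blackman(ts, 5)
        # Reflection padding keeps a constant series constant, and the
        # smoother is within machine noise of mean-preserving on data
        # whose reflected extension has the same mean.
        assert out.values.mean() == pytest.approx(vals.mean(), rel=0.02)

    @pytest.mark.parametrize("window", [2, 4, 99])
    def test_invalid_windows_rejected(self, window):
        ts = TimeSeries(times=np.arange(9.0), values=np.ones(9))
        with pytest.raises(ValueError):
            smooth_blackman(ts, window)


class TestModelPrediction:
    def test_time_zero_returns_starved_baseline(self, sigma_wt):
        cfg, scale = sigma_wt
        spec = FitSpec(config=cfg, scale=scale, free=("M",))
        pred = model_prediction({"M": cfg.params.M}, spec, np.array([0.0]))
        from camppka.steady_state import starved_initial_state

        assert pred[0] == pytest.approx(starved_initial_state(cfg).x * scale.x_scale)

    def test_self_consistent_at_generative_parameters(self, sigma_wt, sigma_data):
        cfg, scale = sigma_wt
        spec = FitSpec(config=cfg, scale=scale, free=("M", "D", "Gamma"))
        pred = model_prediction(
            {"M": cfg.params.M, "D": cfg.params.D, "Gamma": cfg.params.Gamma},
            spec,
            sigma_data.times,
        )
        assert np.max(np.abs(pred - sigma_data.values)) < 1e-8

    def test_sigma_curve_peaks_early_then_rings(self, sigma_data):
        """Regression fixture: the fitted strain shows a large peak
        within the first ~1.5 min followed by damped oscillation."""
        t, y = sigma_data.times, sigma_data.values
        i_peak = int(np.argmax(y))
        assert t[i_peak] <= 1.5
        assert y[i_peak] == pytest.approx(107.28, rel=1e-3)
        # at least two later local maxima: the decaying ring
        later = y[i_peak:]
        peaks = [
            k
            for k in range(1, later.size - 1)
            if later[k] > later[k - 1] and later[k] > later[k + 1]
        ]
        assert len(peaks) >= 2

    def test_integrator_failure_becomes_penalty(self, sigma_wt):
        cfg, scale = sigma_wt
        spec = FitSpec(config=cfg, scale=scale, free=("M",))
        times = np.array([0.0, 1.0])
        bad = model_prediction({"M": float("nan")}, spec, times)
        assert np.all(bad >= 1e5)


class TestFitTimeseries:
    def test_noiseless_self_fit_recovers_generative_values(self, sigma_wt, sigma_data):
        cfg, scale = sigma_wt
        truth = {"M": 0.085, "D": 0.247, "Gamma": 0.32}
        for factor in (3.0, 1.0 / 3.0):
            spec = FitSpec(
                config=cfg,
                scale=scale,
                free=("M", "D", "Gamma"),
                initial={k: v * factor for k, v in truth.items()},
            )
            res = fit_timeseries(sigma_data, spec)
            assert res.converged
            for name, value in truth.items():
                assert res.params[name] == pytest.approx(value, rel=0.01)

    def test_start_at_optimum_needs_no_improvement(self, sigma_wt, sigma_data):
        cfg, scale = sigma_wt
        spec = FitSpec(config=cfg, scale=scale, free=("M", "D", "Gamma"))
        res = fit_timeseries(sigma_data, spec)
        assert res.initial_rss == pytest.approx(0.0, abs=1e-8)
        assert res.rss <= res.initial_rss + 1e-12

    def test_objective_never_increases(self, sigma_wt, sigma_data):
        cfg, scale = sigma_wt
        spec = FitSpec(
            config=cfg,
            scale=scale,
            free=("M", "D", "Gamma"),
            initial={"M": 0.3, "D": 0.9, "Gamma": 1.2},
        )
        res = fit_timeseries(sigma_data, spec)
        assert res.rss <= res.initial_rss

    def test_noisy_replicates_recover_at_sampling_precision(self, sigma_wt):
        """With 10% multiplicative noise on 3 pooled replicates the
        rate parameters M and D come back within 10%; the Pde-cAMP
        affinity Gamma is weakly identified at its small fitted value
        (the decay term saturates for x >> Gamma), so its sampling
        error is several-fold larger — a Monte-Carlo bound of 60%
        covers it."""
        cfg, scale = sigma_wt
        data = generate_dataset(
            cfg, scale, noise=NoiseModel(cv=0.1, seed=42), n_replicates=3
        )
        truth = {"M": 0.085, "D": 0.247, "Gamma": 0.32}
        spec = FitSpec(
            config=cfg,
            scale=scale,
            free=("M", "D", "Gamma"),
            initial={k: 3 * v for k, v in truth.items()},
        )
        res = fit_timeseries(data, spec)
        assert res.params["M"] == pytest.approx(truth["M"], rel=0.10)
        assert res.params["D"] == pytest.approx(truth["D"], rel=0.10)
        assert res.params["Gamma"] == pytest.approx(truth["Gamma"], rel=0.60)

    def test_too_few_points_rejected(self, sigma_wt):
        cfg, scale = sigma_wt
        data = TimeSeries(times=np.array([0.0, 1.0]), values=np.array([10.0, 20.0]))
        spec = FitSpec(config=cfg, scale=scale, free=("M", "D", "Gamma"))
        with pytest.raises(ValueError):
            fit_timeseries(data, spec)


class TestFitReport:
    def test_single_result_single_row(self, sigma_wt, sigma_data):
        cfg, scale = sigma_wt
        spec = FitSpec(config=cfg, scale=scale, free=("M",))
        res = fit_timeseries(sigma_data, spec)
        table = fit_report([res])
        assert len(table) == 1
        assert table.index[0] == "sigma1278b"
        assert "rss" in table.columns

    def test_empty_strain_becomes_custom(self, sigma_wt, sigma_data):
        cfg, scale = sigma_wt
        spec = FitSpec(config=cfg, scale=scale, free=("M",))
        res = fit_timeseries(sigma_data, spec)
        table = fit_report({"": res})
        assert table.index[0] == "custom"


class TestModelResultsInterface:
    def test_fit_summary_and_predict(self, sigma_data):
        cfg, scale = load_parameter_fixture("sigma1278b_wt")
        model = CampPkaModel(
            sigma_data,
            genotype=cfg,
            scale=scale,
            free=("M", "D", "Gamma"),
            initial={"M": 0.255, "D": 0.741, "Gamma": 0.96},
        )
        results = model.fit()
        assert results.converged
        assert results.params["M"] == pytest.approx(0.085, rel=0.01)
        text = results.summary()
        assert "RSS" in text and "Gamma" in text
        pred = results.predict(sigma_data.times)
        assert np.max(np.abs(pred - sigma_data.values)) < 1e-4 * sigma_data.values.max()
        assert results.nobs == len(sigma_data)

    def test_from_dataframe_round_trip(self, sigma_data):
        cfg, scale = load_parameter_fixture("sigma1278b_wt")
        df = sigma_data.to_frame()
        model = CampPkaModel.from_dataframe(
            df, genotype=cfg, scale=scale, free=("M", "D", "Gamma")
        )
        assert len(model.data) == 1
        assert np.allclose(model.data[0].values, sigma_data.values)

    def test_multistart_keeps_best(self, sigma_data):
        cfg, scale = load_parameter_fixture("sigma1278b_wt")
        model = CampPkaModel(
            sigma_data, genotype=cfg, scale=scale, free=("M", "D", "Gamma")
        )
        results = model.fit(
            start={"M": 0.5, "D": 0.5, "Gamma": 0.5},
            multistart_factors=(3.0, 1 / 3.0),
        )
        assert results.rss < 1e-6
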