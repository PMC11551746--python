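"""Binding, association and dissociation estimators; laboratory arithmetic."""

import warnings

import numpy as np
import pytest

from strandex.estimators import (
    AssociationKinetics,
    BoundaryWarning,
    ExponentialDissociation,
    FitConfig,
    HillBindingCurve,
    NonDecayWarning,
    StrandExchangeEstimator,
    _ols_slope,
    aggregate_replicates,
    association_kinetics,
    concentration_from_absorbance,
    fit_dissociation,
    fit_hill,
    fit_time_course,
    stoichiometric_concentration,
)
from strandex.synthetic import (
    NoiseModel,
    generate_association,
    generate_dissociation,
    generate_exchange_course,
    generate_titration,
)
from strandex.timeseries import TimeCourseData


class TestHillBindingCurve:
    def test_noiseless_recovery_simple_isotherm(self):
        conc = np.logspace(-2, 1, 15)
        truth = dict(K_D=1.0, n=1.0, baseline=0.05, amplitude=0.10)
        data = generate_titration(
            K_D_uM=truth["K_D"], n=truth["n"], baseline=truth["baseline"],
            amplitude=truth["amplitude"], concentrations_uM=conc,
            noise=NoiseModel(sd=0.0),
        )
        est = fit_hill(data)
        assert est.K_D_ == pytest.approx(truth["K_D"], rel=1e-6)
        assert est.n_ == pytest.approx(truth["n"], rel=1e-6)
        assert est.baseline_ == pytest.approx(truth["baseline"], abs=1e-8)
        assert est.amplitude_ == pytest.approx(truth["amplitude"], rel=1e-6)

    def test_curve_passes_through_midpoint_at_kd(self):
        data = generate_titration(noise=NoiseModel(sd=0.0))
        est = fit_hill(data)
        mid = est.predict(np.array([est.K_D_]))[0]
        assert mid == pytest.approx(est.baseline_ + est.amplitude_ / 2, rel=1e-9)

    def test_requires_minimum_points(self):
        with pytest.raises(ValueError):
            HillBindingCurve().fit(np.array([0.1, 1, 10]), np.array([0.0, 0.05, 0.1]))


class TestAssociationKinetics:
    def test_nucleation_slope_exact_on_line(self):
        t = np.arange(0, 10.5, 0.5)
        y = 0.15 + 2.5e-3 * t
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = AssociationKinetics(nucleation_window=10.0).fit(t, y)
        assert est.V_N_ == pytest.approx(2.5e-3, rel=1e-12)

    def test_sigmoid_midpoint_and_recovery(self):
        data = generate_association(T_half=20.7, noise=NoiseModel(sd=0.0))
        est = association_kinetics(data, nucleation_window=10.0)
        assert est.T_half_ == pytest.approx(20.7, rel=1e-6)
        mid = est.predict(np.array([est.T_half_]))[0]
        assert mid == pytest.approx(est.baseline_ + est.amplitude_ / 2, rel=1e-9)
        # V_E approximates the analytic central slope of the sigmoid
        analytic = est.amplitude_ * est.n_ / (4 * est.T_half_)
        assert est.V_E_ == pytest.approx(analytic, rel=0.02)

    def test_elongation_window_is_closed_interval(self):
        data = generate_association(T_half=20.0, noise=NoiseModel(sd=0.0))
        est = association_kinetics(data)
        t = data.times
        n_window = np.sum((t >= est.T_half_ - 2) & (t <= est.T_half_ + 2))
        assert n_window == 9  # 0.5 s sampling: inclusive +/- 2 s window

    def test_vn_agrees_with_closed_form_ols(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 10.5, 0.5)
        y = 0.15 + 1e-3 * t + rng.normal(0, 1e-4, t.size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = AssociationKinetics().fit(t, y)
        coeffs = np.polyfit(t, y, 1)
        assert est.V_N_ == pytest.approx(coeffs[0], rel=1e-10)


class TestExponentialDissociation:
    def test_noiseless_recovery_to_high_precision(self):
        data = generate_dissociation(
            k_off=0.05, amplitude=0.08, baseline=0.21, noise=NoiseModel(sd=0.0)
        )
        est = fit_dissociation(data)
        assert est.k_off_ == pytest.approx(0.05, rel=1e-8)
        assert est.amplitude_ == pytest.approx(0.08, rel=1e-8)
        assert est.baseline_ == pytest.approx(0.21, rel=1e-8)
        # value at t=0 equals amplitude + baseline
        assert est.predict(np.array([0.0]))[0] == pytest.approx(0.29, rel=1e-9)

    def test_agrees_with_log_linear_oracle_on_baseline_free_decay(self):
        t = np.arange(0, 100.5, 0.5)
        y = 0.12 * np.exp(-0.03 * t)
        est = ExponentialDissociation().fit(t, y + 0.0)
        k_oracle = -_ols_slope(t, np.log(y))
        assert est.k_off_ == pytest.approx(k_oracle, rel=1e-8)

    def test_constant_series_warns_and_returns_zero_rate(self):
        t = np.arange(0, 50.5, 0.5)
        with pytest.warns(NonDecayWarning):
            est = ExponentialDissociation().fit(t, np.full(t.size, 0.2))
        assert est.k_off_ == 0.0
        assert est.amplitude_ == pytest.approx(0.0, abs=1e-12)

    def test_half_life_identity(self):
        data = generate_dissociation(
            k_off=0.1, amplitude=0.1, baseline=0.2, noise=NoiseModel(sd=0.0)
        )
        est = fit_dissociation(data)
        t_half = np.log(2) / est.k_off_
        decayed = est.predict(np.array([t_half]))[0]
        assert decayed - est.baseline_ == pytest.approx(est.amplitude_ / 2, rel=1e-6)


class TestStrandExchangeFitBehaviour:
    def test_flat_data_pins_capture_rate_at_lower_bound(self):
        times = np.arange(0, 501, 25.0)
        data = TimeCourseData(times=times, values=np.full(times.size, 100.0))
        with pytest.warns(BoundaryWarning):
            fit = fit_time_course(data, FitConfig(n_starts=2, seed=0, rtol=1e-6))
        assert fit.rates_.k1 == pytest.approx(1e-7, rel=1e-2)

    def test_fit_is_deterministic_given_seed(self):
        data = generate_exchange_course(
            times=np.arange(0, 1001, 50.0), noise=NoiseModel(sd=1.0, seed=4)
        )
        cfg = FitConfig(n_starts=3, seed=9, rtol=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = fit_time_course(data, cfg)
            f2 = fit_time_course(data, cfg)
        assert f1.rates_ == f2.rates_
        assert f1.ssr_ == f2.ssr_

    def test_sklearn_param_protocol(self):
        est = StrandExchangeEstimator(n_starts=5, seed=3)
        params = est.get_params()
        assert params["n_starts"] == 5
        est.set_params(seed=7)
        assert est.seed == 7


class TestLaboratoryArithmetic:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((83, 36, 3, 2), 1.992),
            ((3, 1000, 3, 1), 1.0),
            ((30, 100, 3, 2), 2.0),
        ],
    )
    def test_stoichiometric_concentration(self, args, expected):
        assert stoichiometric_concentration(*args) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "absorbance, epsilon, expected",
        [(1.23, 1.23e4, 1e-4), (0.0, 1.23e4, 0.0), (0.186, 1.86e4, 1e-5)],
    )
    def test_concentration_from_absorbance(self, absorbance, epsilon, expected):
        assert concentration_from_absorbance(absorbance, epsilon) == pytest.approx(
            expected
        )

    def test_aggregate_replicates(self):
        assert aggregate_replicates([1, 1, 1]) == (1.0, 0.0, 3)
        mean, sd, n = aggregate_replicates([1, 2, 3])
        assert (mean, sd, n) == (2.0, 1.0, 3)
        assert aggregate_replicates([3, 1, 2])[:2] == (mean, sd)
        with pytest.raises(ValueError):
            aggregate_replicates([1.0])
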