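"""Reactivity-ratio estimators, averaging, gradient classes, ternary fits."""

import numpy as np
import pytest

from ppekinetics import (
    ConversionSeries,
    assess_gradient,
    average_models,
    fit_bsl,
    fit_ideal_integrated,
    fit_jaacks,
    fit_pair,
    fit_ternary,
)

from conftest import make_series, ternary_series

FITTERS = {"jaacks": fit_jaacks, "bsl": fit_bsl, "ideal": fit_ideal_integrated}


def constant_series(x_a, x_b, n=6):
    x = np.column_stack([np.linspace(0, x_a, n), np.linspace(0, x_b, n)])
    return ConversionSeries(
        time=np.arange(n, dtype=float), species=["A", "B"],
        x=x, X=x @ np.array([0.5, 0.5]), f0=np.array([0.5, 0.5]),
    )


class TestSingleModelRecovery:
    @pytest.mark.parametrize("model", list(FITTERS))
    def test_recovers_true_ratio_noiseless(self, model):
        series = make_series(3.0)
        est = FITTERS[model](series, ("A", "B"))
        assert est.r1 == pytest.approx(3.0, rel=1e-6)
        assert est.r2 == pytest.approx(1.0 / 3.0, rel=1e-6)
        assert est.R2 == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("model", list(FITTERS))
    def test_equal_rates_give_unity(self, model):
        series = make_series(1.0)
        est = FITTERS[model](series, ("A", "B"))
        assert est.r1 == pytest.approx(1.0, rel=1e-6)
        assert est.r2 == pytest.approx(1.0, rel=1e-6)

    def test_jaacks_identical_columns_slope_one(self):
        series = constant_series(0.6, 0.6)
        est = fit_jaacks(series, ("A", "B"))
        assert est.r1 == 1.0 and est.r2 == 1.0

    def test_no_consumption_is_an_error(self):
        series = constant_series(0.0, 0.0)
        with pytest.raises(ValueError, match="consumption"):
            fit_jaacks(series, ("A", "B"))

    def test_bsl_zero_residual_at_unity(self):
        series = make_series(1.0)
        est = fit_bsl(series, ("A", "B"))
        ia, ib = series.index("A"), series.index("B")
        resid = series.x[:, ib] - (1 - (1 - series.x[:, ia]) ** (1 / est.r1))
        assert np.max(np.abs(resid)) < 1e-9

    def test_ideal_flat_composition_at_unity(self):
        series = make_series(1.0, f0=(0.4, 0.6))
        est = fit_ideal_integrated(series, ("A", "B"))
        assert est.r1 == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("model", ["jaacks", "bsl"])
    def test_swap_antisymmetry(self, model):
        series = make_series(4.0, noise_sigma=0.02, seed=6)
        fwd = FITTERS[model](series, ("A", "B"))
        rev = FITTERS[model](series, ("B", "A"))
        assert fwd.r1 == rev.r2 and fwd.r2 == rev.r1


class TestModelEquivalence:
    @pytest.mark.parametrize("true_r", [0.1, 0.5, 1.0, 2.0, 5.0, 20.0])
    def test_three_models_agree_noiseless(self, true_r):
        series = make_series(true_r)
        ests = [f(series, ("A", "B")) for f in FITTERS.values()]
        r1s = [e.r1 for e in ests]
        assert np.ptp(r1s) / np.mean(r1s) < 1e-6
        for e in ests:
            assert e.r1 == pytest.approx(true_r, rel=1e-3)
            assert e.r1 * e.r2 == pytest.approx(1.0, rel=0.02)


class TestNoiseBehaviour:
    def test_mean_recovery_under_noise(self):
        # 30 replicates suffice for a smoke check; the full 200-replicate
        # calibration lives in the acceptance suite
        means = []
        for seed in range(30):
            series = make_series(5.0, n_points=50, noise_sigma=0.02, seed=seed)
            avg = average_models(fit_pair(series, ("A", "B")))
            means.append(avg.r1_mean)
        assert np.mean(means) == pytest.approx(5.0, rel=0.05)

    def test_sd_decreases_with_more_points(self):
        def spread(n_points):
            vals = [
                average_models(
                    fit_pair(
                        make_series(5.0, n_points=n_points, noise_sigma=0.02, seed=s),
                        ("A", "B"),
                    )
                ).r1_mean
                for s in range(25)
            ]
            return np.std(vals)

        assert spread(60) < spread(12)

    def test_truncation_stability_within_se(self):
        series60 = make_series(5.0, n_points=50, noise_sigma=0.02, seed=2, x_max=0.6)
        series50 = make_series(5.0, n_points=50, noise_sigma=0.02, seed=2, x_max=0.5)
        e60 = fit_jaacks(series60, ("A", "B"))
        e50 = fit_jaacks(series50, ("A", "B"))
        assert abs(e60.r1 - e50.r1) < 5 * max(e60.se1, e50.se1)


class TestAveraging:
    def test_mean_and_sample_sd(self):
        from ppekinetics import ReactivityEstimate

        ests = [
            ReactivityEstimate(m, ("A", "B"), r, 1.0 / r, 0.0, 0.0, 1.0, 10, 0.6)
            for m, r in zip(("jaacks", "bsl", "ideal"), (5.2, 4.9, 4.6))
        ]
        avg = average_models(ests)
        assert avg.r1_mean == pytest.approx(4.9, abs=1e-12)
        assert avg.r1_sd == pytest.approx(0.3, abs=1e-12)

    def test_single_model_warns_sd_zero(self):
        from ppekinetics import ReactivityEstimate

        est = ReactivityEstimate("jaacks", ("A", "B"), 2.0, 0.5, 0.0, 0.0, 1.0, 10, 0.6)
        with pytest.warns(UserWarning, match="single model"):
            avg = average_models([est])
        assert avg.r1_sd == 0.0

    def test_empty_inclusion_set_is_error(self):
        from ppekinetics import ReactivityEstimate

        est = ReactivityEstimate("jaacks", ("A", "B"), 2.0, 0.5, 0.0, 0.0, 1.0, 10, 0.6)
        with pytest.raises(ValueError, match="no estimates"):
            average_models([est], excluded=(("jaacks", "bad fit"),))

    def test_preset_pipeline_round_trip(self):
        from ppekinetics import conversions, generate, preset, truncate

        cfg = preset("P1", noise_sigma=0.0, n_points=60)
        series = truncate(conversions(generate(cfg)), 0.6)
        avg = average_models(fit_pair(series, ("PhPPn", "MePPn")))
        true_r1 = cfg.rates.ratio("PhPPn", "MePPn")
        assert avg.r1_mean == pytest.approx(true_r1, rel=1e-3)


class TestGradientClasses:
    @pytest.mark.parametrize(
        "r1, r2, expected_class",
        [
            (4.9, 0.21, "medium"),      # Δr = 4.69
            (26.02, 0.0384, "block"),   # Δr ~ 26
            (1.0, 1.0, "soft"),
        ],
    )
    def test_classification(self, r1, r2, expected_class):
        grad = assess_gradient((r1, r2))
        assert grad.gradient_class == expected_class

    def test_p1_printed_ratios_round_to_five(self):
        grad = assess_gradient((4.9, 0.21))
        assert grad.delta_r == pytest.approx(4.69, abs=1e-12)
        assert round(grad.delta_r) == 5

    @pytest.mark.parametrize(
        "delta, expected",
        [(1.5, "soft"), (1.50001, "medium"), (7.5, "medium"),
         (7.50001, "hard"), (25.0, "hard"), (25.00001, "block")],
    )
    def test_boundaries_half_open(self, delta, expected):
        # (1 + delta, 1) keeps the difference exactly representable
        grad = assess_gradient((1.0 + delta, 1.0))
        assert grad.gradient_class == expected

    def test_order_independent(self):
        assert assess_gradient((0.21, 4.9)).delta_r == assess_gradient((4.9, 0.21)).delta_r

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            assess_gradient((0.0, 1.0))


class TestTernary:
    def test_noiseless_recovery_and_transitivity(self):
        series = ternary_series(k=(4.0, 2.0, 1.0))
        table = fit_ternary(series)
        r = table.ratio_dict()
        assert r[("A", "B")] == pytest.approx(2.0, rel=1e-3)
        assert r[("A", "C")] == pytest.approx(4.0, rel=1e-3)
        assert r[("B", "C")] == pytest.approx(2.0, rel=1e-3)
        assert r[("A", "C")] == pytest.approx(r[("A", "B")] * r[("B", "C")], rel=1e-3)

    def test_symmetric_system_all_unity(self):
        series = ternary_series(k=(1.0, 1.0, 1.0))
        for value in fit_ternary(series).ratio_dict().values():
            assert value == pytest.approx(1.0, rel=1e-6)

    def test_p9_round_trip_within_two_percent(self):
        from ppekinetics import conversions, generate, preset, truncate

        cfg = preset("P9", noise_sigma=0.0, n_points=60)
        series = truncate(conversions(generate(cfg)), 0.6)
        table = fit_ternary(series)
        g12 = assess_gradient(table.averages[("EtPPn", "ETP")])
        g23 = assess_gradient(table.averages[("ETP", "EPP")])
        assert g12.delta_r == pytest.approx(14.0, rel=0.02)
        assert g23.delta_r == pytest.approx(13.0, rel=0.02)

    def test_lambda_flags_excluded_from_average(self):
        series = ternary_series(k=(4.0, 2.0, 1.0), noise_sigma=0.01, seed=4)
        flags = ((("A", "B"), "bsl", "unstable fit"),)
        table = fit_ternary(series, lambda_flags=flags)
        avg = table.averages[("A", "B")]
        assert "bsl" not in avg.models
        assert ("bsl", "unstable fit") in avg.excluded
        # other pairs unaffected
        assert set(table.averages[("A", "C")].models) == {"jaacks", "bsl", "ideal"}

    def test_non_ternary_series_needs_explicit_triple(self):
        series = make_series(2.0)
        with pytest.raises(ValueError, match="not ternary"):
            fit_ternary(series)
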