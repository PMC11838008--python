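"""Calibration: weighted cost, multistart fit, Fisher-information CIs,
goodness of fit, product-model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fermflux as ff
from fermflux.calibration import _PENALTY_RESIDUAL
from fermflux.kinetics import IntegrationError


def quiescent_config(**param_overrides):
    """Configuration whose model holds every state constant (no nitrogen,
    no secondary growth) unless a mechanism is switched back on."""
    params = ff.preset_parameters("fast").with_values(
        {"phi_c": 0.0, "kc_mal": 0.0, **param_overrides})
    return ff.ModelConfiguration(
        name="quiescent", params=params,
        estimable=("y_eth", "vmax_glx", "kc_mal", "k_nh4", "yxn"))


def replicate_rows(obs, time, mean, spread):
    """Three replicates (m - s, m, m + s): sample std exactly ``spread``."""
    return [
        {"time": time, "observable": obs, "replicate": r + 1, "value": v}
        for r, v in enumerate((mean - spread, mean, mean + spread))
    ]


def dataset_from_points(points, initial_state, **kwargs):
    rows = []
    for obs, time, mean, spread in points:
        rows.extend(replicate_rows(obs, time, mean, spread))
    return ff.TimeSeriesDataset(pd.DataFrame(rows), initial_state, **kwargs)


class TestWeightedCost:
    def test_hand_summed_residuals(self):
        """Constant-prediction setup reproduces the weighted sum exactly."""
        config = quiescent_config()
        y0 = ff.make_initial_state(XC=0.29, XP=0.59, XmRNA=0.12, Eth=5.0)
        # residuals (1, 2, 0.25) at sigma (1, 2, 0.5): cost 1 + 1 + 0.25
        dataset = dataset_from_points(
            [("Eth", 1.0, 6.0, 1.0), ("Eth", 2.0, 7.0, 2.0),
             ("Eth", 3.0, 5.25, 0.5)], y0)
        cost = ff.weighted_llk_cost(config.params, dataset, config)
        assert cost == pytest.approx(2.25, rel=1e-6)

    def test_single_point(self):
        config = quiescent_config()
        y0 = ff.make_initial_state(XC=0.29, XP=0.59, XmRNA=0.12, Eth=5.0)
        dataset = dataset_from_points([("Eth", 2.0, 7.0, 1.0)], y0)
        assert ff.weighted_llk_cost(config.params, dataset, config) == (
            pytest.approx(4.0, rel=1e-6))

    def test_perfect_prediction_costs_zero(self):
        params = ff.preset_parameters("fast")
        dataset, _ = ff.generate_dataset(params, ff.synthetic_must(),
                                         ff.SamplingDesign(cv=0.0, seed=3))
        config = ff.ModelConfiguration(name="t", params=params,
                                       estimable=("vmax_glx",))
        assert ff.weighted_llk_cost(params, dataset, config) < 1e-8

    def test_invariant_under_reordering(self):
        params = ff.preset_parameters("fast")
        dataset, _ = ff.generate_dataset(params, ff.synthetic_must(),
                                         ff.SamplingDesign(cv=0.02, seed=4))
        config = ff.ModelConfiguration(name="t", params=params,
                                       estimable=("vmax_glx",))
        shuffled = ff.TimeSeriesDataset(
            dataset.data.sample(frac=1.0, random_state=0),
            dataset.initial_state)
        assert ff.weighted_llk_cost(params, shuffled, config) == (
            pytest.approx(ff.weighted_llk_cost(params, dataset, config),
                          rel=1e-12))

    def test_sigma_scaling(self):
        """Doubling every sigma quarters the cost."""
        config = quiescent_config()
        y0 = ff.make_initial_state(XC=0.29, XP=0.59, XmRNA=0.12, Eth=5.0)
        d1 = dataset_from_points(
            [("Eth", 1.0, 6.0, 1.0), ("Eth", 2.0, 7.0, 2.0)], y0)
        d2 = dataset_from_points(
            [("Eth", 1.0, 6.0, 2.0), ("Eth", 2.0, 7.0, 4.0)], y0)
        c1 = ff.weighted_llk_cost(config.params, d1, config)
        c2 = ff.weighted_llk_cost(config.params, d2, config)
        assert c2 == pytest.approx(c1 / 4.0, rel=1e-9)

    def test_integration_failure_penalized(self, monkeypatch):
        config = quiescent_config()
        y0 = ff.make_initial_state(XC=0.29, XP=0.59, XmRNA=0.12, Eth=5.0)
        dataset = dataset_from_points([("Eth", 2.0, 7.0, 1.0)], y0)

        def boom(*args, **kwargs):
            raise IntegrationError("synthetic failure", 1.0)

        monkeypatch.setattr("fermflux.calibration.simulate", boom)
        cost = ff.weighted_llk_cost(config.params, dataset, config)
        assert cost == pytest.approx(_PENALTY_RESIDUAL ** 2)


class TestFit:
    def test_noise_free_fixed_point(self):
        """Initialized at the generating parameters, the fit stays there."""
        params = ff.preset_parameters("fast")
        dataset, _ = ff.generate_dataset(
            params, ff.synthetic_must(),
            ff.SamplingDesign(cv=0.0, seed=5,
                              observables=("X", "Glx", "F", "Eth")))
        config = ff.ModelConfiguration(name="t", params=params,
                                       estimable=("vmax_glx", "y_eth"))
        result = ff.fit(dataset, config,
                        ff.OptimizerSettings(seed=1, n_starts=0))
        assert result.cost < 1e-8
        assert result.theta_hat.vmax_glx == pytest.approx(params.vmax_glx,
                                                          rel=1e-6)
        assert result.theta_hat.y_eth == pytest.approx(params.y_eth, rel=1e-6)

    def test_cost_never_above_trace(self):
        params = ff.preset_parameters("fast")
        dataset, _ = ff.generate_dataset(
            params, ff.synthetic_must(),
            ff.SamplingDesign(cv=0.01, seed=6,
                              observables=("X", "Glx", "Eth")))
        config = ff.ModelConfiguration(name="t", params=params,
                                       estimable=("vmax_glx", "y_eth"))
        result = ff.fit(dataset, config,
                        ff.OptimizerSettings(seed=2, n_starts=2, max_nfev=40))
        assert result.cost <= min(result.trace) + 1e-12

    def test_seed_robustness_and_recovery(self):
        """Different seeds converge to the same optimum near the truth."""
        truth = ff.preset_parameters("fast")
        dataset, _ = ff.generate_dataset(
            truth, ff.synthetic_must(),
            ff.SamplingDesign(cv=0.01, seed=7,
                              observables=("X", "Glx", "F", "Eth")))
        # fit from perturbed defaults, not the generating values
        start = truth.with_values({"vmax_glx": 1.2, "y_eth": 0.55})
        config = ff.ModelConfiguration(name="t", params=start,
                                       estimable=("vmax_glx", "y_eth"))
        results = [
            ff.fit(dataset, config,
                   ff.OptimizerSettings(seed=s, n_starts=2, max_nfev=60))
            for s in (11, 22)
        ]
        c1, c2 = results[0].cost, results[1].cost
        assert abs(c1 - c2) <= 0.01 * max(c1, c2)
        for res in results:
            assert res.theta_hat.vmax_glx == pytest.approx(truth.vmax_glx,
                                                           rel=0.05)
            assert res.theta_hat.y_eth == pytest.approx(truth.y_eth, rel=0.05)

    def test_unknown_free_parameter_rejected(self):
        params = ff.preset_parameters("fast")
        dataset, _ = ff.generate_dataset(
            params, ff.synthetic_must(),
            ff.SamplingDesign(cv=0.0, seed=8, observables=("Eth",)))
        config = ff.ModelConfiguration(name="t", params=params,
                                       estimable=("vmax_glx",))
        with pytest.raises(ValueError, match="not estimable"):
            ff.fit(dataset, config,
                   ff.OptimizerSettings(seed=1, free=("y_eth",)))


def linear_yield_setup():
    """Sugar-only medium: ethanol is exactly linear in the yield y_eth,
    Eth(t) = y_eth * s(t) with a yield-independent regressor s(t)."""
    config = quiescent_config()
    y0 = ff.make_initial_state(XC=0.29, XP=0.59, XmRNA=0.12, Glx=50.0)
    times = (5.0, 15.0, 30.0, 60.0, 100.0)
    truth = config.params
    traj = ff.simulate(truth, y0, np.concatenate([[0.0], times]))
    eth = traj.column("Eth")[1:]
    regressor = eth / truth.y_eth
    return config, y0, times, eth, regressor


class TestConfidenceIntervals:
    def test_linear_limit_closed_form(self):
        config, y0, times, eth, s_t = linear_yield_setup()
        sigma = 3.0  # above the 5% floor of max(|Eth|) ~ 1
        dataset = dataset_from_points(
            [("Eth", t, e, sigma) for t, e in zip(times, eth)], y0)
        result = ff.FitResult(
            theta_hat=config.params, free_names=("y_eth",), cost=0.0,
            trace=(), seed=0, n_points=dataset.n_points, config=config)
        half = ff.confidence_intervals(result, dataset, alpha=0.05)
        gamma = len(times) - 1
        expected = (stats.t.ppf(0.975, gamma) * sigma
                    / np.sqrt(np.sum(s_t ** 2)))
        assert half["y_eth"] == pytest.approx(expected, rel=1e-4)

    def test_fim_additivity_shrinks_by_sqrt2(self):
        config, y0, times, eth, s_t = linear_yield_setup()
        sigma = 3.0
        points = [("Eth", t, e, sigma) for t, e in zip(times, eth)]
        doubled = points + [("Eth", t + 1e-6, e, sigma)
                            for t, e in zip(times, eth)]
        halves = []
        for pts in (points, doubled):
            dataset = dataset_from_points(pts, y0)
            result = ff.FitResult(
                theta_hat=config.params, free_names=("y_eth",), cost=0.0,
                trace=(), seed=0, n_points=dataset.n_points, config=config)
            halves.append(ff.confidence_intervals(result, dataset)["y_eth"])
        t_ratio = stats.t.ppf(0.975, 9) / stats.t.ppf(0.975, 4)
        assert halves[1] / halves[0] == pytest.approx(t_ratio / np.sqrt(2.0),
                                                      rel=1e-3)

    def test_structurally_unidentifiable_warns(self):
        """Parameters with no effect on the observed data give a singular
        information matrix and a pseudo-inverse warning."""
        config = quiescent_config()
        y0 = ff.make_initial_state(XC=0.29, XP=0.59, XmRNA=0.12, Glx=50.0)
        times = (5.0, 20.0, 50.0)
        traj = ff.simulate(config.params, y0,
                           np.concatenate([[0.0], times]))
        eth = traj.column("Eth")[1:]
        dataset = dataset_from_points(
            [("Eth", t, e, 2.0) for t, e in zip(times, eth)], y0)
        result = ff.FitResult(
            theta_hat=config.params, free_names=("k_nh4", "yxn"), cost=0.0,
            trace=(), seed=0, n_points=dataset.n_points, config=config)
        with pytest.warns(UserWarning, match="singular"):
            ff.confidence_intervals(result, dataset)

    def test_nonpositive_dof_rejected(self):
        config = quiescent_config()
        y0 = ff.make_initial_state(XC=0.29, XP=0.59, XmRNA=0.12, Eth=5.0)
        dataset = dataset_from_points(
            [("Eth", t, 5.0, 1.0) for t in (1.0, 2.0, 3.0)], y0)
        result = ff.FitResult(
            theta_hat=config.params,
            free_names=("y_eth", "vmax_glx", "kc_mal", "k_nh4", "yxn"),
            cost=0.0, trace=(), seed=0, n_points=dataset.n_points,
            config=config)
        with pytest.raises(ValueError, match="degrees of freedom"):
            ff.confidence_intervals(result, dataset)


class TestRSquared:
    def test_perfect_fit_is_one(self):
        params = ff.preset_parameters("fast")
        dataset, _ = ff.generate_dataset(
            params, ff.synthetic_must(),
            ff.SamplingDesign(cv=0.0, seed=9,
                              observables=("X", "Glx", "Eth", "Glycerol")))
        config = ff.ModelConfiguration(name="t", params=params,
                                       estimable=("vmax_glx",))
        result = ff.FitResult(theta_hat=params, free_names=("vmax_glx",),
                              cost=0.0, trace=(), seed=0,
                              n_points=dataset.n_points, config=config)
        r2 = ff.r_squared(result, dataset)
        assert set(r2) == {"X", "Glx", "Eth", "Glycerol"}
        for obs, value in r2.items():
            assert value == pytest.approx(1.0, abs=1e-9), obs

    def test_mean_prediction_scores_zero(self):
        """Data symmetric around a constant prediction: R^2 = 0."""
        config = quiescent_config()
        y0 = ff.make_initial_state(XC=0.29, XP=0.59, XmRNA=0.12, Eth=5.0)
        dataset = dataset_from_points(
            [("Eth", 1.0, 4.0, 1.0), ("Eth", 2.0, 6.0, 1.0)], y0)
        result = ff.FitResult(theta_hat=config.params, free_names=("y_eth",),
                              cost=0.0, trace=(), seed=0,
                              n_points=dataset.n_points, config=config)
        assert ff.r_squared(result, dataset)["Eth"] == pytest.approx(0.0,
                                                                     abs=1e-9)

    def test_constructed_three_quarters(self):
        """Malate decay fixture engineered to SSres = 2, SStot = 8."""
        config = quiescent_config(kc_mal=0.01)
        y0 = ff.make_initial_state(XC=0.29, XP=0.59, XmRNA=0.12, Mal=10.0)
        rate = 0.01 * 0.59  # kc_mal * XP, XP constant without growth
        a, b, c = 1.5, np.sqrt(0.75), 1.0 / np.sqrt(2.0)
        preds = np.array([5 + a, 5 - a, 5 + b, 5 - b])
        times = np.log(10.0 / preds) / rate
        errors = np.array([c, c, -c, -c])
        order = np.argsort(times)
        dataset = dataset_from_points(
            [("Mal", t, p + e, 1.0)
             for t, p, e in zip(times[order], preds[order], errors[order])],
            y0)
        result = ff.FitResult(theta_hat=config.params, free_names=("kc_mal",),
                              cost=0.0, trace=(), seed=0,
                              n_points=dataset.n_points, config=config)
        assert ff.r_squared(result, dataset)["Mal"] == pytest.approx(0.75,
                                                                     abs=1e-5)

    def test_zero_variance_observable_missing(self):
        config = quiescent_config()
        y0 = ff.make_initial_state(XC=0.29, XP=0.59, XmRNA=0.12, Eth=5.0)
        dataset = dataset_from_points(
            [("Eth", 1.0, 5.0, 1.0), ("Eth", 2.0, 5.0, 1.0)], y0)
        result = ff.FitResult(theta_hat=config.params, free_names=("y_eth",),
                              cost=0.0, trace=(), seed=0,
                              n_points=dataset.n_points, config=config)
        assert "Eth" not in ff.r_squared(result, dataset)


class TestSelectProductModel:
    @staticmethod
    def _config_and_dataset(variant, tau_gns=0.05):
        truth = ff.preset_parameters("fast").with_values(
            {"y_products.BDO": 4e-3, "tau_gns": tau_gns})
        truth.variants["BDO"] = variant
        dataset, _ = ff.generate_dataset(
            truth, ff.synthetic_must(),
            ff.SamplingDesign(cv=0.0, seed=21, observables=("BDO",)))
        config = ff.ModelConfiguration(
            name="sel", params=truth, estimable=("y_products.BDO",))
        return config, dataset

    @pytest.mark.parametrize("variant", ["nitrogen_delayed",
                                         "nitrogen_delayed_repressed"])
    def test_recovers_generating_variant(self, variant):
        config, dataset = self._config_and_dataset(variant)
        chosen = ff.select_product_model(
            dataset, "BDO", config,
            ff.OptimizerSettings(seed=1, n_starts=2, max_nfev=30))
        assert chosen == variant

    def test_tie_breaks_to_unrepressed(self):
        """With the regulator frozen at zero both variants coincide; the
        simpler (un-repressed) candidate wins the tie."""
        config, dataset = self._config_and_dataset(
            "nitrogen_delayed_repressed", tau_gns=0.0)
        chosen = ff.select_product_model(
            dataset, "BDO", config,
            ff.OptimizerSettings(seed=1, n_starts=1, max_nfev=20))
        assert chosen == "nitrogen_delayed"

    def test_unknown_metabolite_rejected(self):
        config, dataset = self._config_and_dataset("nitrogen_delayed")
        with pytest.raises(KeyError):
            ff.select_product_model(dataset, "Eth", config)
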