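"""Well-mixed kinetics: forward model and parameter-recovery estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from biolumox.config import ConfigError, KineticConfig, OxygenLevel
from biolumox.kinetics import (DegenerateFitWarning, LuminescenceTrace,
                               VelocityDataset, equivalent_cell_density,
                               extrapolate_initial_velocity,
                               fit_biexponential, fit_exponential_decay,
                               interpolate_velocity_oxygen, lineweaver_burk,
                               michaelis_menten_velocity,
                               simulate_batch_reaction)
from biolumox.synthetic_data import NoiseSpec, gen_velocity_dataset

from conftest import rk4_integrate


class TestMichaelisMenten:
    def test_half_saturation_identity(self, config):
        for pct, ctx in [(21.0, "lysate"), (0.0, "lysate"), (21.0, "cell")]:
            oxy = config.oxygen(pct)
            k = config.km(oxy, ctx)
            v = michaelis_menten_velocity(k, oxy, config, ctx)
            assert v == pytest.approx(config.v_max / 2.0, rel=1e-12)

    def test_zero_substrate_gives_zero_velocity(self, config):
        assert michaelis_menten_velocity(0.0, config.oxygen(21.0), config) == 0.0

    def test_normoxic_lysate_curve_governed_by_km_42_6(self, config):
        # v(S)/vmax = S/(42.6+S) over the titration range
        for s in [10.0, 42.6, 470.0]:
            v = michaelis_menten_velocity(s, config.oxygen(21.0), config)
            assert v == pytest.approx(config.v_max * s / (42.6 + s), rel=1e-12)

    def test_negative_substrate_rejected(self, config):
        with pytest.raises(ValueError):
            michaelis_menten_velocity(-1.0, config.oxygen(21.0), config)

    def test_intermediate_oxygen_requires_interpolation(self, config):
        with pytest.raises(ValueError):
            config.km(config.oxygen(10.0))

    @given(s=st.floats(0.1, 5000.0), ds=st.floats(0.1, 100.0))
    def test_monotone_saturating_in_substrate(self, s, ds):
        cfg = KineticConfig()
        oxy = cfg.oxygen(21.0)
        v1 = michaelis_menten_velocity(s, oxy, cfg)
        v2 = michaelis_menten_velocity(s + ds, oxy, cfg)
        assert v1 <= v2 <= cfg.v_max


class TestOxygenInterpolation:
    def test_endpoints_reproduce_endpoint_velocities(self, config):
        for pct in (0.0, 21.0):
            v_i = interpolate_velocity_oxygen(100.0, pct, config)
            v_e = michaelis_menten_velocity(100.0, config.oxygen(pct), config)
            assert v_i == pytest.approx(v_e, rel=1e-14)

    def test_quarter_oxygen_is_midpoint(self, config):
        # sqrt(5.25/21) = 0.5 forces the arithmetic midpoint
        v0 = michaelis_menten_velocity(100.0, config.oxygen(0.0), config)
        v21 = michaelis_menten_velocity(100.0, config.oxygen(21.0), config)
        v = interpolate_velocity_oxygen(100.0, 5.25, config)
        assert v == pytest.approx(v0 + 0.5 * (v21 - v0), rel=1e-14)

    def test_out_of_range_oxygen_rejected(self, config):
        for p in (-0.1, 21.1):
            with pytest.raises(ValueError):
                interpolate_velocity_oxygen(100.0, p, config)

    @given(p=st.floats(0.0, 20.0), dp=st.floats(0.001, 1.0), s=st.floats(1.0, 2000.0))
    def test_monotone_in_oxygen(self, p, dp, s):
        cfg = KineticConfig()
        hi = min(p + dp, 21.0)
        assert (interpolate_velocity_oxygen(s, p, cfg)
                <= interpolate_velocity_oxygen(s, hi, cfg) + 1e-15)


class TestBatchSimulation:
    def test_no_substrate_means_no_light(self, config):
        t = np.linspace(0, 1000, 50)
        res = simulate_batch_reaction(config, {"luciferin_um": 0.0,
                                               "enzyme_nM": 0.1}, t, "lysate")
        assert np.all(res.trace.flux == 0.0)

    def test_lysate_matches_rk4_oracle(self, config):
        """Independent fixed-step RK4 on the 3-state lysate system."""
        t = np.linspace(0, 2000, 41)
        res = simulate_batch_reaction(config, {"luciferin_um": 470.0,
                                               "enzyme_nM": 5.0}, t, "lysate")
        k_dec = config.decay_lysate_normoxic * config.decay_unit_scale
        km, vmax, qy = 42.6, config.v_max, config.quantum_yield

        def rhs(tt, y):
            v = vmax * y[1] * y[0] / (km + y[0])
            return np.array([-v, -k_dec * y[1], qy * v])

        oracle = rk4_integrate(rhs, [470.0, 5.0e-3, 0.0], t)
        sim = res.history[["luciferin", "enzyme", "photons_um"]].to_numpy()
        scale = np.abs(oracle).max(axis=0)
        assert np.max(np.abs(sim - oracle) / scale) < 1e-3

    def test_closed_system_conserves_luciferin(self, config):
        t = np.linspace(0, 3.0e4, 60)
        res = simulate_batch_reaction(config, {"luciferin_um": 470.0,
                                               "enzyme_nM": 100.0}, t, "lysate")
        h = res.history
        total = h.luciferin + h.photons_um / config.quantum_yield
        assert np.max(np.abs(total - total.iloc[0])) / total.iloc[0] < 1e-3
        assert h.photons_um.iloc[-1] <= config.quantum_yield * 470.0 * (1 + 1e-9)

    def test_cell_conservation_including_membrane_pool(self, config):
        t = np.linspace(0, 5.0e4, 80)
        res = simulate_batch_reaction(config, {"luciferin_um": 470.0,
                                               "cells_per_ml": 1.0e7}, t, "cell")
        h = res.history
        total = (h.luciferin_ext + h.luciferin_int
                 + h.photons_um / config.quantum_yield)
        assert np.max(np.abs(total - total.iloc[0])) / total.iloc[0] < 1e-3
        assert (h[["luciferin_ext", "luciferin_int", "enzyme"]] >= 0).all().all()

    def test_flash_trace_log_is_piecewise_linear(self, config):
        """470 µM intact cells: two log-linear segments (fast then slow)."""
        t = np.linspace(0, 1.2e5, 500)
        res = simulate_batch_reaction(config, {"luciferin_um": 470.0,
                                               "cells_per_ml": 1.0e7}, t, "cell")
        logf = np.log(res.trace.flux[2:])
        slopes = -np.gradient(logf, t[2:]) / config.decay_unit_scale
        early = np.median(slopes[(t[2:] > 1e3) & (t[2:] < 5e3)])
        late = np.median(slopes[t[2:] > 6e4])
        assert early == pytest.approx(config.decay_cell_fast_normoxic, rel=0.05)
        assert late == pytest.approx(config.decay_cell_slow_normoxic, rel=0.05)

    def test_kappa_zero_pins_fast_regime(self):
        cfg = KineticConfig(kappa=0.0)
        t = np.linspace(0, 2.0e4, 200)
        res = simulate_batch_reaction(cfg, {"luciferin_um": 470.0,
                                            "cells_per_ml": 1.0e7}, t, "cell")
        fit = fit_exponential_decay(res.trace, window=(2e3, 2e4))
        assert fit["rate"] == pytest.approx(cfg.decay_cell_fast_normoxic,
                                            rel=0.05)

    def test_kappa_above_initial_pins_slow_regime(self):
        cfg = KineticConfig(kappa=5000.0)
        t = np.linspace(0, 2.0e5, 200)
        res = simulate_batch_reaction(cfg, {"luciferin_um": 470.0,
                                            "cells_per_ml": 1.0e5}, t, "cell")
        fit = fit_exponential_decay(res.trace, window=(2e3, 2e5))
        assert fit["rate"] == pytest.approx(cfg.decay_cell_slow_normoxic,
                                            rel=0.05)


class TestExponentialFits:
    def test_pure_exponential_recovered_exactly(self):
        t = np.linspace(0, 3000, 50)
        trace = LuminescenceTrace(t, 5.0e5 * np.exp(-1e-3 * t))
        fit = fit_exponential_decay(trace)
        assert fit["rate_per_s"] == pytest.approx(1e-3, rel=1e-12)
        assert fit["amplitude"] == pytest.approx(5.0e5, rel=1e-10)
        assert fit["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_trace_gives_zero_rate(self):
        t = np.linspace(0, 100, 20)
        fit = fit_exponential_decay(LuminescenceTrace(t, np.full(20, 7.0)))
        assert fit["rate"] == 0.0

    def test_roundtrip_against_simulator(self, config):
        t = np.linspace(0, 1500, 120)
        res = simulate_batch_reaction(config, {"luciferin_um": 470.0,
                                               "enzyme_nM": 0.1}, t, "lysate")
        fit = fit_exponential_decay(res.trace)
        assert fit["rate"] == pytest.approx(config.decay_lysate_normoxic,
                                            rel=0.01)

    def test_nonpositive_flux_rejected(self):
        t = np.linspace(0, 10, 10)
        y = np.ones(10)
        y[3] = 0.0
        with pytest.raises(ValueError):
            fit_exponential_decay(LuminescenceTrace(t, y))

    def test_noisy_replicates_median_error_small(self):
        t = np.linspace(0, 1500, 100)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = 1e6 * np.exp(-3948e-6 * t) * np.exp(rng.normal(0, 0.05, t.size))
            errs.append(abs(fit_exponential_decay(
                LuminescenceTrace(t, y))["rate"] / 3948.0 - 1.0))
        assert np.median(errs) < 0.10


class TestBiexponentialFit:
    tg = np.unique(np.concatenate([np.linspace(1, 2.5e4, 600),
                                   np.linspace(2.5e4, 1.4e5, 300)]))

    def test_two_component_rates_recovered(self):
        y = 1e6 * np.exp(-1.8e-4 * self.tg) + 2e4 * np.exp(-2.7e-5 * self.tg)
        fit = fit_biexponential(LuminescenceTrace(self.tg, y))
        assert fit["rate_fast"] == pytest.approx(180.0, rel=0.02)
        assert fit["rate_slow"] == pytest.approx(27.0, rel=0.02)
        assert not fit["degenerate"]

    def test_single_exponential_takes_degeneracy_path(self):
        y = 1e6 * np.exp(-1.8e-4 * self.tg)
        with pytest.warns(DegenerateFitWarning):
            fit = fit_biexponential(LuminescenceTrace(self.tg, y))
        assert fit["degenerate"]
        assert fit["rate_fast"] == fit["rate_slow"]
        assert fit["rate_fast"] == pytest.approx(180.0, rel=0.01)

    def test_regime_switch_roundtrip(self, config):
        """470 µM intact-cell flash through the kappa switch."""
        res = simulate_batch_reaction(config, {"luciferin_um": 470.0,
                                               "cells_per_ml": 1.0e7},
                                      self.tg, "cell")
        fit = fit_biexponential(res.trace)
        assert fit["rate_fast"] == pytest.approx(
            config.decay_cell_fast_normoxic, rel=0.05)
        assert fit["rate_slow"] == pytest.approx(
            config.decay_cell_slow_normoxic, rel=0.05)

    def test_noisy_replicates_median_error_small(self):
        errs = []
        clean = 1e6 * np.exp(-1.8e-4 * self.tg) + 2e4 * np.exp(-2.7e-5 * self.tg)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = clean * np.exp(rng.normal(0, 0.05, self.tg.size))
            fit = fit_biexponential(LuminescenceTrace(self.tg, y))
            errs.append(max(abs(fit["rate_fast"] / 180.0 - 1),
                            abs(fit["rate_slow"] / 27.0 - 1)))
        assert np.median(errs) < 0.10


class TestInitialVelocityExtrapolation:
    def test_no_pair_returns_amplitude_at_zero(self):
        t = np.linspace(10, 1000, 60)
        trace = LuminescenceTrace(t, 2e5 * np.exp(-2e-3 * t))
        res = extrapolate_initial_velocity(trace)
        assert res["t0"] == 0.0
        assert res["v0"] == pytest.approx(2e5, rel=1e-9)

    def test_scaled_copies_keep_ratio_at_any_t0(self):
        t = np.linspace(10, 1000, 60)
        y = 1e5 * np.exp(-3e-3 * t)
        res = extrapolate_initial_velocity(
            LuminescenceTrace(t, 4.0 * y), LuminescenceTrace(t, y),
            ratio_criterion=4.0)
        # equal decay rates: the ratio is the scale factor at every t0
        assert res["ratio"] == pytest.approx(4.0, rel=1e-9)
        assert res["v0"] / res["v0_pair"] == pytest.approx(4.0, rel=1e-9)

    def test_paired_traces_reach_configured_criterion(self, config):
        """Normoxic/hypoxic free-luciferase pair solved for the 3.37 ratio."""
        t = np.linspace(5, 1200, 120)
        s0 = 100.0
        norm = simulate_batch_reaction(config, {"luciferin_um": s0,
                                                "enzyme_nM": 0.1}, t,
                                       "solution").trace
        hyp = simulate_batch_reaction(config, {"luciferin_um": s0,
                                               "enzyme_nM": 0.1}, t,
                                      "solution", config.oxygen(0.0)).trace
        res = extrapolate_initial_velocity(
            norm, hyp, ratio_criterion=config.velocity_ratio_criterion)
        assert res["ratio"] == pytest.approx(3.37, rel=1e-6)
        assert res["t0"] > 0.0

    def test_unattainable_criterion_raises(self):
        t = np.linspace(10, 1000, 60)
        y = 1e5 * np.exp(-3e-3 * t)
        with pytest.raises(ValueError, match="unattainable"):
            extrapolate_initial_velocity(
                LuminescenceTrace(t, 2.0 * y), LuminescenceTrace(t, y),
                ratio_criterion=5.0)


class TestLineweaverBurk:
    def test_exact_recovery_from_noise_free_curve(self):
        s = np.array([10.0, 30.0, 100.0, 300.0, 600.0, 1000.0])
        for km, vmax in [(42.6, 1.6), (938.4, 1.6), (7.0, 0.3)]:
            v = vmax * s / (km + s)
            fit = lineweaver_burk(VelocityDataset(
                s, v, OxygenLevel.from_percent(21.0)))
            assert fit["km"] == pytest.approx(km, rel=1e-9)
            assert fit["vmax"] == pytest.approx(vmax, rel=1e-9)
            assert fit["r_squared"] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("pct,km_true", [(21.0, 42.6), (0.0, 938.4)])
    def test_generator_roundtrip(self, config, pct, km_true):
        ds = gen_velocity_dataset(config, [10, 30, 100, 300, 600, 1000],
                                  config.oxygen(pct), "lysate")
        assert lineweaver_burk(ds)["km"] == pytest.approx(km_true, rel=0.01)

    def test_noisy_replicates_median_error_small(self, config):
        errs = []
        for seed in range(100):
            ds = gen_velocity_dataset(config, [10, 30, 100, 300, 600, 1000],
                                      config.oxygen(21.0), "lysate",
                                      NoiseSpec(level=0.05, seed=seed))
            try:
                errs.append(abs(lineweaver_burk(ds)["km"] / 42.6 - 1.0))
            except (ValueError, RuntimeError):
                errs.append(np.inf)
        assert np.median(errs) < 0.10

    def test_too_few_points_rejected(self):
        ds = VelocityDataset(np.array([10.0, 20.0]), np.array([0.2, 0.3]),
                             OxygenLevel.from_percent(21.0))
        with pytest.raises(ValueError):
            lineweaver_burk(ds)


class TestConfigAndEquivalence:
    def test_cell_density_equivalence_arithmetic(self):
        # 0.1 nM enzyme at 0.92 amol/cell is ~1.09e5 cells/ml
        assert equivalent_cell_density(0.1, 0.92) == pytest.approx(1.09e5,
                                                                   rel=5e-3)

    def test_intact_cell_km_is_1_5_fold(self, config):
        oxy = config.oxygen(21.0)
        assert config.km(oxy, "cell") / config.km(oxy, "lysate") == \
            pytest.approx(1.5, rel=1e-12)

    def test_invalid_km_ordering_rejected(self):
        with pytest.raises(ConfigError, match="km_hypoxic"):
            KineticConfig(km_normoxic=100.0, km_hypoxic=50.0)

    def test_oxygen_level_bounds(self):
        with pytest.raises(ConfigError):
            OxygenLevel.from_percent(25.0)
        lvl = OxygenLevel.from_percent(10.5, c_sat=200.0)
        assert lvl.dissolved == pytest.approx(100.0)
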