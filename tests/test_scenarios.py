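"""Treatment runs, schedules, summaries, ensembles, maps and sweeps."""

import numpy as np
import pytest

from brainht.parameters import ParameterSet
from brainht.scenarios import (
    CANONICAL_SCHEDULE,
    make_power_schedule,
    parameter_map,
    perfusion_sweep,
    run_ensemble,
    run_treatment,
    summarize,
)

NO_FLUCT = {"random_amp": 0.0, "harmonic_amp": 0.0}


class TestPowerSchedule:
    def test_canonical_timing(self):
        s = CANONICAL_SCHEDULE
        assert (s.t_start, s.t_full, s.t_off) == (300.0, 900.0, 3600.0)
        assert s(30 * 60.0) == (40.0, 40.0)

    def test_ramp_midpoint_is_half_power(self):
        assert CANONICAL_SCHEDULE(10 * 60.0)[0] == pytest.approx(20.0)

    def test_zero_outside_session(self):
        assert CANONICAL_SCHEDULE(61 * 60.0) == (0.0, 0.0)
        assert CANONICAL_SCHEDULE(0.0) == (0.0, 0.0)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            make_power_schedule(start_min=50.0, ramp_min=20.0, off_min=60.0)


class TestRunTreatment:
    def test_no_power_stays_at_equilibrium(self, defaults):
        schedule = make_power_schedule(P=0.0)
        res = run_treatment(defaults, schedule, horizon=3600.0)
        eq = res.equilibrium
        assert np.max(np.abs(res.T - eq.T_eq)) < 1e-6
        assert np.max(np.abs(res.T_s - eq.T_seq)) < 1e-6
        assert np.max(np.abs(res.T_b - eq.T_beq)) < 1e-6

    def test_functional_temperature_rise(self, functional_run):
        """Well-perfused tumour heats by ~1.42 degC at 40 W/kg."""
        m = summarize(functional_run)
        assert m.dT_max == pytest.approx(1.42, abs=0.1)

    def test_temperature_ordering_during_heating(self, functional_run):
        heating = (functional_run.t >= functional_run.schedule.t_full) & (
            functional_run.t <= functional_run.schedule.t_off
        )
        assert np.all(functional_run.T[heating] >= functional_run.T_s[heating])
        assert np.all(functional_run.T_s[heating] >= functional_run.T_b[heating])

    def test_blood_rise_imperceptible(self, functional_run):
        m = summarize(functional_run)
        assert m.T_b_max - functional_run.equilibrium.T_beq < 0.5

    def test_plateau_reached(self, functional_run):
        """Pseudo-equilibrium: |dT/dt| < 1e-5 degC/s late in the heating."""
        r = functional_run
        late = (r.t >= r.schedule.t_off - 600.0) & (r.t <= r.schedule.t_off)
        rates = np.abs(np.gradient(r.T[late], r.t[late]))
        assert np.max(rates) < 1e-5

    def test_impaired_perfusion_baseline_and_peak(self, impaired_run):
        """Dysfunctional tumour: flow 3.79 at rest, peaks at 4.38."""
        m = summarize(impaired_run)
        assert impaired_run.w[0] == pytest.approx(3.79, abs=0.01)
        assert m.w_max == pytest.approx(4.38, abs=0.05)

    def test_solver_tolerance_independence(self, defaults, functional_run):
        tight = run_treatment(
            defaults.replace(zeta=0.85, gamma=0.08),
            solver_opts={"rtol": 5e-7, "atol": 5e-9},
        )
        assert abs(np.max(tight.T) - np.max(functional_run.T)) < 1e-3

    def test_deterministic_run_is_seed_independent(self, defaults):
        a = run_treatment(defaults, horizon=3600.0, seed=1)
        b = run_treatment(defaults, horizon=3600.0, seed=2)
        assert np.array_equal(a.T, b.T)

    def test_fluctuating_run_reproducible_by_seed(self, defaults):
        a = run_treatment(defaults, fluctuations_on=True, seed=7, horizon=3600.0)
        b = run_treatment(defaults, fluctuations_on=True, seed=7, horizon=3600.0)
        assert np.array_equal(a.T, b.T)


class TestSummaries:
    def test_functional_return_within_15_min(self, functional_run):
        m = summarize(functional_run, return_threshold=0.1)
        assert m.returned
        assert m.return_time < 15 * 60.0

    def test_impaired_return_around_20_min(self, impaired_run):
        m = summarize(impaired_run, return_threshold=0.1)
        assert m.returned
        assert 10 * 60.0 < m.return_time < 25 * 60.0

    def test_constant_run_trivial_metrics(self, defaults):
        res = run_treatment(defaults, make_power_schedule(P=0.0), horizon=3600.0)
        m = summarize(res, return_threshold=0.1)
        assert m.dT_max == pytest.approx(0.0, abs=1e-6)
        assert m.return_time == 0.0


class TestMonotonicity:
    def test_tmax_monotone_in_each_knob(self, defaults):
        """T_max rises with power, falls with zeta, gamma and w0."""
        def tmax(**kw):
            p = defaults.replace(**{k: v for k, v in kw.items() if k != "P"})
            schedule = make_power_schedule(P=kw.get("P", 40.0))
            res = run_treatment(p, schedule, horizon=3600.0)
            return summarize(res).T_max

        by_power = [tmax(P=P) for P in (25.0, 40.0, 50.0)]
        assert by_power == sorted(by_power)

        by_zeta = [tmax(zeta=z) for z in (0.3, 0.5, 0.85, 1.2)]
        assert by_zeta == sorted(by_zeta, reverse=True)

        by_gamma = [tmax(gamma=g) for g in (0.0, 0.05, 0.1)]
        assert by_gamma == sorted(by_gamma, reverse=True)

        by_w0 = [tmax(w0_clinical=w) for w in (10.0, 20.0, 30.0, 49.2)]
        assert by_w0 == sorted(by_w0, reverse=True)


class TestEnsemble:
    def test_degenerate_intervals_collapse_on_nominal(self, defaults):
        env = run_ensemble(
            defaults, (0.85, 0.85), (0.08, 0.08), n_runs=2, seed=0,
            fluctuations_on=False, horizon=3600.0,
        )
        assert np.allclose(env.T_min, env.T_max)
        assert np.allclose(env.T_min, env.nominal.T, atol=1e-9)

    def test_envelope_encloses_nominal(self, defaults):
        env = run_ensemble(
            defaults.replace(zeta=0.85, gamma=0.08),
            (0.79, 0.91), (0.072, 0.088), n_runs=16, seed=3, horizon=4800.0,
        )
        tol = 1e-9
        assert np.all(env.T_min <= env.nominal.T + tol)
        assert np.all(env.T_max >= env.nominal.T - tol)

    def test_envelope_widens_with_fluctuation_amplitude(self, defaults):
        widths = []
        for amp in (0.03, 0.06):
            env = run_ensemble(
                defaults, (0.85, 0.85), (0.08, 0.08), n_runs=4, seed=5,
                horizon=3600.0,
                fluct_opts={"random_amp": amp, "harmonic_amp": amp / 2},
            )
            widths.append(np.max(env.T_max - env.T_min))
        assert widths[1] > widths[0]

    def test_empty_interval_rejected(self, defaults):
        with pytest.raises(ValueError):
            run_ensemble(defaults, (0.9, 0.8), (0.0, 0.1), n_runs=2)


class TestParameterMap:
    def test_extremes_and_monotonicity(self, defaults):
        grid = parameter_map(
            gamma_grid=[0.0, 0.1], zeta_grid=[0.25, 1.0], params=defaults
        )
        assert grid.loc[1.0, 0.1] < 39.0     # intact vasculature: mild
        assert grid.loc[0.25, 0.0] > 42.0    # severely impaired: hot
        assert np.all(np.diff(grid.values, axis=0) < 0)  # falls with zeta
        assert np.all(np.diff(grid.values, axis=1) < 0)  # falls with gamma


class TestPerfusionSweep:
    def test_zero_amplitude_trials_have_zero_sd(self, defaults):
        table = perfusion_sweep(
            (49.2,), (0.85,), n_trials=2, seed=0, params=defaults,
            fluct_opts=NO_FLUCT,
        )
        assert table["T_max_sd"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_small_grid_statistics(self, defaults):
        """T_max falls with w0 and all mean return times are < 60 min."""
        table = perfusion_sweep(
            (15.0, 49.2), (0.3, 0.85), n_trials=3, seed=2, params=defaults,
        )
        assert len(table) == 4
        assert (table["n_returned"] > 0).all()
        assert (table["return_time_mean_s"] < 3600.0).all()
        for z in (0.3, 0.85):
            sub = table[table["zeta"] == z].sort_values("w0_clinical")
            assert sub["T_max_mean"].is_monotonic_decreasing
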