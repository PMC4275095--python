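"""Scenario integration, efficacy metrics, searches and maintenance logic."""

import numpy as np
import pytest

from gpmsim.dynamics import ModelParams
from gpmsim.genetics import GENOTYPE_COPIES
from gpmsim.releases import MaintenancePlan, ReleasePlan
from gpmsim.simulate import (
    ConvergenceWarning,
    find_crossover,
    long_term_density,
    metrics,
    minimum_density,
    rank_strategies,
    recovery_occurs,
    relative_average_density,
    run_scenario,
)


def a_allele_frequency(states: np.ndarray) -> np.ndarray:
    """Frequency of the antipathogen allele among all adults over time."""
    a_copies = np.array([a for _k, a in GENOTYPE_COPIES], dtype=float)
    adults = states[9:18] + states[18:27]
    carried = np.tensordot(a_copies, adults, axes=(0, 0))
    total = 2.0 * adults.sum(axis=0)
    return np.divide(carried, total, out=np.zeros_like(total), where=total > 0)


class TestRunScenario:
    def test_equilibrium_persists_without_releases(self, params):
        traj = run_scenario(params, None, horizon=500.0)
        rel_dev = np.abs(traj.states - traj.states[:, :1])
        scale = np.maximum(traj.states[:, :1], 1.0)
        assert np.max(rel_dev / scale) < 1e-6
        assert np.allclose(traj.rel_competent, 1.0, atol=1e-6)

    def test_zero_ratio_plan_is_a_no_release_run(self, params):
        plan = ReleasePlan(strategy="AP", r=0.0)
        traj = run_scenario(params, plan, horizon=200.0)
        assert np.allclose(traj.rel_competent, 1.0, atol=1e-6)

    def test_ap_release_gives_persistent_reduction(self, params):
        traj = run_scenario(params, ReleasePlan(strategy="AP", sex_mode="male_only"))
        f = traj.rel_competent
        assert np.all(f[traj.times > 1.0] < 1.0)
        assert f[-1] < 0.95  # the A allele persists: no return to baseline

    def test_neutral_a_allele_frequency_settles(self, params):
        # with c_A = 0 the A allele is selectively neutral: after releases
        # end its adult frequency approaches a constant (no systematic loss)
        traj = run_scenario(
            params, ReleasePlan(strategy="AP", sex_mode="male_only"), horizon=1565.0
        )
        freq = a_allele_frequency(traj.states)
        i = np.searchsorted(traj.times, traj.times[-1] - 100.0)
        assert freq[-1] > 0.5
        assert abs(freq[-1] - freq[i]) < 1e-6

    def test_fk_reduces_then_rebounds(self, params):
        traj = run_scenario(params, ReleasePlan(strategy="FK", sex_mode="male_only"))
        f = traj.rel_competent
        i100 = np.searchsorted(traj.times, 100.0)
        assert f[i100] < 0.5                      # reduced while releasing
        assert long_term_density(traj) == pytest.approx(1.0, abs=1e-3)

    def test_fk_carrier_female_classes_stay_zero_without_female_releases(self, params):
        traj = run_scenario(
            params, ReleasePlan(strategy="RR_AP", sex_mode="male_only", T_s=50.0)
        )
        k_carrier = [i for i, (k, _a) in enumerate(GENOTYPE_COPIES) if k > 0]
        assert np.max(np.abs(traj.states[9 + np.array(k_carrier), :])) < 1e-9

    def test_events_mark_phase_changes(self, params):
        traj = run_scenario(params, ReleasePlan(strategy="FK_AP", T_s=50.0))
        labels = [label for _t, label in traj.events]
        assert labels == ["release_KKaa", "release_kkAA", "releases_end"]
        times = [t for t, _ in traj.events]
        assert times == [0.0, 50.0, 100.0]

    def test_tidy_frame_schema(self, params):
        traj = run_scenario(params, None, horizon=10.0)
        df = traj.to_frame()
        assert set(df.columns) == {"time_days", "stage", "genotype", "density"}
        assert set(df["stage"]) == {"J", "F", "M"}
        assert len(df) == 27 * traj.times.size


class TestMetrics:
    def test_relative_average_of_constant_baseline_is_one(self, params):
        traj = run_scenario(params, None, horizon=500.0)
        assert relative_average_density(traj, 0.0, 465.0) == pytest.approx(1.0, abs=1e-6)

    def test_default_window_ends_one_year_after_releases(self, params):
        traj = run_scenario(params, ReleasePlan(strategy="AP", T=100.0), horizon=600.0)
        assert relative_average_density(traj) == pytest.approx(
            relative_average_density(traj, 0.0, 465.0)
        )

    def test_window_validation(self, params):
        traj = run_scenario(params, None, horizon=100.0)
        with pytest.raises(ValueError):
            relative_average_density(traj, 50.0, 40.0)
        with pytest.raises(ValueError):
            relative_average_density(traj, 0.0, 200.0)

    def test_minimum_below_long_term_for_transient_strategy(self, params):
        traj = run_scenario(params, ReleasePlan(strategy="FK"))
        m = metrics(traj)
        assert m.minimum < m.long_term
        assert m.minimum <= m.rel_avg

    def test_nonconverged_horizon_warns(self, params):
        traj = run_scenario(params, ReleasePlan(strategy="AP"), horizon=300.0)
        with pytest.warns(ConvergenceWarning):
            long_term_density(traj)

    def test_metric_continuity_in_fitness_cost(self, params):
        vals = []
        for c in (0.10, 0.102):
            p = params.with_(c_A=c)
            traj = run_scenario(p, ReleasePlan(strategy="AP"), horizon=465.0)
            vals.append(relative_average_density(traj, 0.0, 465.0))
        assert vals[0] != vals[1]
        assert abs(vals[1] - vals[0]) < 0.05 * vals[0]


class TestRanking:
    def test_orders_by_value_with_margins(self, params):
        plans = [ReleasePlan(strategy=s, sex_mode="male_only") for s in ("AP", "FK")]
        rows = rank_strategies(params, plans, metric="minimum")
        assert [r["strategy"] for r in rows] == ["AP", "FK"]
        assert rows[0]["margin"] == 0.0
        assert rows[1]["margin"] > 0.0
        assert not rows[1]["tied_with_previous"]

    def test_identical_plans_reported_as_tie(self, params):
        plans = [ReleasePlan(strategy="AP"), ReleasePlan(strategy="AP")]
        rows = rank_strategies(params, plans, metric="minimum")
        assert rows[1]["tied_with_previous"]


class TestCrossover:
    def test_identical_plans_have_no_crossover(self, params):
        plan = ReleasePlan(strategy="AP", sex_mode="male_only")
        assert (
            find_crossover("c_A", (plan, plan), "rel_avg", (0.0, 0.3), params=params)
            is None
        )

    def test_unknown_axis_rejected(self, params):
        plan = ReleasePlan(strategy="AP")
        with pytest.raises(ValueError):
            find_crossover("mu_Q", (plan, plan), "rel_avg", (0.0, 0.3), params=params)


class TestMaintenance:
    def test_recovery_depends_on_maintenance_fraction(self, params):
        p = params.with_(c_A=0.2)
        weak = ReleasePlan(
            strategy="AP",
            sex_mode="male_only",
            maintenance=MaintenancePlan(theta=0.4, r_p=0.02, horizon=730.0),
        )
        strong = ReleasePlan(
            strategy="AP",
            sex_mode="male_only",
            maintenance=MaintenancePlan(theta=0.4, r_p=1.0, horizon=730.0),
        )
        assert recovery_occurs(p, weak)
        assert not recovery_occurs(p, strong)

    def test_trigger_event_recorded_at_threshold(self, params):
        p = params.with_(c_A=0.2)
        plan = ReleasePlan(
            strategy="AP",
            sex_mode="male_only",
            maintenance=MaintenancePlan(theta=0.4, r_p=0.5, horizon=200.0),
        )
        traj = run_scenario(p, plan)
        t_trig = next(t for t, label in traj.events if label == "maintenance_start")
        i = np.searchsorted(traj.times, t_trig)
        assert traj.rel_competent[i] == pytest.approx(0.4, abs=1e-6)
        assert traj.times[-1] == pytest.approx(t_trig + 200.0)
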