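"""Simulator tests: bolus mass balance, closed forms, grid convergence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monodsense.fedbatch import (
    TRAJ_COLUMNS,
    FeedEvent,
    Trajectory,
    apply_bolus_feed,
    read_feed_schedule,
    simulate,
    total_cell_track,
    write_feed_schedule,
)
from monodsense.kinetics import CultureState, KineticParameters

pos = st.floats(min_value=1e-3, max_value=100.0, allow_nan=False)
small_pos = st.floats(min_value=1e-3, max_value=5.0, allow_nan=False)


class TestBolusFeed:
    def test_mass_balance_worked_example(self):
        state = CultureState(Xv=0.0, Xt=0.0, GLC=2.0, V=1.0)
        fed = apply_bolus_feed(state, FeedEvent(t_feed=1.0, V_feed=0.1, GLC=200.0))
        assert fed.GLC == pytest.approx(20.0, rel=1e-12)
        assert fed.V == pytest.approx(1.1, rel=1e-12)

    def test_identical_composition_leaves_concentrations_unchanged(self):
        state = CultureState(Xv=0.0, Xt=0.0, GLC=5.0, GLN=1.0, LAC=2.0, V=2.0)
        feed = FeedEvent(t_feed=1.0, V_feed=0.5, GLC=5.0, GLN=1.0, LAC=2.0)
        fed = apply_bolus_feed(state, feed)
        for name in ("GLC", "GLN", "LAC", "AMM", "mAb"):
            assert getattr(fed, name) == pytest.approx(getattr(state, name), abs=1e-14)
        assert fed.V == 2.5

    def test_equal_volume_cell_free_feed_halves_cells(self):
        state = CultureState(Xv=1.0, Xt=1.2, V=1.0)
        fed = apply_bolus_feed(state, FeedEvent(t_feed=1.0, V_feed=1.0))
        assert fed.Xv == pytest.approx(0.5, rel=1e-12)
        assert fed.Xt == pytest.approx(0.6, rel=1e-12)

    @given(V=pos, Vf=small_pos, C=st.floats(0, 50), Cf=st.floats(0, 300))
    @settings(max_examples=100, deadline=None)
    def test_species_mass_conserved_to_ten_digits(self, V, Vf, C, Cf):
        state = CultureState(Xv=0.5, Xt=0.5, GLC=C, V=V)
        fed = apply_bolus_feed(state, FeedEvent(t_feed=1.0, V_feed=Vf, GLC=Cf))
        mass_in = C * V + Cf * Vf
        assert fed.GLC * fed.V == pytest.approx(mass_in, rel=1e-10, abs=1e-12)
        assert fed.Xv * fed.V == pytest.approx(0.5 * V, rel=1e-10)

    def test_invalid_feed_rejected(self):
        with pytest.raises(ValueError):
            FeedEvent(t_feed=1.0, V_feed=0.0)
        with pytest.raises(ValueError):
            FeedEvent(t_feed=1.0, V_feed=0.1, GLC=-1.0)


class TestSimulate:
    def test_exponential_closed_form_in_saturating_limit(self, params):
        # vanishing-inoculum regime: produced lactate/ammonium feedback
        # on mu is negligible over the horizon (it scales with Xv0), and
        # atol is tightened to match the state magnitude
        initial = CultureState(Xv=1e-5, Xt=1e-5, GLC=1e5, GLN=1e4, V=1.0)
        traj = simulate(initial, params, t_end=12.0, dt_out=1.0, atol=1e-18)
        expected = 1e-5 * np.exp(params.mu_max * traj.t)
        np.testing.assert_allclose(traj.Xv, expected, rtol=1e-5)

    def test_zero_inoculum_stays_constant(self, params):
        initial = CultureState(Xv=0.0, Xt=0.0, GLC=30.0, GLN=4.0, V=1.0)
        traj = simulate(initial, params, t_end=48.0, dt_out=4.0)
        for col in ("Xv_E9_L", "GLC_mM", "GLN_mM", "LAC_mM", "AMM_mM", "mAb_g_L"):
            np.testing.assert_allclose(traj.column(col), traj.column(col)[0], atol=1e-12)

    def test_batch_lactate_tracks_glucose_consumption(self, traj_batch, params):
        glc = traj_batch.column("GLC_mM")
        lac = traj_batch.column("LAC_mM")
        np.testing.assert_allclose(
            lac - lac[0], params.Y_lac_glc * (glc[0] - glc), rtol=1e-7, atol=1e-9)

    def test_output_grid_refinement_consistent(self, scenario, params):
        coarse = simulate(scenario.initial, params, feeds=scenario.feeds,
                          t_end=120.0, dt_out=2.0)
        fine = simulate(scenario.initial, params, feeds=scenario.feeds,
                        t_end=120.0, dt_out=1.0)
        common = np.arange(0.0, 120.0, 2.0)[1:]  # avoid duplicated feed rows
        common = common[~np.isin(common, [f.t_feed for f in scenario.feeds])]
        for col in ("Xv_E9_L", "GLC_mM", "LAC_mM"):
            a = coarse.interp(col, common)
            b = fine.interp(col, common)
            np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-8)

    def test_default_scenario_shows_fed_batch_phases(self, traj_default):
        t, Xv = traj_default.t, traj_default.Xv
        glc = traj_default.column("GLC_mM")
        lac = traj_default.column("LAC_mM")
        mab = traj_default.column("mAb_g_L")
        v = traj_default.column("V_L")
        between = np.diff(t) > 0  # boluses dilute every species stepwise
        assert Xv.max() > 10 * Xv[0]                      # growth
        assert glc[t <= 72].min() < 0.7 * glc[0]          # substrate decline
        assert lac[-1] > 20.0 and np.all(np.diff(lac)[between] >= -1e-9)
        assert mab[-1] > 0.1 and np.all(np.diff(mab)[between] >= -1e-12)
        assert np.all(np.diff(v) >= 0)                    # volume non-decreasing
        assert np.all(traj_default.Xt >= Xv - 1e-12)
        assert np.all((traj_default.viability > 0) & (traj_default.viability <= 1 + 1e-12))

    def test_substrates_pinned_at_zero_after_depletion(self, scenario, params):
        traj = simulate(scenario.initial, params, feeds=(), t_end=300.0, dt_out=1.0)
        assert np.all(traj.column("GLN_mM") >= 0)
        glc = traj.column("GLC_mM")
        assert np.all(glc >= 0)
        # maintenance exhausts glucose in a long batch; once the
        # depletion event fires the solver pins it at exactly zero
        depleted = np.nonzero(glc == 0.0)[0]
        assert depleted.size > 0
        np.testing.assert_array_equal(glc[depleted[0]:], 0.0)

    def test_feed_rows_reported_before_and_after_bolus(self, traj_default, scenario):
        t0 = scenario.feeds[0].t_feed
        rows = traj_default.data[traj_default.data["t_h"] == t0]
        assert len(rows) == 2
        glc = rows["GLC_mM"].to_numpy()
        assert glc[1] > glc[0]  # bolus raises glucose
        v = rows["V_L"].to_numpy()
        assert v[1] == pytest.approx(v[0] + scenario.feeds[0].V_feed)

    def test_feed_before_start_rejected_after_horizon_ignored(self, scenario, params):
        with pytest.raises(ValueError, match="after the initial time"):
            simulate(scenario.initial, params,
                     feeds=[FeedEvent(t_feed=-1.0, V_feed=0.1)], t_end=24.0)
        # feeds beyond the horizon are simply not reached
        traj = simulate(scenario.initial, params,
                        feeds=[FeedEvent(t_feed=300.0, V_feed=0.1)], t_end=24.0)
        assert np.all(np.diff(traj.t) > 0)

    def test_unordered_feeds_rejected(self, scenario, params):
        feeds = [FeedEvent(t_feed=48.0, V_feed=0.1), FeedEvent(t_feed=48.0, V_feed=0.1)]
        with pytest.raises(ValueError, match="ordered"):
            simulate(scenario.initial, params, feeds=feeds, t_end=72.0)


class TestTotalCellTrack:
    @staticmethod
    def _flat_trajectory(mu_d_saturating: bool):
        t = np.linspace(0.0, 10.0, 41)
        big = 1e9 if mu_d_saturating else 0.0
        df = pd.DataFrame({
            "t_h": t, "Xv_E9_L": np.ones_like(t), "Xt_E9_L": np.ones_like(t),
            "GLC_mM": np.zeros_like(t), "GLN_mM": np.zeros_like(t),
            "LAC_mM": np.full_like(t, big), "AMM_mM": np.full_like(t, big),
            "mAb_g_L": np.zeros_like(t), "V_L": np.ones_like(t),
        })
        return Trajectory(df)

    def test_constant_death_quadrature(self, params):
        # constant Xv = 1 and saturated mu_d = k_d = 0.004 over 10 h
        traj = total_cell_track(self._flat_trajectory(True), params)
        assert traj.Xt[-1] - traj.Xv[-1] == pytest.approx(0.04, rel=1e-6)

    def test_no_death_means_total_equals_viable(self, params):
        traj = total_cell_track(self._flat_trajectory(False), params)
        np.testing.assert_allclose(traj.Xt, traj.Xv)

    def test_matches_simulator_dead_cell_bookkeeping(self, traj_default, scenario):
        tracked = total_cell_track(traj_default, scenario.params,
                                   Xd0=scenario.initial.Xt - scenario.initial.Xv)
        np.testing.assert_allclose(tracked.Xt, traj_default.Xt, rtol=2e-3, atol=1e-4)

    def test_viability_non_increasing_when_death_dominates(self, params):
        # dying culture: no substrates, saturating metabolites
        initial = CultureState(Xv=2.0, Xt=2.0, GLC=0.0, GLN=0.0,
                               LAC=100.0, AMM=50.0, V=1.0)
        traj = simulate(initial, params, t_end=100.0, dt_out=2.0)
        assert np.all(np.diff(traj.viability) <= 1e-12)


class TestIO:
    def test_feed_schedule_csv_roundtrip(self, scenario, tmp_path):
        path = tmp_path / "feeds.csv"
        write_feed_schedule(scenario.feeds, path)
        back = read_feed_schedule(path)
        assert back == scenario.feeds

    def test_trajectory_csv_roundtrip(self, traj_batch, tmp_path):
        path = tmp_path / "traj.csv"
        traj_batch.to_csv(path)
        back = Trajectory.from_csv(path)
        pd.testing.assert_frame_equal(back.data, traj_batch.data)
        assert back.meta["params"] == traj_batch.meta["params"]

    def test_trajectory_requires_all_columns(self):
        with pytest.raises(ValueError, match="missing"):
            Trajectory(pd.DataFrame({"t_h": [0.0, 1.0]}))

    def test_trajectory_rejects_decreasing_time(self):
        df = pd.DataFrame({c: [0.0, 0.0] for c in TRAJ_COLUMNS})
        df["t_h"] = [1.0, 0.0]
        df["V_L"] = 1.0
        with pytest.raises(ValueError, match="non-decreasing"):
            Trajectory(df)
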