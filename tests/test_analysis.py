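"""Synchronized heat maps, TDP, dwell tables and dwell-law fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clampfret.analysis import (
    SyncedTraces,
    compare_dwell_distributions,
    dwell_times,
    fit_dwell_histogram,
    fit_dwells,
    heatmap,
    histogram_mode,
    lrt_exponential_vs_gamma,
    synchronize,
    tdp,
)
from clampfret.hmm import DecodedPath
from clampfret.kinetics import make_scenario, simulate_state_path
from clampfret.pipeline import RunConfig, run_pipeline
from clampfret.qc import FretTrace


def _fret_trace(e_values, anchor_frame=0, dt=0.1, trace_id="ft"):
    e = np.asarray(e_values, dtype=float)
    t = (np.arange(len(e)) + 0.5) * dt
    return FretTrace(
        trace_id=trace_id, time=t, efficiency=e, total=np.full(len(e), 1200.0),
        valid_start=0, valid_end=len(e),
        annotations={"association_frame": anchor_frame,
                     "dissociation_frame": None},
    )


def _decoded(states, means, trace_id="d"):
    states = np.asarray(states, dtype=int)
    k = len(means)
    post = np.zeros((len(states), k))
    post[np.arange(len(states)), states] = 1.0
    return DecodedPath(trace_id=trace_id, states=states, posterior=post,
                       state_means=np.asarray(means, dtype=float))


class TestSynchronize:
    def test_identical_anchor_frames_align_identically(self):
        traces = [_fret_trace([0.3] * 20, anchor_frame=5, trace_id=f"t{i}")
                  for i in range(3)]
        synced = synchronize(traces, "association")
        for t in synced.times:
            assert t[0] == pytest.approx(traces[0].time[0] - traces[0].time[5])

    def test_traces_without_anchor_dropped_with_reason(self):
        good = _fret_trace([0.3] * 10, anchor_frame=2, trace_id="good")
        bad = _fret_trace([0.3] * 10, trace_id="bad")
        bad.annotations["association_frame"] = None
        synced = synchronize([good, bad], "association")
        assert synced.n_traces + len(synced.dropped) == 2
        assert list(synced.dropped["trace_id"]) == ["bad"]
        assert synced.dropped["reason"].iloc[0] == "no_association"

    def test_mean_aligned_e_at_zero_matches_first_bound_state(self):
        cfg = RunConfig(scenario="loading_atp", n_traces=60, seed=41,
                        n_donors_fixed=6)
        art = run_pipeline(cfg, stages=["simulate", "detect", "qc"])
        synced = synchronize(art["fret_traces"], "association")
        first = []
        for t, e in zip(synced.times, synced.efficiencies):
            sel = (t >= 0) & (t < 0.1)  # the anchor frame itself
            first.extend(e[sel])
        first = np.asarray(first)
        se = first.std() / np.sqrt(len(first))
        # tolerance floor covers frame discretization: a short first dwell
        # can already have advanced to the next state within the frame
        assert abs(first.mean() - 0.48) < max(3 * se, 0.02)


class TestHeatMap:
    def test_constant_traces_fill_single_bin_every_column(self):
        traces = [_fret_trace([0.34] * 50, anchor_frame=0, trace_id=f"t{i}")
                  for i in range(4)]
        hm = heatmap(synchronize(traces, "association"), t_range=(0.0, 5.0))
        occupied = hm.counts.sum(axis=1) > 0
        assert occupied.any()
        target_bin = np.searchsorted(hm.e_edges, 0.34, side="right") - 1
        assert np.all(np.argmax(hm.density[occupied], axis=1) == target_bin)

    def test_columns_sum_to_one(self):
        cfg = RunConfig(scenario="loading_atp", n_traces=30, seed=42,
                        n_donors_fixed=6)
        art = run_pipeline(cfg, stages=["simulate", "detect", "qc"])
        hm = heatmap(synchronize(art["fret_traces"], "association"))
        col = hm.density.sum(axis=1)
        occupied = hm.counts.sum(axis=1) > 0
        assert np.allclose(col[occupied], 1.0, atol=1e-9)
        assert np.allclose(col[~occupied], 0.0)


class TestTDP:
    def test_path_without_transitions_gives_empty_histogram(self):
        path = _decoded([1] * 40, [0.34, 0.48, 0.62])
        hist = tdp([path], frame_interval=0.1)
        assert hist.n_transitions == 0

    def test_hand_built_loading_path_counts_two_forward_transitions(self):
        # LI1 -> LI2 -> LS with the printed state means
        means = [0.34, 0.48, 0.62]  # sorted: LS, LI1, LI2
        path = _decoded([1] * 10 + [2] * 10 + [0] * 10, means)
        hist = tdp([path], frame_interval=0.1, window_s=6.0)
        assert hist.n_transitions == 2
        assert hist.pair_count(1, 2) == 1  # 0.48 -> 0.62
        assert hist.pair_count(2, 0) == 1  # 0.62 -> 0.34
        peaks = hist.peaks(2)
        assert set(zip(peaks["e_before"].round(2), peaks["e_after"].round(2))) == {
            (0.49, 0.63), (0.63, 0.35)
        }

    def test_count_conservation_inside_window(self):
        means = [0.3, 0.7]
        rng = np.random.default_rng(43)
        paths = [
            _decoded(rng.integers(0, 2, 80), means, trace_id=f"p{i}")
            for i in range(10)
        ]
        w = 4.0
        hist = tdp(paths, frame_interval=0.1, window_s=w, side="first")
        manual = sum(
            1
            for p in paths
            for frame, _, _ in p.transitions()
            if frame <= int(w / 0.1)
        )
        assert hist.n_transitions == manual == len(hist.transitions)

    def test_last_side_keeps_only_final_window(self):
        means = [0.3, 0.7]
        states = [0] * 100 + [1] * 10
        path = _decoded(states, means)
        hist = tdp([path], frame_interval=0.1, window_s=2.0, side="last")
        assert hist.n_transitions == 1
        hist_early = tdp([path], frame_interval=0.1, window_s=0.5, side="last")
        assert hist_early.n_transitions == 0


class TestDwellTimes:
    def test_interior_run_recorded_uncensored(self):
        path = _decoded([0] * 10 + [1] * 20 + [0] * 10, [0.3, 0.7])
        table = dwell_times([path], state=1, frame_interval=0.1)
        assert len(table) == 1
        assert table["duration_s"].iloc[0] == pytest.approx(2.0)
        assert not table["censored"].iloc[0]

    def test_run_truncated_by_trace_end_is_censored(self):
        path = _decoded([0] * 10 + [1] * 5, [0.3, 0.7])
        table = dwell_times([path], state=1, frame_interval=0.1,
                            policy="keep_flagged")
        assert table["censored"].iloc[0]
        dropped = dwell_times([path], state=1, frame_interval=0.1)
        assert len(dropped) == 0

    def test_observed_entry_and_exit_do_not_censor(self):
        path = _decoded([1] * 5 + [0] * 5 + [1] * 4, [0.3, 0.7])
        table = dwell_times([path], state=1, frame_interval=0.1,
                            start_is_entry=True, end_is_exit=True)
        assert len(table) == 2
        assert not table["censored"].any()

    def test_simulated_dwell_mean_matches_generating_tau(self):
        scheme = make_scenario("loading_atp", reverse_fraction=0.0)
        rng = np.random.default_rng(44)
        dwells = []
        for _ in range(2_000):
            dwells.extend(simulate_state_path(scheme, 60.0, rng).dwell_of("LI1"))
        dwells = np.asarray(dwells)
        se = dwells.std() / np.sqrt(len(dwells))
        assert abs(dwells.mean() - 0.5) < 3 * se


class TestDwellFits:
    def test_equal_dwells_give_tau_equal_to_value(self):
        d = np.full(50, 1.7)
        fit = fit_dwells(d, "exponential")
        assert fit.tau == pytest.approx(1.7)

    def test_exponential_sample_recovery_and_gamma_shape_near_one(self):
        rng = np.random.default_rng(45)
        d = rng.exponential(1.5, 10_000)
        fit = fit_dwells(d, "exponential")
        se = 1.5 / np.sqrt(len(d))
        assert abs(fit.tau - 1.5) < 3 * se
        gam = fit_dwells(d, "gamma")
        lo, hi = gam.ci["shape"]
        assert lo <= 1.0 <= hi

    def test_erlang_dwells_reject_exponential_with_positive_mode(self):
        rng = np.random.default_rng(46)
        d = rng.gamma(2.0, 1.0, 10_000)  # Erlang(2), mode at 1.0
        res = lrt_exponential_vs_gamma(d)
        assert res["gamma"].shape > 1.0
        assert res["pvalue"] < 1e-3
        assert histogram_mode(d) > 0.25

    def test_too_few_dwells_rejected_with_named_minimum(self):
        with pytest.raises(ValueError, match="10"):
            fit_dwells(np.ones(5), "exponential")

    def test_left_truncation_preserves_exponential_mean(self):
        rng = np.random.default_rng(47)
        d = rng.exponential(0.8, 20_000)
        fit = fit_dwells(d, "exponential", t_min=0.3)
        se = 0.8 / np.sqrt(fit.n)
        assert abs(fit.tau - 0.8) < 3 * se

    def test_histogram_fit_tracks_mle(self):
        rng = np.random.default_rng(48)
        d = rng.exponential(1.2, 5_000)
        amp, tau, _, _ = fit_dwell_histogram(d, bin_s=0.2)
        assert tau == pytest.approx(1.2, rel=0.15)

    def test_identical_kinetics_are_ks_indistinguishable(self):
        """UI dwell distributions under ATP and ATP-gamma-S share kinetics."""
        rng = np.random.default_rng(49)
        atp, atpgs = [], []
        for name, out in (("unloading_atp", atp), ("unloading_atpgs", atpgs)):
            scheme = make_scenario(name)
            while len(out) < 400:
                out.extend(simulate_state_path(scheme, 120.0, rng).dwell_of("UI"))
        res = compare_dwell_distributions(np.asarray(atp), np.asarray(atpgs))
        assert res["pvalue"] > 0.01
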