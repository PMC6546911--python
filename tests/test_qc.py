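"""FRET computation, step counting, selection and event detection."""

import numpy as np
import pytest
from scipy import stats

from clampfret.kinetics import make_scenario, simulate_state_path
from clampfret.photophysics import PhotophysicsModel, Trace, render_trace
from clampfret.qc import (
    compute_fret,
    count_photobleach_steps,
    count_spots_over_time,
    detect_association,
    detect_dissociation,
    prepare_fret_trace,
    select_traces,
)
from tests.conftest import constant_bound_traces, staircase_trace


def _trace(donor, acceptor, dt=0.1):
    donor = np.asarray(donor, dtype=float)
    t = (np.arange(len(donor)) + 0.5) * dt
    return Trace(trace_id="x", time=t, donor=donor, acceptor=np.asarray(acceptor, float))


class TestComputeFret:
    def test_zero_acceptor_gives_zero_fret(self):
        ft = compute_fret(_trace([500.0] * 10, [0.0] * 10))
        assert np.allclose(ft.efficiency, 0.0)

    def test_equal_channels_give_half(self):
        ft = compute_fret(_trace([300.0] * 10, [300.0] * 10))
        assert np.allclose(ft.efficiency, 0.5)

    def test_zero_length_trace_rejected(self):
        with pytest.raises(ValueError):
            compute_fret(_trace([], []))

    def test_below_floor_frames_marked_no_signal(self):
        donor = np.array([500.0] * 5 + [1.0] * 5)
        ft = compute_fret(_trace(donor, donor), min_total=50.0)
        assert np.isfinite(ft.efficiency[:5]).all()
        assert np.isnan(ft.efficiency[5:]).all()

    def test_noisy_loaded_state_mean_matches_generating_value(self):
        traces = constant_bound_traces(20, duration=10.0, seed=8)
        model = PhotophysicsModel()
        vals = []
        for tr in traces:
            ft = compute_fret(
                tr, model.background_donor, model.background_acceptor
            )
            vals.append(ft.efficiency[np.isfinite(ft.efficiency)])
        vals = np.concatenate(vals)
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.34) < max(3 * se, 1e-3)


class TestStepCounting:
    def test_constant_trace_has_no_steps(self):
        count, times = count_photobleach_steps(_trace([600.0] * 100, [0.0] * 100))
        assert count == 0 and len(times) == 0

    def test_noiseless_six_donor_staircase_counts_six(self):
        levels = [1200, 1000, 800, 600, 400, 200, 0]
        tr = staircase_trace(levels, frames_per_level=40)
        count, times = count_photobleach_steps(tr, donor_unit=200.0)
        assert count == 6
        assert len(times) == 6

    @pytest.mark.parametrize("n_steps", [1, 2, 3, 4, 5, 6])
    def test_exact_on_noiseless_staircases(self, n_steps):
        levels = [200.0 * k for k in range(n_steps, -1, -1)]
        tr = staircase_trace(levels, frames_per_level=30)
        count, _ = count_photobleach_steps(tr, donor_unit=200.0)
        assert count == n_steps

    def test_noisy_three_step_staircase(self):
        # noise sd = 10% of the step height, 200 frames per segment
        tr = staircase_trace([600, 400, 200, 0], frames_per_level=200,
                             noise_sd=20.0, seed=1)
        count, _ = count_photobleach_steps(tr, donor_unit=200.0)
        assert count == 3

    def test_merged_double_bleach_counted_by_magnitude(self):
        tr = staircase_trace([1200, 800, 600], frames_per_level=50)
        count, _ = count_photobleach_steps(tr, donor_unit=200.0)
        assert count == 3  # one 2-unit drop + one 1-unit drop

    def test_step_times_located_at_transitions(self):
        tr = staircase_trace([400, 200, 0], frames_per_level=50, frame_interval=0.1)
        _, times = count_photobleach_steps(tr, donor_unit=200.0)
        assert np.allclose(times, [5.05, 10.05], atol=0.2)


class TestSelection:
    def test_empty_input_empty_output(self):
        selected, report = select_traces([], mode="loading")
        assert selected == [] and len(report) == 0

    def test_loading_selection_keeps_only_six_donor_traces(self):
        traces = []
        for nd in (4, 5, 6, 6, 5, 4):
            batch = constant_bound_traces(
                2, duration=150.0, n_donors=nd, seed=nd * 10,
                model=PhotophysicsModel(donor_bleach_rate=0.05),
            )
            for tr in batch:
                tr.trace_id = f"{tr.trace_id}_nd{nd}_{len(traces)}"
                traces.append(tr)
        selected, report = select_traces(
            traces, mode="loading", background=100.0, donor_unit=200.0
        )
        chosen = {tr.trace_id for tr in selected}
        for tr, cnt in zip(traces, report["step_count"]):
            if tr.meta["n_donors"] == 6:
                assert tr.trace_id in chosen
            else:
                assert tr.trace_id not in chosen

    def test_unloading_selection_by_intensity_tolerance(self):
        model = PhotophysicsModel(donor_bleach_rate=0.0)
        pool = []
        for nd in (4, 5, 6):
            pool.extend(
                constant_bound_traces(3, duration=5.0, n_donors=nd,
                                      seed=nd, model=model)
            )
        selected, _ = select_traces(
            pool, mode="unloading", background=100.0,
            six_level=model.six_donor_level, intensity_tol=0.10,
        )
        assert {tr.meta["n_donors"] for tr in selected} == {6}

    def test_unloading_without_calibration_rejected(self):
        model = PhotophysicsModel(donor_bleach_rate=0.0)
        pool = constant_bound_traces(3, duration=5.0, n_donors=5, model=model)
        with pytest.raises(ValueError, match="calibration"):
            select_traces(pool, mode="unloading", background=100.0)

    def test_six_step_fraction_matches_binomial_mass(self):
        """With Binomial(6, 0.6) labelling and complete bleaching, the
        fraction passing six-step selection equals the mass at 6."""
        model = PhotophysicsModel(donor_bleach_rate=0.05)
        traces = constant_bound_traces(
            300, duration=200.0, n_donors=None, seed=99, model=model
        )
        _, report = select_traces(
            traces, mode="loading", background=100.0, donor_unit=200.0
        )
        frac = report["passed"].mean()
        p6 = stats.binom.pmf(6, 6, 0.6)
        se = np.sqrt(p6 * (1 - p6) / len(traces))
        assert abs(frac - p6) < 3 * se


class TestEventDetection:
    def test_all_background_trace_has_no_association(self):
        rng = np.random.default_rng(0)
        d = rng.poisson(50.0, 200).astype(float)
        assert detect_association(_trace(d, d), background=100.0, noise_sd=10.0) is None

    def test_noiseless_step_association_found_exactly(self):
        d = np.array([0.0] * 100 + [600.0] * 100)
        assert detect_association(_trace(d, d)) == 100

    def test_association_accuracy_on_flow_in_traces(self):
        # low brightness gives SNR ~ 6 at the six-donor level
        scheme = make_scenario("loading_atp")
        model = PhotophysicsModel(donor_brightness=25.0, donor_bleach_rate=0.0)
        rng = np.random.default_rng(12)
        hits = total = 0
        for _ in range(500):
            p = simulate_state_path(scheme, 15.0, rng)
            tr = render_trace(p, model, seed=rng, n_donors=6)
            truth = tr.meta["true_assoc_frame"]
            if truth is None or truth > tr.n_frames - 5:
                continue
            det = detect_association(tr, background=100.0)
            total += 1
            if det is not None and abs(det - truth) <= 2:
                hits += 1
        assert total > 300
        assert hits / total >= 0.95

    def test_noiseless_full_drop_is_single_step(self):
        d = np.array([600.0] * 400 + [0.0] * 100)
        frame, single = detect_dissociation(_trace(d, d))
        assert frame == 400 and single

    def test_staged_monomer_loss_is_not_single_step(self):
        d = np.array([600.0] * 200 + [400.0] * 30 + [200.0] * 30 + [0.0] * 100)
        _, single = detect_dissociation(_trace(d, d))
        assert not single

    def test_trimer_release_from_plateau_is_single_step(self):
        rng = np.random.default_rng(3)
        sig = np.array([1200.0] * 300 + [0.0] * 100)
        noisy = rng.poisson(sig + 100.0).astype(float)
        frame, single = detect_dissociation(_trace(noisy / 2, noisy / 2),
                                            background=100.0)
        assert frame is not None and abs(frame - 300) <= 1
        assert single


class TestOccupancy:
    def test_inactive_unloader_keeps_flat_occupancy(self):
        traces = constant_bound_traces(
            20, duration=30.0, seed=1, noise=False,
            model=PhotophysicsModel(donor_bleach_rate=0.0,
                                    background_donor=0, background_acceptor=0,
                                    read_noise_sd=0),
        )
        curve = count_spots_over_time(traces, bin_s=2.0, background=0.0)
        assert curve["count"].nunique() == 1
        assert curve["count"].iloc[0] == 20

    def test_active_unloading_decays_monotonically(self):
        scheme = make_scenario("unloading_atp")
        model = PhotophysicsModel(donor_bleach_rate=0.0, background_donor=0,
                                  background_acceptor=0, read_noise_sd=0)
        rng = np.random.default_rng(2)
        traces = [
            render_trace(simulate_state_path(scheme, 40.0, rng), model,
                         seed=rng, n_donors=6, noise=False,
                         fret_mean=scheme.fret_mean)
            for _ in range(40)
        ]
        curve = count_spots_over_time(traces, bin_s=2.0, background=0.0)
        assert np.all(np.diff(curve["count"]) <= 0)
        assert curve["count"].iloc[0] > curve["count"].iloc[-1]

    def test_flow_in_loading_rises_then_plateaus(self):
        scheme = make_scenario("loading_atp")
        model = PhotophysicsModel(donor_bleach_rate=0.0, background_donor=0,
                                  background_acceptor=0, read_noise_sd=0)
        rng = np.random.default_rng(5)
        traces = [
            render_trace(simulate_state_path(scheme, 40.0, rng), model,
                         seed=rng, n_donors=6, noise=False,
                         fret_mean=scheme.fret_mean)
            for _ in range(40)
        ]
        curve = count_spots_over_time(traces, bin_s=2.0, background=0.0)
        assert np.all(np.diff(curve["count"]) >= 0)
        assert curve["count"].iloc[-1] == 40


class TestTotalIntensityInvariance:
    def test_total_is_fret_invariant_before_bleaching(self):
        scheme = make_scenario("loading_atp")
        model = PhotophysicsModel(donor_bleach_rate=0.0, background_donor=0,
                                  background_acceptor=0, read_noise_sd=0)
        path = simulate_state_path(scheme, 60.0, seed=6)
        tr = render_trace(path, model, seed=6, n_donors=6, noise=False,
                          fret_mean=scheme.fret_mean)
        assoc = tr.meta["true_assoc_frame"]
        bound_total = tr.total[assoc:]
        assert np.ptp(bound_total) == pytest.approx(0.0)


class TestPrepareFretTrace:
    def test_window_opens_at_association_and_closes_at_first_bleach(self):
        scheme = make_scenario("loading_atp")
        model = PhotophysicsModel()
        rng = np.random.default_rng(17)
        for _ in range(20):
            path = simulate_state_path(scheme, 200.0, rng)
            tr = render_trace(path, model, seed=rng, n_donors=6,
                              fret_mean=scheme.fret_mean)
            ft = prepare_fret_trace(
                tr, model.background_donor, model.background_acceptor,
                donor_unit=model.donor_brightness, mode="loading",
            )
            truth_assoc = tr.meta["true_assoc_frame"]
            if truth_assoc is None:
                continue
            assert abs(ft.valid_start - truth_assoc) <= 2
            first_bleach = tr.meta["bleach_times"].min()
            if ft.annotations["step_count"] > 0:
                bleach_frame = int(first_bleach / model.frame_interval)
                if first_bleach > tr.time[truth_assoc]:
                    assert abs(ft.valid_end - bleach_frame) <= 3
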