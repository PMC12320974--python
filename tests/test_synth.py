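"""Simulator tests: interval law moments, wall kinematics, rendering, cohorts."""

import numpy as np
import pytest

from flyheart.beats import BeatIntervalSeries
from flyheart.exceptions import (
    ConfigError,
    GeometryError,
    OverlappingPulsesError,
    TooFewBeatsError,
)
from flyheart.synth import (
    BeatModelParams,
    CohortDesign,
    GroupEffect,
    ImagingParams,
    TubeGeometry,
    cv_for_arrhythmicity_index,
    five_strain_design,
    generate_cohort,
    interval_mixture_moments,
    null_design,
    period_for_heart_rate,
    render_kymograph,
    render_stack,
    simulate_intervals,
    simulate_wall_trace,
)


class TestSimulateIntervals:
    def test_deterministic_limit_regular_beat(self):
        """cv=0, no pauses: 59-60 intervals of exactly the mean period."""
        series, truth = simulate_intervals(
            BeatModelParams(mean_period=0.5, period_cv=0.0, pause_prob=0.0, duration=30.0, seed=4)
        )
        assert 59 <= series.intervals.size <= 60
        assert np.allclose(series.intervals, 0.5)
        assert truth.hr == pytest.approx(120.0)

    def test_lognormal_cv_recovered(self):
        """Pooled intervals reproduce the log-normal moments at the stated cv.

        Oracle: for a log-normal with mean m and cv c, SD/mean = c and
        SD/median = c*sqrt(1+c^2).
        """
        c = 0.2
        iv = np.concatenate(
            [
                simulate_intervals(
                    BeatModelParams(mean_period=0.5, period_cv=c, duration=30.0, seed=s)
                )[0].intervals
                for s in range(200)
            ]
        )
        n = iv.size
        assert n > 5000
        se = c / np.sqrt(2 * n)  # Monte-Carlo SE of the SD/mean ratio
        assert np.std(iv, ddof=1) / np.mean(iv) == pytest.approx(c, abs=4 * se)
        assert np.std(iv, ddof=1) / np.median(iv) == pytest.approx(
            c * np.sqrt(1 + c * c), rel=0.05
        )

    def test_pause_mixture_raises_mean_and_dispersion(self):
        """Oracle: mixture mean = m(1 + p(f-1)); pauses add dispersion beyond cv."""
        m, p, f = 0.5, 0.1, 2.0
        base_ai, mixed_ai, means = [], [], []
        for s in range(150):
            kw = dict(mean_period=m, period_cv=0.1, duration=30.0, seed=s)
            base = simulate_intervals(BeatModelParams(**kw))[0].intervals
            mix = simulate_intervals(BeatModelParams(pause_prob=p, pause_factor=f, **kw))[0].intervals
            base_ai.append(np.std(base, ddof=1) / np.median(base))
            mixed_ai.append(np.std(mix, ddof=1) / np.median(mix))
            means.append(np.mean(mix))
        expected_mean, _ = interval_mixture_moments(m, 0.1, p, f)
        assert expected_mean == pytest.approx(m * (1 + p * (f - 1)))
        assert np.mean(means) == pytest.approx(expected_mean, rel=0.02)
        assert np.mean(mixed_ai) > np.mean(base_ai)

    def test_seed_reproducibility(self):
        p = BeatModelParams(mean_period=0.4, period_cv=0.15, pause_prob=0.05, seed=77)
        a = simulate_intervals(p)[0].event_times
        b = simulate_intervals(p)[0].event_times
        assert np.array_equal(a, b)

    def test_duration_below_one_period_fails_loudly(self):
        with pytest.raises(TooFewBeatsError, match="too few beats"):
            simulate_intervals(BeatModelParams(mean_period=2.0, duration=1.0))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BeatModelParams(mean_period=-1)
        with pytest.raises(ValueError):
            BeatModelParams(pause_prob=1.0)
        with pytest.raises(ValueError):
            BeatModelParams(pause_factor=0.5)

    def test_ground_truth_self_consistency(self):
        """Truth metric fields equal the metric formulas on the truth intervals."""
        from flyheart.metrics import arrhythmicity_index, heart_rate

        series, truth = simulate_intervals(BeatModelParams(period_cv=0.2, seed=5))
        assert truth.hr == pytest.approx(heart_rate(series))
        assert truth.ai == pytest.approx(arrhythmicity_index(series))


class TestWallTrace:
    def test_no_events_constant_diastolic_diameter(self):
        geom, img = TubeGeometry(), ImagingParams(duration=2.0)
        series = BeatIntervalSeries(event_times=np.array([0.5, 1.2]), duration=2.0)
        # widen the beat spacing so pulses stay clear, then strip events
        trace = simulate_wall_trace(series, geom, img)
        between = (trace.times < 0.35) | ((trace.times > 0.65) & (trace.times < 1.05))
        assert np.allclose(trace.diameter[between], geom.diastolic_diameter)

    def test_pulse_center_reaches_systolic_diameter(self):
        geom = TubeGeometry(diastolic_diameter=100.0, systolic_diameter=60.0, center_position=60.0)
        img = ImagingParams(duration=2.0, line_length=130)
        series = BeatIntervalSeries(event_times=np.array([1.0, 1.8]), duration=2.0)
        trace = simulate_wall_trace(series, geom, img)
        assert trace.diameter.min() == pytest.approx(60.0)
        assert trace.times[np.argmin(trace.diameter)] == pytest.approx(1.0)

    def test_compact_support_of_pulse(self):
        geom = TubeGeometry(contraction_width=0.2)
        img = ImagingParams(duration=2.0)
        series = BeatIntervalSeries(event_times=np.array([1.0, 1.7]), duration=2.0)
        trace = simulate_wall_trace(series, geom, img)
        outside = (trace.times <= 0.9) | ((trace.times >= 1.1) & (trace.times <= 1.6))
        assert np.allclose(trace.diameter[outside], geom.diastolic_diameter)

    def test_overlapping_pulses_name_the_pair(self):
        geom = TubeGeometry(contraction_width=0.3)
        series = BeatIntervalSeries(event_times=np.array([1.0, 1.2, 2.0]), duration=3.0)
        with pytest.raises(OverlappingPulsesError, match="events 0 and 1") as exc:
            simulate_wall_trace(series, geom, ImagingParams(duration=3.0))
        assert exc.value.pair == (0, 1)


class TestRendering:
    def test_kymograph_shape_is_duration_times_rate(self, regular_recording):
        kymo = regular_recording["kymo"]
        assert kymo.intensity.shape == (80, 3000)

    def test_noiseless_minima_at_wall_positions(self, regular_recording):
        """At an event frame the column's two darkest pixels sit on the walls."""
        rec = regular_recording
        frame = int(round(rec["series"].event_times[5] * 100))
        col = rec["kymo"].intensity[:, frame]
        lower = rec["trace"].lower[frame] / rec["imaging"].pixel_size
        upper = rec["trace"].upper[frame] / rec["imaging"].pixel_size
        darkest = np.argsort(col)[:2]
        assert sorted(np.round([lower, upper]).astype(int)) == sorted(darkest)

    def test_seeded_noise_is_bit_identical(self, noisy_recording):
        rec = noisy_recording
        again = render_kymograph(rec["trace"], rec["imaging"], seed=99)
        assert np.array_equal(again.intensity, rec["kymo"].intensity)

    def test_wall_outside_field_reports_frame(self, regular_recording):
        rec = regular_recording
        img = ImagingParams(line_length=40)  # field 39 um, walls at 15/65 um
        with pytest.raises(GeometryError, match="frame 0"):
            render_kymograph(rec["trace"], img)

    def test_stack_center_line_matches_kymograph(self, regular_recording):
        rec = regular_recording
        stack = render_stack(rec["trace"], width=16)
        assert stack.shape == (3000, 80, 16)
        assert np.array_equal(stack[:, :, 8].T, rec["kymo"].intensity)


class TestCohorts:
    def test_wt_preset_recovers_configured_hr_drop(self):
        """Oracle: HR formula inversion; the configured -14.35 BPM shift comes back."""
        design = five_strain_design(n_per_group=60, seed=3)
        table = generate_cohort(design).table
        wt = table[table.strain == "WT"]
        d_hr = (
            wt[wt.condition == "ATP"].hr_bpm.mean() - wt[wt.condition == "BTP"].hr_bpm.mean()
        )
        # per-animal shift SD 3 BPM -> SE of the mean difference ~ 0.55 at n=60
        assert d_hr == pytest.approx(-14.35, abs=4 * 3.0 * np.sqrt(2) / np.sqrt(60))

    def test_arrhythmic_preset_hits_target_ai(self):
        design = five_strain_design(n_per_group=60, seed=9)
        table = generate_cohort(design).table
        atp = table[(table.strain == "N210K") & (table.condition == "ATP")]
        assert atp.ai_au.mean() == pytest.approx(0.46, rel=0.15)
        btp = table[(table.strain == "N210K") & (table.condition == "BTP")]
        assert btp.ai_au.mean() == pytest.approx(0.08, rel=0.25)

    def test_null_design_has_no_systematic_shift(self):
        table = generate_cohort(null_design(n_per_group=100, seed=2)).table
        wide = table.pivot_table(index="animal_id", columns="condition", values="hr_bpm")
        d = (wide["ATP"] - wide["BTP"]).to_numpy()
        assert abs(d.mean()) < 4 * d.std(ddof=1) / np.sqrt(d.size)

    def test_cohort_reproducible_from_seed(self):
        a = generate_cohort(five_strain_design(n_per_group=3, seed=42)).table
        b = generate_cohort(five_strain_design(n_per_group=3, seed=42)).table
        assert a.equals(b)

    def test_unknown_cell_lists_allowed_labels(self):
        design = null_design(n_per_group=3)
        with pytest.raises(ConfigError, match="allowed strains"):
            design.effect_for("nonsense", "none")

    def test_missing_effect_cell_rejected(self):
        with pytest.raises(ConfigError, match="missing cells"):
            CohortDesign(
                strains=["A", "B"],
                treatments=["x"],
                n_per_group=3,
                effects={("A", "x"): GroupEffect()},
            )


class TestCalibration:
    def test_cv_inversion_closed_form(self):
        """AI = c*sqrt(1+c^2) without pauses; the inverse recovers c."""
        for target in (0.05, 0.2, 0.46):
            c = cv_for_arrhythmicity_index(target)
            assert c * np.sqrt(1 + c * c) == pytest.approx(target, rel=1e-9)

    def test_period_inversion(self):
        m = period_for_heart_rate(120.0, pause_prob=0.1, pause_factor=2.0)
        assert m * 1.1 == pytest.approx(0.5)

    def test_target_below_pause_floor_rejected(self):
        with pytest.raises(ConfigError, match="pause-only floor"):
            cv_for_arrhythmicity_index(0.05, pause_prob=0.3, pause_factor=3.0)
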