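"""Photomotor-response QC: phase labeling and the three exclusion rules."""

import numpy as np
import pytest

from larvatox.behavior_qc import (
    DARK,
    LIGHT,
    LocomotionTrace,
    PhotoperiodSchedule,
    QCThresholds,
    apply_qc,
    dark_below_median_flag,
    label_phases,
    light_dark_ratio_flag,
    light_serial_exceedance_flag,
)
from larvatox.exceptions import (
    DegenerateRatioWarning,
    InsufficientDataWarning,
    MalformedTraceError,
    ValidationError,
)

from conftest import make_trace


class TestPhaseLabeling:
    def test_assay_protocol_alternates_every_30_bins(self, assay_schedule):
        trace = label_phases(np.zeros(240), assay_schedule)
        phases = trace.phase
        assert len(phases) == 240
        assert assay_schedule.n_phases == 8 and assay_schedule.bins_per_phase == 30
        for start in range(0, 240, 30):
            block = phases[start : start + 30]
            expected = LIGHT if (start // 30) % 2 == 0 else DARK
            assert (block == expected).all()

    def test_minimal_schedule(self):
        sched = PhotoperiodSchedule(phase_length_s=12, n_cycles=1, bin_width_s=6)
        trace = label_phases([0, 0, 0, 0], sched)
        assert list(trace.phase) == [LIGHT, LIGHT, DARK, DARK]

    def test_first_phase_dark(self):
        sched = PhotoperiodSchedule(phase_length_s=12, n_cycles=1, bin_width_s=6, first_phase=DARK)
        assert list(sched.phase_labels()) == [DARK, DARK, LIGHT, LIGHT]

    def test_empty_series_rejected(self, assay_schedule):
        with pytest.raises(MalformedTraceError):
            label_phases([], assay_schedule)

    def test_length_mismatch_rejected(self, assay_schedule):
        with pytest.raises(MalformedTraceError):
            label_phases(np.zeros(239), assay_schedule)

    def test_schedule_invariants(self):
        with pytest.raises(ValidationError):
            PhotoperiodSchedule(phase_length_s=10, bin_width_s=6)  # not divisible
        sched = PhotoperiodSchedule()
        assert sched.total_duration_s == 24 * 60
        assert sched.phase_index(0) == 0 and sched.phase_index(30) == 1


class TestLightSerialExceedance:
    def test_constant_series_never_flags(self, assay_schedule):
        # IQR = 0 so the fence equals the constant; exceedance is strict.
        trace = make_trace(assay_schedule, light_value=2.0, dark_value=5.0)
        flag, fence = light_serial_exceedance_flag(trace)
        assert not flag
        assert fence == pytest.approx(2.0)

    def test_two_late_spikes_flag(self, assay_schedule):
        # 28 bins at 1 plus spikes of 9 at the last two bins of each light
        # phase (elapsed 174 s and 180 s > 60 s). Light values pooled over
        # the 4 light phases: 112 ones, 8 nines → Q3 = 1, IQR = 0, fence = 1.
        phases = assay_schedule.phase_labels()
        values = np.where(phases == LIGHT, 1.0, 10.0)
        for start in range(0, 240, 30):
            if phases[start] == LIGHT:
                values[start + 28 : start + 30] = 9.0
        trace = LocomotionTrace("t", "g", values, assay_schedule)
        flag, fence = light_serial_exceedance_flag(trace)
        assert fence == pytest.approx(1.0)
        assert flag

    def test_nonconsecutive_exceedances_do_not_flag(self, assay_schedule):
        phases = assay_schedule.phase_labels()
        values = np.where(phases == LIGHT, 1.0, 10.0)
        # spikes separated by a sub-fence bin, in one light phase, after burn-in
        values[15] = 9.0
        values[17] = 9.0
        trace = LocomotionTrace("t", "g", values, assay_schedule)
        flag, _ = light_serial_exceedance_flag(trace)
        assert not flag

    def test_spikes_inside_burn_in_ignored(self, assay_schedule):
        phases = assay_schedule.phase_labels()
        values = np.where(phases == LIGHT, 1.0, 10.0)
        values[0:2] = 9.0  # elapsed 6 s and 12 s, within the 60 s burn-in
        trace = LocomotionTrace("t", "g", values, assay_schedule)
        flag, _ = light_serial_exceedance_flag(trace)
        assert not flag

    def test_burn_in_boundary_skips_exactly_ten_bins(self, assay_schedule):
        # bin 9 ends at 60 s (not > 60), bin 10 ends at 66 s: the earliest
        # flaggable pair is bins 10-11 of a light phase.
        phases = assay_schedule.phase_labels()
        base = np.where(phases == LIGHT, 1.0, 10.0)
        inside = base.copy()
        inside[9:11] = 9.0
        flag_inside, _ = light_serial_exceedance_flag(
            LocomotionTrace("a", "g", inside, assay_schedule)
        )
        assert not flag_inside  # pair straddles the burn-in boundary
        past = base.copy()
        past[10:12] = 9.0
        flag_past, _ = light_serial_exceedance_flag(
            LocomotionTrace("b", "g", past, assay_schedule)
        )
        assert flag_past

    def test_too_few_light_bins_warns(self):
        sched = PhotoperiodSchedule(phase_length_s=6, n_cycles=1, bin_width_s=6)
        trace = LocomotionTrace("t", "g", [1.0, 2.0], sched)
        with pytest.warns(InsufficientDataWarning):
            flag, _ = light_serial_exceedance_flag(trace)
        assert not flag


class TestDarkBelowMedian:
    def test_normal_scototaxis_not_flagged(self, assay_schedule):
        trace = make_trace(assay_schedule, light_value=1.0, dark_value=3.0)
        flag, median = dark_below_median_flag(trace)
        assert not flag
        assert median == pytest.approx(1.0)

    def test_two_consecutive_low_dark_bins_flag(self, assay_schedule):
        phases = assay_schedule.phase_labels()
        values = np.where(phases == LIGHT, 5.0, 6.0)
        dark_bins = np.flatnonzero(phases == DARK)
        values[dark_bins[3]] = 4.0
        values[dark_bins[4]] = 4.0  # adjacent within the first dark phase
        trace = LocomotionTrace("t", "g", values, assay_schedule)
        flag, median = dark_below_median_flag(trace)
        assert median == pytest.approx(5.0)
        assert flag

    def test_isolated_low_dark_bin_not_flagged(self, assay_schedule):
        phases = assay_schedule.phase_labels()
        values = np.where(phases == LIGHT, 5.0, 6.0)
        dark_bins = np.flatnonzero(phases == DARK)
        values[dark_bins[3]] = 4.0
        trace = LocomotionTrace("t", "g", values, assay_schedule)
        flag, _ = dark_below_median_flag(trace)
        assert not flag

    def test_low_pair_across_phase_boundary_not_flagged(self, assay_schedule):
        # last bin of dark phase 1 and first bin of dark phase 2 are not serial
        phases = assay_schedule.phase_labels()
        values = np.where(phases == LIGHT, 5.0, 6.0)
        values[59] = 4.0  # end of first dark phase
        values[90] = 4.0  # start of second dark phase
        trace = LocomotionTrace("t", "g", values, assay_schedule)
        flag, _ = dark_below_median_flag(trace)
        assert not flag


class TestLightDarkRatio:
    @pytest.mark.parametrize(
        "light,dark,expected_flag,expected_ratio",
        [
            (0.9, 1.0, True, 0.9),  # boundary inclusive
            (0.0, 1.0, False, 0.0),
            (2.0, 1.0, True, 2.0),  # hyper-responder in light
            (0.89, 1.0, False, 0.89),
        ],
    )
    def test_ratio_boundary(self, assay_schedule, light, dark, expected_flag, expected_ratio):
        trace = make_trace(assay_schedule, light_value=light, dark_value=dark)
        flag, ratio = light_dark_ratio_flag(trace)
        assert flag is expected_flag
        assert ratio == pytest.approx(expected_ratio)

    def test_zero_dark_movement_is_nonresponder(self, assay_schedule):
        trace = make_trace(assay_schedule, light_value=1.0, dark_value=0.0)
        with pytest.warns(DegenerateRatioWarning):
            flag, ratio = light_dark_ratio_flag(trace)
        assert flag and np.isinf(ratio)


class TestApplyQC:
    def test_clean_cohort_retained_and_idempotent(self, assay_schedule):
        traces = [
            make_trace(assay_schedule, light_value=1.0 + 0.01 * i, dark_value=3.0, larva_id=f"t{i}")
            for i in range(10)
        ]
        retained, report = apply_qc(traces)
        assert len(retained) == 10
        assert not report.per_trace["excluded"].any()
        again, report2 = apply_qc(retained)
        assert len(again) == 10

    def test_report_consistency(self, assay_schedule):
        good = make_trace(assay_schedule, 1.0, 3.0, larva_id="good")
        bad = make_trace(assay_schedule, 3.0, 3.0, larva_id="bad")  # ratio 1.0
        retained, report = apply_qc([good, bad])
        df = report.per_trace.set_index("larva_id")
        assert retained[0].larva_id == "good" and len(retained) == 1
        # excluded is the OR of the three flags
        flags = df[["light_rule_flag", "dark_rule_flag", "ratio_flag"]].any(axis=1)
        assert (df["excluded"] == flags).all()
        ret = report.retention
        assert int(ret["n_input"].sum()) == 2
        assert int(ret["n_retained"].sum()) + int(ret["n_excluded"].sum()) == 2

    def test_mixed_schedules_rejected(self, assay_schedule, mini_schedule):
        t1 = make_trace(assay_schedule, 1.0, 3.0)
        t2 = make_trace(mini_schedule, 1.0, 3.0)
        with pytest.raises(ValidationError):
            apply_qc([t1, t2])


def _random_cohort(rng, schedule, n_traces=6):
    traces = []
    for i in range(n_traces):
        # mix clean and pathological shapes so every rule is exercised
        kind = rng.integers(0, 3)
        if kind == 0:
            base = np.where(schedule.phase_labels() == LIGHT, 0.5, 1.5)
        elif kind == 1:
            base = np.full(schedule.n_bins, 1.0)
        else:
            base = rng.uniform(0, 2, schedule.n_bins)
        values = np.clip(base + rng.normal(0, 0.3, schedule.n_bins), 0, None)
        if rng.random() < 0.3:
            values[rng.integers(0, schedule.n_bins)] *= 8
        traces.append(LocomotionTrace(f"t{i}", "g", values, schedule))
    return traces


def _brute_force_flags(trace, thresholds):
    """Enumerate all consecutive bin pairs directly (oracle for run length 2)."""
    phases = trace.phase
    sched = trace.schedule
    light = trace.distance_cm[phases == LIGHT]
    q1, q3 = np.percentile(light, [25, 75])
    fence = q3 + thresholds.iqr_multiplier * (q3 - q1)
    median = np.median(light)
    light_flag = dark_flag = False
    for i in range(sched.n_bins - 1):
        same_phase = sched.phase_index(i) == sched.phase_index(i + 1)
        if not same_phase:
            continue
        a, b = trace.distance_cm[i], trace.distance_cm[i + 1]
        if phases[i] == LIGHT:
            elapsed_i = (i % sched.bins_per_phase + 1) * sched.bin_width_s
            elapsed_j = (i % sched.bins_per_phase + 2) * sched.bin_width_s
            if (
                elapsed_i > thresholds.light_burn_in_s
                and elapsed_j > thresholds.light_burn_in_s
                and a > fence
                and b > fence
            ):
                light_flag = True
        else:
            if a < median and b < median:
                dark_flag = True
    light_mean = trace.distance_cm[phases == LIGHT].mean()
    dark_mean = trace.distance_cm[phases == DARK].mean()
    ratio_flag = dark_mean == 0 or light_mean / dark_mean >= thresholds.ratio_cutoff
    return light_flag, dark_flag, ratio_flag


class TestQCProperties:
    """Invariants checked over 500 random small synthetic cohorts."""

    N_COHORTS = 500

    def test_oracle_equivalence_and_locality_and_monotonicity(self, mini_schedule):
        thresholds = QCThresholds(light_burn_in_s=12.0)
        looser_ratio = QCThresholds(light_burn_in_s=12.0, ratio_cutoff=1.5)
        looser_iqr = QCThresholds(light_burn_in_s=12.0, iqr_multiplier=3.0)
        rng = np.random.default_rng(2024)
        for _ in range(self.N_COHORTS):
            cohort = _random_cohort(rng, mini_schedule)
            _, report = apply_qc(cohort, thresholds)
            df = report.per_trace.set_index("larva_id")
            for trace in cohort:
                expected = _brute_force_flags(trace, thresholds)
                row = df.loc[trace.larva_id]
                got = (
                    bool(row["light_rule_flag"]),
                    bool(row["dark_rule_flag"]),
                    bool(row["ratio_flag"]),
                )
                assert got == expected
                # per-trace locality: the same flags when evaluated alone
                _, solo = apply_qc([trace], thresholds)
                srow = solo.per_trace.iloc[0]
                assert (
                    bool(srow["light_rule_flag"]),
                    bool(srow["dark_rule_flag"]),
                    bool(srow["ratio_flag"]),
                ) == got
                # monotonicity: relaxing thresholds never adds exclusions
                if not row["ratio_flag"]:
                    assert not light_dark_ratio_flag(trace, looser_ratio)[0]
                if not row["light_rule_flag"]:
                    assert not light_serial_exceedance_flag(trace, looser_iqr)[0]

    def test_idempotence_on_random_cohorts(self, mini_schedule):
        thresholds = QCThresholds(light_burn_in_s=12.0)
        rng = np.random.default_rng(7)
        for _ in range(50):
            cohort = _random_cohort(rng, mini_schedule, n_traces=8)
            retained, _ = apply_qc(cohort, thresholds)
            retained2, report2 = apply_qc(retained, thresholds)
            assert len(retained2) == len(retained)
            assert not report2.per_trace["excluded"].any()
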