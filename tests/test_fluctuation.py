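"""First-dose window, EMB, peak effect, wearing-off, QC and classification."""

import math

import numpy as np
import pandas as pd
import pytest

import pkgfluct as pf
from pkgfluct import FluctuationAssessment
from pkgfluct.fluctuation import _next_dose_gap


def make_series(values_by_clock, n_days=6, start="2024-03-04", default=np.nan):
    """Severity series on the full 2-min grid; values_by_clock maps
    minute-of-day -> severity (callable or dict), default elsewhere."""
    idx = pd.date_range(start, periods=n_days * 720, freq="2min")
    minutes = idx.hour * 60 + idx.minute
    if callable(values_by_clock):
        values = np.array([values_by_clock(m) for m in minutes], dtype=float)
    else:
        values = np.array([values_by_clock.get(m, default) for m in minutes], dtype=float)
    return pd.Series(values, index=idx)


class TestFirstDoseClock:
    def test_first_reminder_after_0500(self, recording_factory):
        rec = recording_factory(bks=np.full(720, 20.0), dose_clocks=("04:30", "07:00"))
        assert pf.first_dose_clock(rec) == 7 * 60

    def test_no_reminders_not_estimable(self, recording_factory):
        rec = recording_factory(bks=np.full(720, 20.0))
        assert pf.first_dose_clock(rec) is None
        assert pf.assess_subject(rec).fluct_class == "not_estimable"

    def test_reminder_exactly_0500_used(self, recording_factory):
        rec = recording_factory(bks=np.full(720, 20.0), dose_clocks=("05:00",))
        assert pf.first_dose_clock(rec) == 5 * 60

    def test_next_dose_gap(self, recording_factory):
        rec = recording_factory(bks=np.full(720, 20.0), dose_clocks=("07:00", "12:00"))
        assert _next_dose_gap(rec, 7 * 60, pf.DEFAULT_CONFIG) == 300


class TestEmb:
    def test_constant_severity_all_slots(self):
        series = make_series(lambda m: 3.2)
        mean, sd = pf.emb(series, 7 * 60)
        assert mean == pytest.approx(3.2)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_half_available_is_estimable(self):
        # 15 of 30 slots available: exactly 50% unavailable, still estimated
        series = make_series(lambda m: 3.0)
        idx = series.index
        window = (idx.hour * 60 + idx.minute).isin([416, 418, 420, 422, 424])
        slots = np.flatnonzero(window)
        series.iloc[slots[15:]] = np.nan
        mean, _ = pf.emb(series, 7 * 60)
        assert mean == pytest.approx(3.0)

    def test_under_half_available_not_estimable(self):
        # 14 of 30 available: more than 50% unavailable
        series = make_series(lambda m: 3.0)
        idx = series.index
        window = (idx.hour * 60 + idx.minute).isin([416, 418, 420, 422, 424])
        slots = np.flatnonzero(window)
        series.iloc[slots[14:]] = np.nan
        mean, _ = pf.emb(series, 7 * 60)
        assert math.isnan(mean)


class TestPeakEffect:
    def test_v_shaped_minimum_recovered(self):
        def trace(m):
            tau = m - 7 * 60
            if 0 <= tau <= 120:
                return 3.5 - 2.0 * max(0.0, 1.0 - abs(tau - 60) / 45.0)
            return 3.5

        series = make_series(trace)
        offsets, smoothed, days = pf.response_curve(series, 7 * 60)
        off, sev_min, sd = pf.peak_effect(offsets, smoothed, days)
        assert off == pytest.approx(60, abs=2)
        assert sev_min < 2.0
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_flat_series_ties_to_earliest_offset(self):
        series = make_series(lambda m: 3.0)
        offsets, smoothed, days = pf.response_curve(series, 7 * 60)
        off, sev_min, _ = pf.peak_effect(offsets, smoothed, days)
        assert off == 46.0
        assert sev_min == pytest.approx(3.0)

    def test_all_offsets_unavailable_not_estimable(self):
        series = make_series(lambda m: np.nan)
        offsets, smoothed, days = pf.response_curve(series, 7 * 60)
        off, sev_min, _ = pf.peak_effect(offsets, smoothed, days)
        assert math.isnan(off) and math.isnan(sev_min)

    def test_noisy_trough_at_70min_recovered(self):
        # sharp-trough wearing-off response, sigma 0.15, 6 days
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            scenario = pf.canonical_scenario(
                "FC_WO", seed=seed, response_peak_min=70.0, plateau_min=0.0
            )
            rec, truth = pf.simulate_subject(scenario)
            a = pf.assess_subject(rec)
            if abs(a.pte_offset_min - 70.0) <= 6.0:
                hits += 1
        assert hits >= 90


class TestLevodopaResponse:
    @pytest.mark.parametrize(
        "emb_sev,pte_sev,delta,significant",
        [(3.6, 2.0, 1.6, True), (3.15, 2.0, 1.15, True), (2.0, 2.3, -0.3, False)],
    )
    def test_threshold(self, emb_sev, pte_sev, delta, significant):
        d1, sig = pf.levodopa_response(emb_sev, pte_sev)
        assert d1 == pytest.approx(delta)
        assert sig is significant


class TestExcessVariability:
    @pytest.mark.parametrize(
        "sd_dose,sd_pte,excluded",
        [(1.2, 1.3, True), (1.2, 0.4, False), (0.0, 0.0, False)],
    )
    def test_conjunction_rule(self, sd_dose, sd_pte, excluded):
        assert pf.excess_variability(sd_dose, sd_pte) is excluded

    def test_disjunctive_rule_via_config(self):
        cfg = pf.DEFAULT_CONFIG.with_overrides(variability_rule="or")
        assert pf.excess_variability(1.2, 0.4, cfg) is True


class TestWearingOff:
    def make_curve(self, rise, pte_offset=60):
        offsets = np.arange(0, 242, 2, dtype=float)
        smoothed = np.full_like(offsets, 1.2)
        smoothed[offsets > pte_offset] = 1.2 + rise
        return offsets, smoothed

    def test_rise_above_threshold(self):
        offsets, smoothed = self.make_curve(1.1)
        wo, d2 = pf.wearing_off(offsets, smoothed, 60.0, 1.2)
        assert wo is True and d2 == pytest.approx(1.1)

    def test_subthreshold_rise(self):
        offsets, smoothed = self.make_curve(0.9)
        wo, d2 = pf.wearing_off(offsets, smoothed, 60.0, 1.2)
        assert wo is False and d2 == pytest.approx(0.9)

    def test_persisting_flat_response(self):
        offsets = np.arange(0, 242, 2, dtype=float)
        smoothed = np.full_like(offsets, 1.2)
        wo, d2 = pf.wearing_off(offsets, smoothed, 60.0, 1.2)
        assert wo is False and d2 == pytest.approx(0.0)

    def test_rise_after_next_dose_ignored(self):
        offsets, smoothed = self.make_curve(0.0)
        smoothed[offsets > 100] = 3.0  # rise only after the next reminder
        wo, d2 = pf.wearing_off(offsets, smoothed, 60.0, 1.2, next_dose_gap_min=100.0)
        assert wo is False and d2 == pytest.approx(0.0)

    def test_empty_window_not_estimable(self):
        offsets = np.arange(0, 242, 2, dtype=float)
        smoothed = np.full_like(offsets, np.nan)
        wo, d2 = pf.wearing_off(offsets, smoothed, 60.0, 1.2)
        assert wo is None and math.isnan(d2)


def make_assessment(emb=3.5, pte=2.0, wo=False, qc=False):
    a = FluctuationAssessment(subject_id="X")
    a.emb_severity = emb
    a.pte_severity = pte
    a.levodopa_response = emb - pte if not (math.isnan(emb) or math.isnan(pte)) else float("nan")
    a.wearing_off = wo
    a.qc_excluded = qc
    return a


class TestClassify:
    @pytest.mark.parametrize(
        "emb,pte,wo,expected",
        [
            (1.0, 0.6, False, "NFC"),      # delta1 0.4, controlled morning
            (3.0, 2.6, False, "NFU"),      # delta1 0.4, uncontrolled morning
            (3.5, 1.5, False, "FC_P"),     # delta1 2.0, reaches target, persists
            (3.5, 1.5, True, "FC_WO"),
            (4.5, 3.0, False, "FU_P"),     # delta1 1.5, stays above target
            (4.5, 3.0, True, "FU_WO"),
        ],
    )
    def test_six_classes(self, emb, pte, wo, expected):
        assert pf.classify(make_assessment(emb, pte, wo)) == expected

    def test_qc_exclusion_dominates(self):
        assert pf.classify(make_assessment(qc=True)) == "excluded_variability"

    def test_missing_inputs_not_estimable(self):
        assert pf.classify(make_assessment(emb=float("nan"))) == "not_estimable"

    def test_total_partition_over_grid(self):
        # every estimable, QC-passing combination lands in exactly one class
        for emb in np.linspace(0.0, 5.5, 12):
            for pte in np.linspace(0.0, 5.5, 12):
                for wo in (False, True):
                    cls = pf.classify(make_assessment(emb, pte, wo))
                    assert cls in pf.FLUCTUATOR_CLASSES


class TestEndToEnd:
    def test_definitional_ordering(self):
        rec, truth = pf.simulate_subject(pf.canonical_scenario("FC_P", seed=3))
        a = pf.assess_subject(rec)
        assert a.levodopa_response >= 0
        assert a.pte_severity <= a.emb_severity
        assert 46 <= a.pte_offset_min <= 90

    def test_invariant_to_evening_content(self):
        rec, truth = pf.simulate_subject(pf.canonical_scenario("NFU", seed=5))
        a1 = pf.assess_subject(rec)
        mod = rec.epochs.copy()
        ts = pd.to_datetime(mod["timestamp"])
        evening = (ts.dt.hour >= 19) & (ts.dt.hour < 21)
        mod.loc[evening, "bks"] = 10.0
        rec2 = pf.SubjectRecording(subject_id="T2", epochs=mod, doses=rec.doses)
        a2 = pf.assess_subject(rec2)
        assert a1.fluct_class == a2.fluct_class
        assert a1.levodopa_response == pytest.approx(a2.levodopa_response)
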