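"""First-dose levodopa response, wearing-off and the six-way fluctuator
classification.

The analysis is anchored on the first medication reminder at or after
05:00 (the "first dose time", DT).  Early-morning bradykinesia (EMB) is
the mean severity over the 5-epoch (10-min) window centred on DT, pooled
across all recorded days; it is not estimable when more than half of the
window's epoch-slots are unavailable (asleep, inactive or not worn) or
when there is no qualifying reminder.

The time of peak levodopa effect (PTE) is found on the mean-by-offset
severity curve: severities at matching offsets from DT are pooled across
days, smoothed over a 15-epoch (30-min) centred window, and the minimum
(least bradykinesia = maximal mobility) over offsets 46-90 min post-dose
is the peak effect; ties break to the earliest offset.  The default
smoothing kernel is a moving average: a moving median flattens a
symmetric trough into a plateau half a window wide, which together with
the earliest-tie rule would bias the peak-effect time early; the mean
keeps a unique minimum for convex troughs.  A median kernel remains
available through the configuration.

The levodopa response is Δ₁ = EMB severity − PTE severity, significant
when >= 1.15 severity levels (~14 UPDRS-III points).  Wearing-off is a
rise Δ₂ >= 1 severity level of the smoothed curve within 2 h after PTE
(stopping at the next dose reminder).  Recordings whose severity standard
deviation exceeds 1 level at both anchor times are QC-excluded as
excess-variability.

Classification (a total partition of QC-passing, estimable recordings):

* Δ₁ < 1.15, EMB < 2.5  → NFC  (non-fluctuator, controlled)
* Δ₁ < 1.15, EMB >= 2.5 → NFU  (non-fluctuator, uncontrolled)
* Δ₁ >= 1.15, PTE severity < 2.5  → FC_P / FC_WO by wearing-off
* Δ₁ >= 1.15, PTE severity >= 2.5 → FU_P / FU_WO by wearing-off
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig, DEFAULT_CONFIG, parse_clock
from .epoch_io import SubjectRecording
from .masking import EpochMask, compute_masks, moving_median
from . import severity as sev

FLUCTUATOR_CLASSES = ("NFC", "NFU", "FC_P", "FC_WO", "FU_P", "FU_WO")
ALL_CLASSES = FLUCTUATOR_CLASSES + ("excluded_variability", "not_estimable")


@dataclass
class FluctuationAssessment:
    """Per-recording levodopa-response estimate and fluctuator class.

    Clock times are "HH:MM" strings; severities are continuous levels.
    NaN marks a not-estimable quantity.
    """

    subject_id: str
    first_dose_time: str | None = None
    emb_severity: float = float("nan")
    emb_present: bool | None = None
    pte_time: str | None = None
    pte_offset_min: float = float("nan")
    pte_severity: float = float("nan")
    levodopa_response: float = float("nan")
    significant_response: bool | None = None
    wearing_off: bool | None = None
    delta2: float = float("nan")
    sd_dose: float = float("nan")
    sd_pte: float = float("nan")
    qc_excluded: bool = False
    fluct_class: str = "not_estimable"


def _fmt_clock(minutes: float) -> str:
    m = int(round(minutes)) % (24 * 60)
    return f"{m // 60:02d}:{m % 60:02d}"


def first_dose_clock(recording: SubjectRecording, config: PipelineConfig = DEFAULT_CONFIG) -> int | None:
    """Clock time (minutes after midnight) of the first reminder at or after
    05:00, snapped to the epoch grid; None when no reminder qualifies."""
    earliest = parse_clock(config.first_dose_earliest)
    clocks = []
    for ev in recording.doses:
        t = pd.Timestamp(ev.reminder_time)
        minutes = t.hour * 60 + t.minute
        if minutes >= earliest:
            clocks.append(minutes)
    if not clocks:
        return None
    step = config.epoch_minutes
    return int(round(min(clocks) / step)) * step


def _next_dose_gap(recording: SubjectRecording, dose_clock: int, config: PipelineConfig) -> float:
    """Minutes from the first dose to the next distinct reminder clock time
    (inf when there is none)."""
    gaps = []
    for ev in recording.doses:
        t = pd.Timestamp(ev.reminder_time)
        minutes = t.hour * 60 + t.minute
        if minutes > dose_clock:
            gaps.append(minutes - dose_clock)
    return min(gaps) if gaps else math.inf


def severity_series(
    recording: SubjectRecording,
    masks: EpochMask | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.Series:
    """Per-epoch continuous severity indexed by timestamp; NaN where the
    epoch is unavailable (not worn, asleep or inactive — no daytime
    restriction, since the dose windows fall in the early morning)."""
    if masks is None:
        masks = compute_masks(recording.epochs, config)
    bks = recording.epochs["bks"].to_numpy(dtype=float)
    values = np.asarray(sev.bks_to_severity(bks, config), dtype=float)
    values = values.copy()
    values[~masks.awake_worn] = np.nan
    index = pd.DatetimeIndex(pd.to_datetime(recording.epochs["timestamp"])).floor("min")
    return pd.Series(values, index=index)


def _slots_by_day(series: pd.Series, dose_clock: int, offsets_min: np.ndarray) -> np.ndarray:
    """Matrix of severity values (days x offsets) at clock time
    dose_clock + offset on each recorded date; NaN where unavailable."""
    dates = series.index.normalize().unique().sort_values()
    rows = []
    for date in dates:
        targets = date + pd.to_timedelta(dose_clock + offsets_min, unit="min")
        rows.append(series.reindex(targets).to_numpy())
    return np.vstack(rows)


def emb(
    series: pd.Series, dose_clock: int, config: PipelineConfig = DEFAULT_CONFIG
) -> tuple[float, float]:
    """Early-morning bradykinesia severity and its standard deviation.

    Mean (and sd, ddof=1) of severity over the available slots of the
    5-epoch window centred on the first dose time, across all recorded
    days.  Returns (NaN, NaN) when fewer than half the slots are available.
    """
    half = config.emb_window_epochs // 2
    offsets = np.arange(-half, half + 1) * config.epoch_minutes
    values = _slots_by_day(series, dose_clock, offsets).ravel()
    n_slots = values.size
    avail = values[~np.isnan(values)]
    if n_slots == 0 or avail.size < config.emb_min_available_frac * n_slots:
        return float("nan"), float("nan")
    mean = float(np.mean(avail))
    sd = float(np.std(avail, ddof=1)) if avail.size > 1 else 0.0
    return mean, sd


def response_curve(
    series: pd.Series,
    dose_clock: int,
    config: PipelineConfig = DEFAULT_CONFIG,
    max_offset_min: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed mean-by-offset severity curve after the first dose.

    Severities at matching offsets from the dose time are pooled across
    days into a mean-by-offset curve (an offset needs at least
    ``min_days_per_offset`` contributing days, capped at the number of
    recorded days), then smoothed over the configured centred window
    (moving average by default, moving median optionally).

    Returns (offsets_min, smoothed_curve, day_matrix).
    """
    if max_offset_min is None:
        half_window = (config.smoothing_window_epochs // 2) * config.epoch_minutes
        max_offset_min = config.pte_max_offset_min + config.wearing_off_window_min + half_window
    offsets = np.arange(0, max_offset_min + config.epoch_minutes, config.epoch_minutes)
    day_matrix = _slots_by_day(series, dose_clock, offsets)
    n_days = day_matrix.shape[0]
    min_days = min(config.min_days_per_offset, n_days)
    counts = np.sum(~np.isnan(day_matrix), axis=0)
    sums = np.nansum(day_matrix, axis=0)
    mean_curve = np.full(offsets.shape, np.nan)
    enough = counts >= max(min_days, 1)
    mean_curve[enough] = sums[enough] / counts[enough]
    if config.pte_smoothing == "median":
        smoothed = moving_median(mean_curve, config.smoothing_window_epochs)
    else:
        smoothed = (
            pd.Series(mean_curve)
            .rolling(config.smoothing_window_epochs, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    return offsets, smoothed, day_matrix


def peak_effect(
    offsets: np.ndarray,
    smoothed: np.ndarray,
    day_matrix: np.ndarray,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[float, float, float]:
    """Time, severity and across-day sd of the peak levodopa effect.

    The peak effect is the minimum of the smoothed curve over offsets
    46-90 min post-dose (least bradykinesia); ties break to the earliest
    offset.  Returns (offset_min, severity, sd) or NaNs when every offset
    in the window is unavailable.
    """
    window = (offsets >= config.pte_min_offset_min) & (offsets <= config.pte_max_offset_min)
    values = np.where(window, smoothed, np.nan)
    if np.all(np.isnan(values)):
        return float("nan"), float("nan"), float("nan")
    idx = int(np.nanargmin(values))  # first occurrence of the minimum
    day_values = day_matrix[:, idx]
    day_values = day_values[~np.isnan(day_values)]
    sd = float(np.std(day_values, ddof=1)) if day_values.size > 1 else 0.0
    return float(offsets[idx]), float(values[idx]), sd


def levodopa_response(
    emb_severity: float, pte_severity: float, config: PipelineConfig = DEFAULT_CONFIG
) -> tuple[float, bool | None]:
    """Δ₁ = EMB severity − PTE severity; significant iff >= 1.15 levels."""
    delta1 = emb_severity - pte_severity
    if math.isnan(delta1):
        return float("nan"), None
    return float(delta1), bool(delta1 >= config.significant_response)


def excess_variability(
    sd_dose: float, sd_pte: float, config: PipelineConfig = DEFAULT_CONFIG
) -> bool:
    """QC: excess variability when the severity sd exceeds one level at the
    first-dose time and the peak-effect time (conjunction by default;
    ``variability_rule="or"`` switches to either)."""
    if math.isnan(sd_dose) or math.isnan(sd_pte):
        return False
    over_dose = sd_dose > config.excess_variability_sd
    over_pte = sd_pte > config.excess_variability_sd
    if config.variability_rule == "and":
        return over_dose and over_pte
    return over_dose or over_pte


def wearing_off(
    offsets: np.ndarray,
    smoothed: np.ndarray,
    pte_offset_min: float,
    pte_severity: float,
    next_dose_gap_min: float = math.inf,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[bool | None, float]:
    """Wearing-off test: Δ₂ = maximal rise of the smoothed curve above the
    peak-effect severity within 2 h after PTE (stopping at the next dose
    reminder); wearing-off iff Δ₂ >= 1.  (None, NaN) when the window holds
    no available offset."""
    if math.isnan(pte_offset_min):
        return None, float("nan")
    upper = min(pte_offset_min + config.wearing_off_window_min, next_dose_gap_min)
    window = (offsets > pte_offset_min) & (offsets <= upper)
    values = np.where(window, smoothed, np.nan)
    if np.all(np.isnan(values)):
        return None, float("nan")
    delta2 = float(np.nanmax(values) - pte_severity)
    return bool(delta2 >= config.wearing_off_delta), delta2


def classify(assessment: FluctuationAssessment, config: PipelineConfig = DEFAULT_CONFIG) -> str:
    """Six-way fluctuator class for a completed assessment."""
    if assessment.qc_excluded:
        return "excluded_variability"
    d1 = assessment.levodopa_response
    if math.isnan(assessment.emb_severity) or math.isnan(assessment.pte_severity) or math.isnan(d1):
        return "not_estimable"
    if d1 < config.significant_response:
        return "NFC" if assessment.emb_severity < config.target_level else "NFU"
    controlled = assessment.pte_severity < config.target_level
    if assessment.wearing_off is None:
        return "not_estimable"
    suffix = "WO" if assessment.wearing_off else "P"
    return ("FC_" if controlled else "FU_") + suffix


def assess_subject(
    recording: SubjectRecording,
    masks: EpochMask | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> FluctuationAssessment:
    """Run the full first-dose analysis for one recording."""
    if masks is None:
        masks = compute_masks(recording.epochs, config)
    out = FluctuationAssessment(subject_id=recording.subject_id)
    dose_clock = first_dose_clock(recording, config)
    if dose_clock is None:
        return out
    out.first_dose_time = _fmt_clock(dose_clock)

    series = severity_series(recording, masks, config)
    out.emb_severity, out.sd_dose = emb(series, dose_clock, config)
    if not math.isnan(out.emb_severity):
        out.emb_present = bool(out.emb_severity >= config.target_level)

    offsets, smoothed, day_matrix = response_curve(series, dose_clock, config)
    out.pte_offset_min, out.pte_severity, out.sd_pte = peak_effect(
        offsets, smoothed, day_matrix, config
    )
    if not math.isnan(out.pte_offset_min):
        out.pte_time = _fmt_clock(dose_clock + out.pte_offset_min)

    out.levodopa_response, out.significant_response = levodopa_response(
        out.emb_severity, out.pte_severity, config
    )
    out.qc_excluded = excess_variability(out.sd_dose, out.sd_pte, config)
    out.wearing_off, out.delta2 = wearing_off(
        offsets,
        smoothed,
        out.pte_offset_min,
        out.pte_severity,
        _next_dose_gap(recording, dose_clock, config),
        config,
    )
    out.fluct_class = classify(out, config)
    return out
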