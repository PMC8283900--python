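"""Synthetic cohort generator with known ground truth.

Each simulated subject is a 6-day recording of 2-minute epochs whose
bradykinesia severity follows a dose-locked pharmacodynamic trace:

    severity(t) = clip(baseline − amplitude · R(t − dose) + ε, 0, 5.5)

where R rises linearly from 0 at ``response_onset_min`` to 1 at
``response_peak_min`` (46-90 min post-dose, the published peak-effect
window), holds at full effect for ``plateau_min`` minutes, and then
either keeps holding (persisting response) or decays exponentially with
the stated half-time (wearing-off); ε is Gaussian noise.  The plateau
matches the clinical geometry in which the decline of a wearing-off
response is detected roughly 2-3 hours after the dose, not at the peak
itself.  Severity is mapped to the bradykinesia score through the inverse
of the severity calibration, so the analysis pipeline sees exactly the
score scale it expects.  Outside the wake window the score is drawn
>= 80 (sleep).  Dyskinesia is dose-locked by default: the dyskinesia
score sits near ``dysk_amplitude`` while the response is within 0.3
severity levels of its peak and near zero otherwise (mirroring the
observation that high dyskinesia time co-occurs with controlled
bradykinesia).  Walking and tremor flags are sampled independently per
awake epoch; optional inactivity bouts inject sustained BKS≈45 blocks to
exercise the moving-median mask.

The six canonical scenarios reproduce the fluctuator taxonomy: NFC, NFU,
FC_P, FC_WO, FU_P and FU_WO, with awake baselines kept below severity 4
(BKS 40) so that sustained severe bradykinesia is not swallowed by the
inactivity mask, and margins of at least 0.1 severity levels on every
decision boundary.

Everything is reproducible from the scenario seed (numpy's PCG64
generator on an integer epoch grid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig, DEFAULT_CONFIG, ValidationError, parse_clock
from .epoch_io import DoseEvent, SubjectRecording, write_epochs, write_doses
from . import severity as sev

EPOCHS_PER_DAY = 720  # 24 h of 2-min epochs
DEFAULT_START = "2024-03-04"


@dataclass(frozen=True)
class SubjectScenario:
    """Generative parameters for one simulated subject."""

    subject_id: str = "SIM"
    baseline_severity: float = 3.5       # severity level when levodopa has no effect
    response_amplitude: float = 0.0      # Δ₁ ground truth, severity levels
    response_onset_min: float = 15.0     # minutes post-dose at which severity starts falling
    response_peak_min: float = 60.0      # minutes post-dose of full effect (46-90)
    plateau_min: float = 30.0            # minutes held at full effect after the peak
    wearing_off: bool = False            # decay after the plateau vs persisting response
    wearing_off_halftime_min: float = 30.0
    dose_times: tuple[str, ...] = ("07:00", "12:00", "17:00")
    wake_time: str = "06:00"
    sleep_time: str = "22:00"
    noise_sd: float = 0.15               # severity-level units
    dysk_amplitude: float = 0.0          # DKS plateau during peak effect
    walking_rate: float = 0.02           # per awake epoch
    tremor_rate: float = 0.02
    not_worn_rate: float = 0.0
    inactive_bout_start: str | None = None  # clock time of a daily BKS≈45 block
    inactive_bout_min: float = 0.0
    n_days: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 46 <= self.response_peak_min <= 90:
            raise ValidationError(f"response_peak_min must be in [46, 90], got {self.response_peak_min}")
        if not 0 <= self.response_onset_min < self.response_peak_min:
            raise ValidationError("response_onset_min must be in [0, response_peak_min)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for name in ("walking_rate", "tremor_rate", "not_worn_rate"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if not 0 <= self.baseline_severity <= sev.MAX_SEVERITY:
            raise ValidationError("baseline_severity must be in [0, 5.5]")
        if not 1 <= self.n_days <= 10:
            raise ValidationError("n_days must be in [1, 10]")
        if self.plateau_min < 0:
            raise ValidationError("plateau_min must be >= 0")
        if self.wearing_off and self.wearing_off_halftime_min <= 0:
            raise ValidationError("wearing_off_halftime_min must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the pipeline should recover for a simulated subject."""

    subject_id: str
    true_class: str
    true_delta1: float
    true_ptb_fraction: float
    true_ptd_fraction: float
    true_pte_offset_min: float


def _response_fraction(minute_of_day: np.ndarray, scenario: SubjectScenario) -> np.ndarray:
    """Dose-response fraction R(t) in [0, 1], combined over doses by max."""
    r_total = np.zeros_like(minute_of_day, dtype=float)
    onset, peak = scenario.response_onset_min, scenario.response_peak_min
    for dose in scenario.dose_times:
        tau = minute_of_day - parse_clock(dose)
        r = np.zeros_like(r_total)
        rising = (tau >= onset) & (tau < peak)
        r[rising] = (tau[rising] - onset) / (peak - onset)
        decay_start = peak + scenario.plateau_min
        holding = (tau >= peak) & (tau < decay_start)
        r[holding] = 1.0
        after = tau >= decay_start
        if scenario.wearing_off:
            r[after] = np.exp2(-(tau[after] - decay_start) / scenario.wearing_off_halftime_min)
        else:
            r[after] = 1.0
        r_total = np.maximum(r_total, r)
    return r_total


def true_class(scenario: SubjectScenario, config: PipelineConfig = DEFAULT_CONFIG) -> str:
    """Fluctuator class implied by the scenario geometry."""
    b, a = scenario.baseline_severity, scenario.response_amplitude
    if a < config.significant_response:
        return "NFC" if b < config.target_level else "NFU"
    pte_severity = max(b - a, 0.0)
    if scenario.wearing_off:
        decay_minutes = max(config.wearing_off_window_min - scenario.plateau_min, 0.0)
        rise = a * (1.0 - 2.0 ** (-decay_minutes / scenario.wearing_off_halftime_min))
        wo = rise >= config.wearing_off_delta
    else:
        wo = False
    prefix = "FC_" if pte_severity < config.target_level else "FU_"
    return prefix + ("WO" if wo else "P")


def simulate_subject(
    scenario: SubjectScenario,
    start_date: str = DEFAULT_START,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[SubjectRecording, GroundTruth]:
    """Generate one recording and its ground truth (reproducible from seed)."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_days * EPOCHS_PER_DAY
    timestamps = pd.date_range(start=start_date, periods=n, freq="2min")
    minute_of_day = (timestamps.hour * 60 + timestamps.minute).to_numpy()

    wake = parse_clock(scenario.wake_time)
    sleep_t = parse_clock(scenario.sleep_time)
    awake = (minute_of_day >= wake) & (minute_of_day < sleep_t)

    r = _response_fraction(minute_of_day, scenario)
    severity_clean = np.clip(
        scenario.baseline_severity - scenario.response_amplitude * r, 0.0, sev.MAX_SEVERITY
    )
    noise = rng.normal(0.0, scenario.noise_sd, size=n) if scenario.noise_sd > 0 else np.zeros(n)
    severity_noisy = np.clip(severity_clean + noise, 0.0, sev.MAX_SEVERITY)

    bks = np.asarray(sev.severity_to_bks(severity_noisy, config), dtype=float)
    bks[~awake] = rng.uniform(config.sleep_bks, config.sleep_bks + 30.0, size=int((~awake).sum()))

    in_bout = np.zeros(n, dtype=bool)
    if scenario.inactive_bout_start is not None and scenario.inactive_bout_min > 0:
        b0 = parse_clock(scenario.inactive_bout_start)
        in_bout = awake & (minute_of_day >= b0) & (minute_of_day < b0 + scenario.inactive_bout_min)
        bks[in_bout] = 45.0 + rng.normal(0.0, 1.0, size=int(in_bout.sum()))

    dks = np.abs(rng.normal(0.0, 0.5, size=n))
    dks[~awake] = np.abs(rng.normal(0.0, 0.2, size=int((~awake).sum())))
    near_peak = np.zeros(n, dtype=bool)
    if scenario.dysk_amplitude > 0:
        near_peak = awake & (
            scenario.response_amplitude * r >= scenario.response_amplitude - 0.3
        )
        dks[near_peak] = np.clip(
            scenario.dysk_amplitude + rng.normal(0.0, 1.0, size=int(near_peak.sum())), 0.0, None
        )

    walking = awake & (rng.random(n) < scenario.walking_rate)
    tremor = awake & (rng.random(n) < scenario.tremor_rate)
    worn = rng.random(n) >= scenario.not_worn_rate

    epochs = pd.DataFrame(
        {
            "timestamp": timestamps,
            "bks": bks,
            "dks": dks,
            "worn": worn,
            "tremor": tremor,
            "walking": walking,
        }
    )
    doses = [
        DoseEvent(reminder_time=(pd.Timestamp(start_date) + pd.Timedelta(days=d, minutes=parse_clock(clock))).to_pydatetime())
        for d in range(scenario.n_days)
        for clock in scenario.dose_times
    ]
    recording = SubjectRecording(subject_id=scenario.subject_id, epochs=epochs, doses=doses)

    # ground truth from the noiseless trace / generated flags
    day_start, day_end = parse_clock(config.day_start), parse_clock(config.day_end)
    daytime = (minute_of_day >= day_start) & (minute_of_day < day_end)
    ptb_denom = daytime & awake & worn & ~in_bout
    true_ptb = float(np.mean(severity_clean[ptb_denom] >= config.target_level)) if ptb_denom.any() else float("nan")
    ptd_denom = daytime & worn
    true_ptd = (
        float(np.mean((dks >= config.dks_threshold) & ~walking & ~tremor & ptd_denom) / np.mean(ptd_denom))
        if ptd_denom.any()
        else float("nan")
    )
    truth = GroundTruth(
        subject_id=scenario.subject_id,
        true_class=true_class(scenario, config),
        true_delta1=scenario.response_amplitude,
        true_ptb_fraction=true_ptb,
        true_ptd_fraction=true_ptd,
        true_pte_offset_min=(
            scenario.response_peak_min if scenario.response_amplitude > 0 else float("nan")
        ),
    )
    return recording, truth


# --- canonical scenario library -----------------------------------------

#: baseline severity, response amplitude, wearing-off for the six classes.
CANONICAL_PARAMS: dict[str, dict] = {
    "NFC": dict(baseline_severity=1.5, response_amplitude=0.0, wearing_off=False),
    "NFU": dict(baseline_severity=3.5, response_amplitude=0.3, wearing_off=False),
    "FC_P": dict(baseline_severity=3.6, response_amplitude=2.2, wearing_off=False),
    "FC_WO": dict(baseline_severity=3.6, response_amplitude=2.2, wearing_off=True),
    "FU_P": dict(baseline_severity=3.9, response_amplitude=1.3, wearing_off=False),
    "FU_WO": dict(baseline_severity=3.9, response_amplitude=1.3, wearing_off=True),
}


def canonical_scenario(name: str, subject_id: str | None = None, seed: int = 0, **overrides) -> SubjectScenario:
    """One of the six canonical fluctuator scenarios (case-insensitive name)."""
    key = name.upper()
    if key not in CANONICAL_PARAMS:
        raise ValidationError(f"unknown scenario {name!r}; choose from {sorted(CANONICAL_PARAMS)}")
    params = dict(CANONICAL_PARAMS[key])
    params.update(overrides)
    return SubjectScenario(subject_id=subject_id or f"{key}-{seed}", seed=seed, **params)


def simulate_cohort(
    n: int,
    scenario_mix: Mapping[str, float],
    seed: int = 0,
    start_date: str = DEFAULT_START,
    config: PipelineConfig = DEFAULT_CONFIG,
    **overrides,
) -> list[tuple[SubjectRecording, GroundTruth]]:
    """Simulate ``n`` subjects with scenario names drawn from a weighted mix.

    Each subject gets an independent child seed below 2^31; the cohort is
    byte-identical for a fixed (n, mix, seed).
    """
    if n == 0:
        return []
    names = sorted(scenario_mix)
    weights = np.array([scenario_mix[k] for k in names], dtype=float)
    if weights.sum() <= 0:
        raise ValidationError("scenario_mix weights must sum to a positive value")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        name = names[int(rng.choice(len(names), p=weights))]
        child_seed = int(rng.integers(0, 2**31))
        scenario = canonical_scenario(name, subject_id=f"S{i:04d}", seed=child_seed, **overrides)
        cohort.append(simulate_subject(scenario, start_date=start_date, config=config))
    return cohort


def write_cohort(
    cohort: Sequence[tuple[SubjectRecording, GroundTruth]], out_dir: str | Path
) -> None:
    """Emit epochs.csv, doses.csv and ground_truth.json for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recordings = [rec for rec, _ in cohort]
    write_epochs(recordings, out / "epochs.csv")
    write_doses({rec.subject_id: rec.doses for rec in recordings}, out / "doses.csv")
    truths = [asdict(truth) for _, truth in cohort]
    (out / "ground_truth.json").write_text(json.dumps(truths, indent=2))
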