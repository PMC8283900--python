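"""The median-score family and percent time in dyskinesia (PTD).

All medians are 50th percentiles (linear interpolation between order
statistics) over the 09:00-18:00 daytime window, pooled across all recorded
days, restricted to worn epochs:

* median BKS (mBKS) — over epochs with bradykinesia score <= 80 (awake);
* active median BKS — additionally excluding inactivity;
* median DKS (mDKS) — all worn daytime epochs;
* adjusted median DKS — walking epochs removed (gait energy contaminates
  the dyskinesia signal) and epochs with tremor and DKS >= 10 contribute
  zero (the elevated score is attributed to tremor, not dyskinesia);
* PTD — percent of worn daytime epochs with DKS >= 10 and neither walking
  nor tremor detected.  The DKS >= 10 threshold is the 75th percentile of
  the control population for the adjusted score.

An empty sample after masking yields NaN ("not estimable") rather than an
exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig, DEFAULT_CONFIG
from .epoch_io import SubjectRecording
from .masking import EpochMask, compute_masks
from . import severity as sev


@dataclass
class SummaryScores:
    """Per-subject summary of the median-score family and time fractions."""

    subject_id: str
    mbks: float
    active_mbks: float
    mdks: float
    adjusted_mdks: float
    ptd: float
    ptb: float
    ptb_minutes: float
    ptb_category: str
    pct_level: dict[int, float] = field(default_factory=dict)


def _nan_median(values: np.ndarray) -> float:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return float("nan")
    return float(np.percentile(values, 50))


def median_bks(recording: SubjectRecording, masks: EpochMask, config: PipelineConfig = DEFAULT_CONFIG) -> float:
    """Median bradykinesia score: 50th percentile of BKS over worn daytime
    epochs with BKS <= 80, all days pooled."""
    bks = recording.epochs["bks"].to_numpy(dtype=float)
    sample = masks.worn & masks.daytime & (bks <= config.sleep_bks)
    return _nan_median(bks[sample])


def active_median_bks(recording: SubjectRecording, masks: EpochMask, config: PipelineConfig = DEFAULT_CONFIG) -> float:
    """Median BKS with inactivity epochs also removed."""
    bks = recording.epochs["bks"].to_numpy(dtype=float)
    sample = masks.worn & masks.daytime & (bks <= config.sleep_bks) & ~masks.inactive
    return _nan_median(bks[sample])


def median_dks(recording: SubjectRecording, masks: EpochMask, config: PipelineConfig = DEFAULT_CONFIG) -> float:
    """Median dyskinesia score over worn daytime epochs."""
    dks = recording.epochs["dks"].to_numpy(dtype=float)
    return _nan_median(dks[masks.worn & masks.daytime])


def adjusted_median_dks(recording: SubjectRecording, masks: EpochMask, config: PipelineConfig = DEFAULT_CONFIG) -> float:
    """Median DKS after walking exclusion and tremor zeroing.

    Walking epochs are removed from the sample; an epoch with tremor *and*
    DKS >= 10 contributes the value 0 (tremor below the threshold leaves the
    score unchanged)."""
    ep = recording.epochs
    dks = ep["dks"].to_numpy(dtype=float).copy()
    walking = ep["walking"].to_numpy(dtype=bool)
    tremor = ep["tremor"].to_numpy(dtype=bool)
    dks[tremor & (dks >= config.dks_threshold)] = 0.0
    sample = masks.worn & masks.daytime & ~walking
    return _nan_median(dks[sample])


def ptd(recording: SubjectRecording, masks: EpochMask, config: PipelineConfig = DEFAULT_CONFIG) -> float:
    """Percent time in dyskinesia.

    Numerator: daytime worn epochs with DKS >= 10 and neither walking nor
    tremor detected.  Denominator: daytime worn epochs by default
    (``ptd_denominator="worn"``); ``"all"`` counts every daytime epoch
    including not-worn ones."""
    ep = recording.epochs
    dks = ep["dks"].to_numpy(dtype=float)
    walking = ep["walking"].to_numpy(dtype=bool)
    tremor = ep["tremor"].to_numpy(dtype=bool)
    if config.ptd_denominator == "worn":
        denom = masks.worn & masks.daytime
    else:
        denom = masks.daytime
    n_denom = int(denom.sum())
    if n_denom == 0:
        return float("nan")
    numer = denom & masks.worn & (dks >= config.dks_threshold) & ~walking & ~tremor
    return 100.0 * int(numer.sum()) / n_denom


def compute_summary(
    recording: SubjectRecording,
    masks: EpochMask | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> SummaryScores:
    """All summary scores for one recording (masks computed if not given)."""
    if masks is None:
        masks = compute_masks(recording.epochs, config)
    severity = sev.bks_to_severity(recording.epochs["bks"].to_numpy(dtype=float), config)
    available = masks.available_active
    ptb_value = sev.ptb(severity, available, config)
    return SummaryScores(
        subject_id=recording.subject_id,
        mbks=median_bks(recording, masks, config),
        active_mbks=active_median_bks(recording, masks, config),
        mdks=median_dks(recording, masks, config),
        adjusted_mdks=adjusted_median_dks(recording, masks, config),
        ptd=ptd(recording, masks, config),
        ptb=ptb_value,
        ptb_minutes=sev.ptb_to_minutes(ptb_value, config) if not np.isnan(ptb_value) else float("nan"),
        ptb_category=sev.ptb_category(ptb_value, config),
        pct_level=sev.percent_time_per_level(severity, available),
    )
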