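"""End-to-end glue: recording -> summary row with every score and the
fluctuator class."""

from __future__ import annotations

from dataclasses import asdict

import pandas as pd

from .config import PipelineConfig, DEFAULT_CONFIG
from .epoch_io import SubjectRecording
from .masking import compute_masks
from .summary_scores import compute_summary
from .fluctuation import assess_subject

SUMMARY_COLUMNS = [
    "subject_id",
    "mbks",
    "active_mbks",
    "mdks",
    "adjusted_mdks",
    "ptb",
    "ptd",
    "ptb_minutes",
    "ptb_category",
    "pct_level_0",
    "pct_level_1",
    "pct_level_2",
    "pct_level_3",
    "pct_level_4",
    "pct_level_5",
    "first_dose_time",
    "emb_severity",
    "emb_present",
    "pte_time",
    "pte_offset_min",
    "pte_severity",
    "levodopa_response",
    "significant_response",
    "wearing_off",
    "delta2",
    "sd_dose",
    "sd_pte",
    "qc_excluded",
    "fluct_class",
]


def summarize_recording(
    recording: SubjectRecording, config: PipelineConfig = DEFAULT_CONFIG
) -> dict:
    """One flat summary row: median scores, PTB/PTD, response and class."""
    masks = compute_masks(recording.epochs, config)
    scores = compute_summary(recording, masks, config)
    assessment = assess_subject(recording, masks, config)
    row = {
        "subject_id": recording.subject_id,
        "mbks": scores.mbks,
        "active_mbks": scores.active_mbks,
        "mdks": scores.mdks,
        "adjusted_mdks": scores.adjusted_mdks,
        "ptb": scores.ptb,
        "ptd": scores.ptd,
        "ptb_minutes": scores.ptb_minutes,
        "ptb_category": scores.ptb_category,
    }
    for lv in range(6):
        row[f"pct_level_{lv}"] = scores.pct_level.get(lv, float("nan"))
    a = asdict(assessment)
    a.pop("subject_id")
    row.update(a)
    return row


def summarize_cohort(
    recordings: list[SubjectRecording], config: PipelineConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Summary table with one row per subject (header-only when empty)."""
    rows = [summarize_recording(rec, config) for rec in recordings]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
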