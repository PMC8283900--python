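"""Bradykinesia severity levels, percent time in bradykinesia (PTB) and
related conversions.

The continuous severity level is a 0-5.5 scale tied to the MDS-UPDRS III:
the UPDRS-III range is divided into six intervals (levels 0-5, edges at
0, 10, 22.5, 35, 47.5 and 60 points), and a monotone calibration maps the
per-epoch bradykinesia score (BKS) onto this scale.  The half-integer
boundary 2.5 — BKS 26, UPDRS III 35 — separates "in target / controlled"
(levels 0-2) from "above target / uncontrolled" (levels 3-5).  On the
linear part of the scale one severity level spans 12.5 UPDRS-III points,
so the 1.15-level significant levodopa response corresponds to a ~14-point
UPDRS-III reduction.

PTB is the percent of available daytime epochs (worn, awake, active) whose
severity level is 3, 4 or 5; 30% is the upper limit of the control range
(90th percentile of controls) and PTB >= 75% marks predominantly severe,
non-fluctuating bradykinesia.
"""

from __future__ import annotations

import numpy as np

from .config import (
    ConfigurationError,
    PipelineConfig,
    DEFAULT_CONFIG,
    ValidationError,
    UPDRS_LEVEL_EDGES,
    UPDRS_POINTS_PER_LEVEL,
)

# severity -> UPDRS anchor grid: half-integer severity boundaries map onto
# the interval edges (0.5 -> 10, 1.5 -> 22.5, ..., 4.5 -> 60), linear between,
# extended at 12.5 points/level above 4.5.
_SEV_ANCHORS = np.array([0.0, 0.5, 1.5, 2.5, 3.5, 4.5, 5.5])
_UPDRS_ANCHORS = np.array([0.0, 10.0, 22.5, 35.0, 47.5, 60.0, 72.5])

MAX_SEVERITY = 5.5


def _calibration_arrays(config: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    anchors = np.asarray(config.calibration_anchors, dtype=float)
    bks, lev = anchors[:, 0], anchors[:, 1]
    if np.any(np.diff(bks) <= 0) or np.any(np.diff(lev) < 0):
        raise ConfigurationError("calibration anchors must be monotone")
    return bks, lev


def bks_to_severity(bks, config: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray | float:
    """Continuous severity level for bradykinesia score(s).

    Piecewise-linear through the calibration anchors, clipped to
    [0, 5.5]; the fixed point is BKS 26 -> level 2.5.  NaN passes through.
    """
    xs, ys = _calibration_arrays(config)
    out = np.interp(np.asarray(bks, dtype=float), xs, ys)
    out = np.clip(out, 0.0, MAX_SEVERITY)
    if np.isscalar(bks) or np.ndim(bks) == 0:
        return float(out)
    return out


def severity_to_bks(level, config: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray | float:
    """Inverse of :func:`bks_to_severity` (used by the simulator)."""
    xs, ys = _calibration_arrays(config)
    out = np.interp(np.asarray(level, dtype=float), ys, xs)
    if np.isscalar(level) or np.ndim(level) == 0:
        return float(out)
    return out


def severity_to_updrs(level) -> np.ndarray | float:
    """UPDRS-III-equivalent score for continuous severity level(s).

    Level 2.5 -> 35 points; 12.5 points per level on the linear part, so a
    1.15-level change is ~14 UPDRS-III points.
    """
    out = np.interp(np.asarray(level, dtype=float), _SEV_ANCHORS, _UPDRS_ANCHORS)
    if np.isscalar(level) or np.ndim(level) == 0:
        return float(out)
    return out


def severity_to_level(severity) -> np.ndarray | int:
    """Integer severity level 0-5: the UPDRS-equivalent value binned by the
    interval edges, lower-closed ([35, 47.5) -> level 3).  This makes
    "severity >= 2.5" and "level in {3,4,5}" coincide exactly."""
    updrs = np.asarray(severity_to_updrs(severity), dtype=float)
    levels = np.digitize(updrs, UPDRS_LEVEL_EDGES[1:], right=False)
    if np.isscalar(severity) or np.ndim(severity) == 0:
        return int(levels)
    return levels


def ptb(severity: np.ndarray, available: np.ndarray, config: PipelineConfig = DEFAULT_CONFIG) -> float:
    """Percent of available epochs above the bradykinesia target.

    ``available`` should be the active availability mask (worn, daytime,
    not asleep, not inactive).  NaN when no epoch is available.
    """
    sev = np.asarray(severity, dtype=float)[np.asarray(available, dtype=bool)]
    sev = sev[~np.isnan(sev)]
    if sev.size == 0:
        return float("nan")
    return 100.0 * float(np.mean(sev >= config.target_level))


def percent_time_in_level(
    severity: np.ndarray, available: np.ndarray, level: int
) -> float:
    """Percent of available epochs in one integer severity level."""
    sev = np.asarray(severity, dtype=float)[np.asarray(available, dtype=bool)]
    sev = sev[~np.isnan(sev)]
    if sev.size == 0:
        return float("nan")
    levels = severity_to_level(sev)
    return 100.0 * float(np.mean(levels == level))


def percent_time_per_level(severity: np.ndarray, available: np.ndarray) -> dict[int, float]:
    """Percent time in each level 0-5 (partitions 100% over available epochs)."""
    return {lv: percent_time_in_level(severity, available, lv) for lv in range(6)}


def ptb_category(ptb_value: float, config: PipelineConfig = DEFAULT_CONFIG) -> str:
    """PTB severity category: < 30% normal, 30-75% intermediate, >= 75% high."""
    if np.isnan(ptb_value):
        return "not_estimable"
    if ptb_value < config.ptb_normal_limit:
        return "normal"
    if ptb_value < config.ptb_high_limit:
        return "intermediate"
    return "high"


def ptb_to_minutes(ptb_value: float, config: PipelineConfig = DEFAULT_CONFIG) -> float:
    """Nominal minutes above target per 9-hour day.

    ``minutes = max(0, PTB - 30) * 7.714`` — PTB below the 30% control limit
    counts as zero; PTB 100% maps to the full 540-minute day.
    """
    if np.isnan(ptb_value):
        return float("nan")
    if not 0.0 <= ptb_value <= 100.0:
        raise ValidationError(f"ptb must be in [0, 100], got {ptb_value}")
    return max(0.0, ptb_value - config.ptb_normal_limit) * config.minutes_per_ptb_point


def referenced_improvement(before: float, after: float, reference: float = 0.0) -> float:
    """Percent improvement of a score referenced to a normal-range limit.

    ``100 * (before - after) / (before - reference)`` — e.g. a PTB fall from
    63% to 50% is a 20.6% improvement referenced to 0 but a 39% improvement
    referenced to the 30% control limit.
    """
    if before <= reference:
        raise ValidationError(
            f"before ({before}) must exceed the reference ({reference})"
        )
    return 100.0 * (before - after) / (before - reference)
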