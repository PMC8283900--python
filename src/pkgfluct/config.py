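"""Pipeline configuration: every threshold and window in one place.

All defaults correspond to the published PKG (Parkinson's KinetiGraph)
conventions: 2-minute epochs, a 09:00-18:00 daytime window, sleep at
bradykinesia score (BKS) >= 80, inactivity when the 30-min moving-median
BKS exceeds 40, a dyskinesia score (DKS) threshold of 10 for percent time
in dyskinesia, the 2.5 severity-level target boundary, the 1.15-level
significant levodopa response, and the 46-90 min post-dose window for the
time of peak levodopa effect.

The BKS -> severity-level calibration is a user-replaceable monotone anchor
table; only the anchor (bks 26 -> level 2.5) is fixed by the published
target definition, the rest are package defaults placed so that the
published score landmarks (bks 23 ~ onset of elevated percent time in
bradykinesia, bks >= 80 sleep) fall where the severity scale expects them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml


class PkgFluctError(Exception):
    """Base class for package errors."""


class ParseError(PkgFluctError):
    """A file could not be parsed (names the offending line where known)."""


class ValidationError(PkgFluctError):
    """Input data violates an invariant (duplicate timestamps, negative DKS...)."""


class ConfigurationError(PkgFluctError):
    """A configuration value is unusable (even median window, non-monotone calibration...)."""


#: BKS -> continuous severity level anchor table (piecewise linear between).
#: Only (26 -> 2.5) is fixed by the target definition; see module docstring.
DEFAULT_CALIBRATION_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (23.0, 2.26),
    (26.0, 2.5),
    (40.0, 4.0),
    (80.0, 5.5),
)

#: UPDRS-III interval lower edges for integer severity levels 0..5
#: (level 3 is [35, 47.5), level 5 is >= 60).
UPDRS_LEVEL_EDGES: tuple[float, ...] = (0.0, 10.0, 22.5, 35.0, 47.5, 60.0)

#: UPDRS-III points per unit severity level on the linear part of the scale.
UPDRS_POINTS_PER_LEVEL: float = 12.5


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds, windows and rules of the pipeline.

    Times of day are "HH:MM" strings (wall-clock; the daytime window and dose
    anchors are defined on local clock time, no timezone arithmetic).
    """

    # --- epoch grid ---
    epoch_minutes: int = 2

    # --- masking ---
    sleep_bks: float = 80.0            # epoch is sleep iff bks >= this
    inactivity_window_epochs: int = 15  # 30 min at 2-min epochs
    inactivity_threshold: float = 40.0  # inactive iff moving-median bks > this (strict)
    day_start: str = "09:00"
    day_end: str = "18:00"             # half-open [day_start, day_end)

    # --- summary scores ---
    dks_threshold: float = 10.0        # PTD numerator: dks >= this
    ptd_denominator: str = "worn"      # "worn": daytime worn epochs; "all": all daytime epochs

    # --- severity / PTB ---
    calibration_anchors: tuple[tuple[float, float], ...] = DEFAULT_CALIBRATION_ANCHORS
    target_level: float = 2.5          # in-target iff severity < this
    ptb_normal_limit: float = 30.0     # % ; upper limit of the control range
    ptb_high_limit: float = 75.0       # % ; boundary of the "high" PTB category
    ptd_normal_limit: float = 20.0     # %
    minutes_per_ptb_point: float = 7.714  # minutes above target per PTB point over 30%

    # --- levodopa response / fluctuation ---
    first_dose_earliest: str = "05:00"   # first reminder at-or-after this clock time
    emb_window_epochs: int = 5           # 10 min centred on the first dose time
    emb_min_available_frac: float = 0.5  # estimable iff available slots >= this fraction
    pte_min_offset_min: int = 46         # peak-effect search window, minutes post dose
    pte_max_offset_min: int = 90
    smoothing_window_epochs: int = 15    # smoothing window for the response curve
    pte_smoothing: str = "mean"          # response-curve kernel: "mean" or "median"
    min_days_per_offset: int = 3         # pooled-offset floor (capped at the day count)
    significant_response: float = 1.15   # levodopa response significant iff >= this
    wearing_off_delta: float = 1.0       # wearing-off iff rise >= this within the window
    wearing_off_window_min: int = 120    # minutes after peak effect searched for the rise
    excess_variability_sd: float = 1.0   # QC: sd of severity at the anchor times
    variability_rule: str = "and"        # "and": both sds must exceed; "or": either

    def __post_init__(self) -> None:
        if self.inactivity_window_epochs % 2 == 0 or self.inactivity_window_epochs < 3:
            raise ConfigurationError(
                f"inactivity_window_epochs must be odd and >= 3, got {self.inactivity_window_epochs}"
            )
        if self.smoothing_window_epochs % 2 == 0 or self.smoothing_window_epochs < 3:
            raise ConfigurationError(
                f"smoothing_window_epochs must be odd and >= 3, got {self.smoothing_window_epochs}"
            )
        if self.pte_smoothing not in ("mean", "median"):
            raise ConfigurationError(f"pte_smoothing must be 'mean' or 'median', got {self.pte_smoothing!r}")
        if self.ptd_denominator not in ("worn", "all"):
            raise ConfigurationError(f"ptd_denominator must be 'worn' or 'all', got {self.ptd_denominator!r}")
        if self.variability_rule not in ("and", "or"):
            raise ConfigurationError(f"variability_rule must be 'and' or 'or', got {self.variability_rule!r}")
        anchors = tuple((float(b), float(s)) for b, s in self.calibration_anchors)
        bks = [b for b, _ in anchors]
        lev = [s for _, s in anchors]
        if sorted(bks) != bks or len(set(bks)) != len(bks) or sorted(lev) != lev:
            raise ConfigurationError("calibration_anchors must be strictly increasing in bks and non-decreasing in level")
        object.__setattr__(self, "calibration_anchors", anchors)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    # --- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["calibration_anchors"] = [list(a) for a in self.calibration_anchors]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "calibration_anchors" in data:
            data["calibration_anchors"] = tuple(tuple(a) for a in data["calibration_anchors"])
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def parse_clock(value: str) -> int:
    """Parse 'HH:MM' into minutes after midnight."""
    try:
        hh, mm = value.split(":")
        minutes = int(hh) * 60 + int(mm)
    except (ValueError, AttributeError) as exc:
        raise ConfigurationError(f"bad clock time {value!r}; expected 'HH:MM'") from exc
    if not 0 <= minutes < 24 * 60:
        raise ConfigurationError(f"clock time {value!r} out of range")
    return minutes


DEFAULT_CONFIG = PipelineConfig()
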