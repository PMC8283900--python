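"""Epoch masks: not-worn, sleep, inactivity and the daytime window.

Every summary score is computed over "available" epochs only, where
availability is the conjunction of the masks relevant to that score:

* worn — the logger's own wear flag;
* sleep — bradykinesia score >= 80 (sustained immobility, usually sleep);
* inactive — the 30-minute centred moving-median bradykinesia score is
  strictly greater than 40 (too little movement for bradykinesia to be
  clinically assessable);
* daytime — clock time in the half-open window [09:00, 18:00), i.e. exactly
  270 two-minute epochs per full day.

The moving median is centred and unweighted over 15 epochs by default; at
recording edges the window truncates, and absent epochs (grid gaps) are
skipped rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, PipelineConfig, DEFAULT_CONFIG, parse_clock


@dataclass(frozen=True)
class EpochMask:
    """Per-epoch boolean masks aligned to the rows of a recording's epochs.

    ``available`` (worn, daytime, not asleep) is the denominator for the
    median dyskinesia scores; ``available_active`` additionally removes
    inactivity and is the denominator for percent time in bradykinesia and
    the active median bradykinesia score.
    """

    worn: np.ndarray
    sleep: np.ndarray
    inactive: np.ndarray
    daytime: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.worn)
        for name in ("sleep", "inactive", "daytime"):
            if len(getattr(self, name)) != n:
                raise ConfigurationError("mask arrays must have one entry per epoch")

    @property
    def available(self) -> np.ndarray:
        return self.worn & self.daytime & ~self.sleep

    @property
    def available_active(self) -> np.ndarray:
        return self.available & ~self.inactive

    @property
    def awake_worn(self) -> np.ndarray:
        """Worn, awake, active epochs without the daytime restriction —
        availability for the early-morning / peak-effect windows."""
        return self.worn & ~self.sleep & ~self.inactive


def moving_median(values, window_epochs: int) -> np.ndarray:
    """Centred moving median with truncated windows at the edges.

    NaN entries (absent or not-worn epochs) are skipped, not imputed: the
    median at epoch i is taken over the present values in the centred window.
    Windows containing no present value yield NaN.
    """
    if window_epochs % 2 == 0 or window_epochs < 3:
        raise ConfigurationError(f"moving-median window must be odd and >= 3, got {window_epochs}")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window_epochs, center=True, min_periods=1).median().to_numpy()


def moving_median_on_grid(timestamps, values, window_epochs: int, epoch_minutes: int = 2) -> np.ndarray:
    """Moving median respecting the nominal epoch grid.

    The series is laid out on the full ``epoch_minutes`` grid spanning the
    recording so that a 15-epoch window is always 30 minutes of wall-clock
    time; grid positions with no epoch contribute nothing to the median.
    Returns the smoothed values at the original (present) epochs.
    """
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps))
    s = pd.Series(np.asarray(values, dtype=float), index=ts)
    grid = pd.date_range(ts[0], ts[-1], freq=f"{epoch_minutes}min")
    full = grid.union(ts)
    smoothed = (
        s.reindex(full)
        .rolling(window_epochs, center=True, min_periods=1)
        .median()
    )
    return smoothed.reindex(ts).to_numpy()


def detect_sleep(epochs: pd.DataFrame, config: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Sleep mask: bradykinesia score >= 80 (boundary included)."""
    return epochs["bks"].to_numpy(dtype=float) >= config.sleep_bks


def detect_inactivity(epochs: pd.DataFrame, config: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Inactivity mask: 30-min moving-median BKS strictly greater than 40.

    Not-worn epochs carry no usable score and are excluded from the median
    (treated as absent); they are reported as not-inactive here and removed
    by the worn mask instead.
    """
    bks = epochs["bks"].to_numpy(dtype=float).copy()
    worn = epochs["worn"].to_numpy(dtype=bool)
    bks[~worn] = np.nan
    med = moving_median_on_grid(
        epochs["timestamp"], bks, config.inactivity_window_epochs, config.epoch_minutes
    )
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(med, nan=-np.inf) > config.inactivity_threshold


def daytime_mask(epochs: pd.DataFrame, config: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Daytime mask: clock time in [day_start, day_end), half-open."""
    ts = pd.to_datetime(epochs["timestamp"])
    minutes = ts.dt.hour.to_numpy() * 60 + ts.dt.minute.to_numpy()
    start = parse_clock(config.day_start)
    end = parse_clock(config.day_end)
    return (minutes >= start) & (minutes < end)


def compute_masks(epochs: pd.DataFrame, config: PipelineConfig = DEFAULT_CONFIG) -> EpochMask:
    """All masks for a recording's epochs frame."""
    return EpochMask(
        worn=epochs["worn"].to_numpy(dtype=bool),
        sleep=detect_sleep(epochs, config),
        inactive=detect_inactivity(epochs, config),
        daytime=daytime_mask(epochs, config),
    )
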