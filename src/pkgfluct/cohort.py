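"""Cohort-level arithmetic: treatment-change tables, transition tables and
statistical helpers.

The treatment-change summary mirrors the usual before/after layout:
Δ% = 100·(before − after)/before, a standardized effect size, and a
Welch t-test p-value per measure.  The effect-size formula is selectable
("pooled" — sqrt of the mean of the two variances — by default, with
baseline-SD and paired alternatives), since published before/after tables
rarely state which convention they used.

The classification transition table cross-tabulates fluctuator classes
before and after an intervention over the full 8-value class set and
reports the proportion unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ValidationError
from .fluctuation import ALL_CLASSES


@dataclass(frozen=True)
class PairedCohort:
    """Per-subject before/after values of one named measure."""

    measure: str
    before: np.ndarray
    after: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.before, dtype=float)
        a = np.asarray(self.after, dtype=float)
        if b.shape != a.shape or b.ndim != 1:
            raise ValidationError("before/after must be 1-D arrays of equal length")
        if b.size < 2:
            raise ValidationError("need at least 2 paired subjects")
        object.__setattr__(self, "before", b)
        object.__setattr__(self, "after", a)

    @property
    def n(self) -> int:
        return int(self.before.size)


def delta_percent(before_mean: float, after_mean: float) -> float:
    """Percent change of a score following treatment: 100·(before−after)/before.

    NaN when the before-treatment mean is zero (the change is undefined as a
    percentage of a zero baseline)."""
    if before_mean == 0:
        return float("nan")
    return 100.0 * (before_mean - after_mean) / before_mean


def effect_size(
    before_mean: float,
    before_sd: float,
    after_mean: float,
    after_sd: float,
    formula: str = "pooled",
    correlation: float = 0.0,
) -> float:
    """Standardized mean difference between before and after.

    * ``pooled`` — (before−after)/sqrt((sd₁²+sd₂²)/2);
    * ``baseline`` — standardized by the before-treatment SD alone;
    * ``paired`` — standardized by the SD of the change score implied by the
      two SDs and a correlation (sqrt(sd₁²+sd₂²−2ρ·sd₁·sd₂)).
    """
    diff = before_mean - after_mean
    if formula == "pooled":
        denom = np.sqrt((before_sd**2 + after_sd**2) / 2.0)
    elif formula == "baseline":
        denom = before_sd
    elif formula == "paired":
        denom = np.sqrt(before_sd**2 + after_sd**2 - 2.0 * correlation * before_sd * after_sd)
    else:
        raise ValidationError(f"unknown effect-size formula {formula!r}")
    if denom == 0:
        return float("nan") if diff == 0 else float("inf") * np.sign(diff)
    return float(diff / denom)


def welch_t(before, after) -> tuple[float, float]:
    """Welch's two-sample t-test (unequal variances); returns (t, two-sided p)."""
    res = stats.ttest_ind(np.asarray(before, float), np.asarray(after, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided)."""
    res = stats.mannwhitneyu(np.asarray(x, float), np.asarray(y, float), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def chi_square(table) -> tuple[float, float]:
    """Chi-square test of independence on a contingency table."""
    res = stats.chi2_contingency(np.asarray(table, float))
    return float(res.statistic), float(res.pvalue)


def anova_sidak(*groups) -> dict:
    """One-way ANOVA with Šídák-adjusted pairwise Welch comparisons.

    Returns the omnibus F and p plus a list of pairwise entries
    (i, j, t, p_raw, p_sidak) with p_sidak = 1 − (1 − p)^m over the m pairs.
    """
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("need at least two groups")
    f_stat, p_omni = stats.f_oneway(*arrays)
    pairs = []
    m = len(arrays) * (len(arrays) - 1) // 2
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            t, p = welch_t(arrays[i], arrays[j])
            pairs.append(
                {"i": i, "j": j, "t": t, "p_raw": p, "p_sidak": float(1.0 - (1.0 - p) ** m)}
            )
    return {"F": float(f_stat), "p": float(p_omni), "pairwise": pairs}


def pearson_ci(x, y, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Pearson correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r = float(stats.pearsonr(x, y).statistic)
    n = x.size
    if n <= 3 or abs(r) >= 1.0:
        return r, (float("nan"), float("nan"))
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + confidence / 2.0) / np.sqrt(n - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


@dataclass(frozen=True)
class TransitionTable:
    """Cross-tab of fluctuator classes before vs after an intervention."""

    counts: pd.DataFrame  # rows = class before, columns = class after
    n: int
    percent_unchanged: float


def transition_table(classes_before, classes_after) -> TransitionTable:
    """Full class-transition cross-tab with marginal consistency.

    Row sums equal the before-class counts; the diagonal fraction is the
    percent of subjects whose class did not change.
    """
    before = pd.Categorical(list(classes_before), categories=ALL_CLASSES)
    after = pd.Categorical(list(classes_after), categories=ALL_CLASSES)
    if len(before) != len(after):
        raise ValidationError("before/after class vectors must have equal length")
    counts = pd.crosstab(
        pd.Series(before, name="before"), pd.Series(after, name="after"), dropna=False
    ).reindex(index=ALL_CLASSES, columns=ALL_CLASSES, fill_value=0)
    n = len(before)
    unchanged = int(np.trace(counts.to_numpy())) if n else 0
    pct = 100.0 * unchanged / n if n else float("nan")
    return TransitionTable(counts=counts, n=n, percent_unchanged=pct)


def treatment_change_table(cohorts: list[PairedCohort], formula: str = "pooled") -> pd.DataFrame:
    """Before/after summary per measure: means, SDs, Δ%, effect size, Welch p."""
    rows = []
    for c in cohorts:
        bm, am = float(np.mean(c.before)), float(np.mean(c.after))
        bs, as_ = float(np.std(c.before, ddof=1)), float(np.std(c.after, ddof=1))
        _, p = welch_t(c.before, c.after)
        rows.append(
            {
                "measure": c.measure,
                "n": c.n,
                "before_mean": bm,
                "before_sd": bs,
                "after_mean": am,
                "after_sd": as_,
                "delta_pct": delta_percent(bm, am),
                "effect_size": effect_size(bm, bs, am, as_, formula=formula),
                "p_welch": p,
            }
        )
    return pd.DataFrame(rows)
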