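"""Tumor volumes, ΔT/C antitumor-activity statistics, and group tests.

Tumor volume follows the caliper formula ``TV = 0.5 * length * width**2``
(mm³).  Antitumor activity on day t is

    ΔT/C = (T_t - T_1) / (C_t - C_1) * 100

with T and C the mean treated and control volumes; when the treated mean
falls below its day-1 value the regression branch

    ΔT/C = (T_t - T_1) / T_1 * 100

applies instead (negative by construction).  Lower ΔT/C means stronger
antitumor activity.  ΔT/C is computed on arm means per day; a per-animal
variant is available for uncertainty estimates.

Two-group comparisons use the Welch t test (unequal variances,
Welch–Satterthwaite degrees of freedom); families of per-model tests are
Benjamini–Hochberg adjusted.

Animals are censored at the humane endpoint (2,000 mm³ by default): once an
animal's volume exceeds the limit its later measurements are dropped and
arm means use the animals still on study, with the per-day count retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .markers import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "EfficacyResult",
    "GroupComparison",
    "tumor_volume",
    "arm_day_means",
    "delta_t_c",
    "delta_t_c_table",
    "welch_t",
    "compare_high_low",
    "score_change_tests",
]

HUMANE_ENDPOINT_MM3 = 2000.0


@dataclass(frozen=True)
class EfficacyResult:
    """ΔT/C (percent) for one treated arm at one day, with provenance."""

    delta_t_c: float
    branch_used: str  # "ratio" or "regression"
    day: int
    treated_day: float
    treated_day1: float
    control_day: float | None
    control_day1: float | None
    model: str | None = None
    arm: str | None = None


@dataclass(frozen=True)
class GroupComparison:
    """A Welch t test between two groups."""

    statistic_name: str
    group_labels: tuple[str, str]
    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float
    adj_p: float | None = None


def tumor_volume(length_mm, width_mm) -> float | np.ndarray:
    """Caliper tumor volume, 0.5 * length * width² (mm³).

    Length is expected to be the longer axis; if width exceeds length the
    two are swapped with a warning, so the squared term is always the
    shorter axis.
    """
    length = np.asarray(length_mm, dtype=float)
    width = np.asarray(width_mm, dtype=float)
    if (length <= 0).any() or (width <= 0).any():
        raise ValueError("tumor dimensions must be positive")
    swapped = width > length
    if swapped.any():
        log.warning(
            "%d measurement(s) with width > length: axes swapped", int(swapped.sum())
        )
        length, width = np.where(swapped, width, length), np.where(
            swapped, length, width
        )
    out = 0.5 * length * width**2
    return float(out) if out.ndim == 0 else out


def arm_day_means(
    growth: pd.DataFrame, censor_at: float | None = HUMANE_ENDPOINT_MM3
) -> pd.DataFrame:
    """Mean volume per (model, arm, day), censoring at the humane endpoint.

    After an animal's volume first exceeds ``censor_at``, its subsequent
    measurements are excluded; means use the animals still on study.
    Returns columns model, arm, day, mean_volume, n_animals.
    """
    df = growth.copy()
    if censor_at is not None:
        df = df.sort_values(["model", "arm", "animal", "day"])
        exceeded = df["volume_mm3"] > censor_at
        # a measurement is kept until strictly after the first exceedance
        prior_exceed = (
            exceeded.groupby(
                [df["model"], df["arm"], df["animal"]], observed=True
            ).cumsum()
            - exceeded.astype(int)
        )
        dropped = prior_exceed > 0
        if dropped.any():
            log.info(
                "%d measurement(s) dropped after the humane endpoint",
                int(dropped.sum()),
            )
        df = df[~dropped]
    out = (
        df.groupby(["model", "arm", "day"], observed=True)["volume_mm3"]
        .agg(mean_volume="mean", n_animals="size")
        .reset_index()
    )
    return out


def delta_t_c(
    treated_means_by_day: Mapping[int, float] | pd.Series,
    control_means_by_day: Mapping[int, float] | pd.Series,
    day: int,
    model: str | None = None,
    arm: str | None = None,
) -> EfficacyResult:
    """ΔT/C at ``day``, choosing the ratio or regression branch.

    The regression branch triggers when the treated mean at ``day`` is
    strictly below the treated mean at day 1; the ratio branch requires a
    nonzero control volume change.
    """
    treated = pd.Series(dict(treated_means_by_day))
    control = pd.Series(dict(control_means_by_day))
    for series, label in ((treated, "treated"), (control, "control")):
        if 1 not in series.index or day not in series.index:
            raise KeyError(f"{label} series must contain day 1 and day {day}")
    t1, tt = float(treated[1]), float(treated[day])
    c1, ct = float(control[1]), float(control[day])
    if tt < t1:
        value = (tt - t1) / t1 * 100.0
        return EfficacyResult(value, "regression", day, tt, t1, ct, c1, model, arm)
    dc = ct - c1
    if dc == 0:
        raise ZeroDivisionError(
            "control volume change is zero on the ratio branch; ΔT/C undefined"
        )
    value = (tt - t1) / dc * 100.0
    return EfficacyResult(value, "ratio", day, tt, t1, ct, c1, model, arm)


def delta_t_c_table(
    growth: pd.DataFrame,
    day: int,
    arms: tuple[str, ...] | None = None,
    control_arm: str = "NT",
    censor_at: float | None = HUMANE_ENDPOINT_MM3,
) -> pd.DataFrame:
    """ΔT/C per (model, treated arm) at ``day`` from a long growth table."""
    means = arm_day_means(growth, censor_at=censor_at)
    if arms is None:
        arms = tuple(a for a in means["arm"].unique() if a != control_arm)
    rows = []
    for model, sub in means.groupby("model", observed=True, sort=False):
        by_arm = {
            a: g.set_index("day")["mean_volume"] for a, g in sub.groupby("arm")
        }
        if control_arm not in by_arm:
            log.warning("model %s lacks control arm %s; skipped", model, control_arm)
            continue
        for arm in arms:
            if arm not in by_arm:
                log.warning("model %s lacks arm %s; skipped", model, arm)
                continue
            res = delta_t_c(by_arm[arm], by_arm[control_arm], day, model, arm)
            rows.append(
                (model, arm, day, res.delta_t_c, res.branch_used)
            )
    return pd.DataFrame(
        rows, columns=["model", "arm", "day", "delta_t_c", "branch_used"]
    )


def welch_t(x, y, labels: tuple[str, str] = ("x", "y")) -> GroupComparison:
    """Two-sided Welch t test (unequal variances).

    Degenerate input where both groups have zero variance and equal means
    is reported as t = 0, p = 1 (logged) rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            log.info("both groups constant and equal: t=0, p=1 by convention")
            return GroupComparison(
                "Welch t", labels, 0.0, float(len(x) + len(y) - 2), 1.0,
                float(x.mean()), float(y.mean()),
            )
        raise ValueError("both groups have zero variance with different means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return GroupComparison(
        "Welch t",
        labels,
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
        float(x.mean()),
        float(y.mean()),
    )


def compare_high_low(
    delta_t_c_by_model: pd.Series, high_labels: pd.Series
) -> GroupComparison:
    """Welch t on per-model ΔT/C, high vs low group.

    A lower mean ΔT/C in the high group means stronger antitumor activity
    in high-MVD models.
    """
    high_labels = high_labels.reindex(delta_t_c_by_model.index)
    if high_labels.isna().any():
        raise ValueError("every model needs a high/low label")
    hi = delta_t_c_by_model[high_labels.astype(bool)]
    lo = delta_t_c_by_model[~high_labels.astype(bool)]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError(
            "each group needs >= 2 models; choose a different high/low threshold"
        )
    return welch_t(hi, lo, labels=("high", "low"))


def score_change_tests(
    scores_nt: Mapping[str, np.ndarray],
    scores_treated: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Per-model Welch t of a signature score, untreated vs treated, with BH.

    Models missing either arm (or with fewer than 2 samples in one) are
    skipped with a warning.  Returns columns model, t, df, p, adj_p,
    direction ('decrease' when the treated mean is lower).
    """
    rows, skipped = [], []
    for model in scores_nt:
        nt = np.asarray(scores_nt[model], dtype=float)
        if model not in scores_treated:
            skipped.append(model)
            continue
        tr = np.asarray(scores_treated[model], dtype=float)
        if len(nt) < 2 or len(tr) < 2:
            skipped.append(model)
            continue
        cmp = welch_t(nt, tr, labels=("NT", "treated"))
        direction = "decrease" if cmp.mean_y < cmp.mean_x else "increase"
        rows.append((model, cmp.t, cmp.df, cmp.p, direction))
    if skipped:
        log.warning("model(s) skipped (missing arm or n<2): %s", skipped)
    table = pd.DataFrame(rows, columns=["model", "t", "df", "p", "direction"])
    table["adj_p"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table[["model", "t", "df", "p", "adj_p", "direction"]]
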