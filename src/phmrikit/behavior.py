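"""Behavioral statistics: open-field ANOVA, novel-object recognition, tail flick.

Open-field measures (distance travelled, wall/corner/center time) and
tail-flick latencies are compared across dose groups with a one-way ANOVA
(Tukey HSD post hocs by default, Fisher LSD on request).  Novel-object
memory is summarised by the investigation ratio IR = novel / (novel +
familiar), tested against chance (0.5) with a one-sample two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lipidomics import dose_anova_lsd

__all__ = [
    "one_way_anova",
    "posthoc_pairwise",
    "investigation_ratio",
    "ir_vs_chance",
    "analyze_measure",
    "validate_behavior_table",
]

MEASURES = (
    "distance",
    "wall_time",
    "corner_time",
    "center_time",
    "ir",
    "tail_flick_latency",
)


def validate_behavior_table(table: pd.DataFrame, session_seconds: float | None = None) -> pd.DataFrame:
    """Validate a long-format behavior table (subject_id, group, measure, value)."""
    required = {"subject_id", "group", "measure", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    unknown = set(table["measure"]) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    times = table[table["measure"].isin(("wall_time", "corner_time", "center_time"))]
    if (times["value"] < 0).any():
        raise ValueError("time measures must be >= 0")
    if session_seconds is not None and (times["value"] > session_seconds).any():
        raise ValueError(f"time measures exceed the session length {session_seconds} s")
    ir = table.loc[table["measure"] == "ir", "value"]
    if ((ir < 0) | (ir > 1)).any():
        raise ValueError("investigation ratios must lie in [0, 1]")
    return table


def one_way_anova(values_by_group: dict[str, np.ndarray]) -> dict:
    """Classical one-way ANOVA: F with (k-1, n-k) df and its p-value.

    Zero within-group variance gives F = 0 / p = 1 when the group means are
    equal and F = inf / p = 0 otherwise.
    """
    result = dose_anova_lsd(values_by_group, alpha=0.0)  # alpha 0: no post hocs
    return {"F": result["F"], "df": result["df"], "p_value": result["p_value"]}


def posthoc_pairwise(
    values_by_group: dict[str, np.ndarray], method: str = "tukey"
) -> dict:
    """Pairwise group comparisons after an omnibus ANOVA.

    ``method`` is "tukey" (default, studentized-range family correction) or
    "lsd" (unadjusted pooled-MSE t-tests).
    """
    labels = list(values_by_group)
    groups = [np.asarray(values_by_group[g], dtype=float).ravel() for g in labels]
    if method == "tukey":
        res = stats.tukey_hsd(*groups)
        return {
            (labels[i], labels[j]): {"p_value": float(res.pvalue[i, j])}
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        }
    if method == "lsd":
        full = dose_anova_lsd(values_by_group, alpha=1.0)
        return full["pairwise"]
    raise ValueError("method must be 'tukey' or 'lsd'")


def investigation_ratio(novel_seconds: float, familiar_seconds: float) -> float:
    """IR = time investigating the novel object / time investigating both.

    A subject with zero total investigation time has no defined IR and is
    flagged by raising; callers exclude and log such subjects.
    """
    if novel_seconds < 0 or familiar_seconds < 0:
        raise ValueError("investigation times must be >= 0")
    total = novel_seconds + familiar_seconds
    if total == 0:
        raise ValueError("undefined IR: subject never investigated either object")
    return novel_seconds / total


def ir_vs_chance(ratios: np.ndarray) -> tuple[float, float]:
    """One-sample two-tailed t-test of investigation ratios against 0.5.

    Zero-variance inputs use the exact convention: all ratios equal to 0.5
    give t = 0 / p = 1, all equal to another value give p = 0.
    """
    x = np.asarray(ratios, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need >= 2 ratios")
    if x.var(ddof=1) == 0:
        if np.isclose(x.mean(), 0.5):
            return 0.0, 1.0
        return float(np.sign(x.mean() - 0.5) * np.inf), 0.0
    t, p = stats.ttest_1samp(x, 0.5)
    return float(t), float(p)


@dataclass
class MeasureResult:
    measure: str
    anova: dict
    pairwise: dict


def analyze_measure(
    table: pd.DataFrame, measure: str, posthoc: str = "tukey"
) -> MeasureResult:
    """ANOVA + post hocs for one measure of a validated behavior table."""
    sub = table[table["measure"] == measure]
    if sub.empty:
        raise ValueError(f"no records for measure {measure!r}")
    grouped = {g: blk["value"].to_numpy() for g, blk in sub.groupby("group", sort=False)}
    anova = one_way_anova(grouped)
    pairs = posthoc_pairwise(grouped, posthoc) if anova["p_value"] < 0.05 else {}
    return MeasureResult(measure, anova, pairs)
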