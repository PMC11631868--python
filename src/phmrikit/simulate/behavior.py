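"""Behavioral measure table generator (open field, novel object, tail flick)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..behavior import MEASURES, validate_behavior_table

__all__ = ["generate_behavior_table", "DEFAULT_MEANS", "DEFAULT_SDS"]

#: per-measure baseline means for a 600 s open-field session / 10 s tail flick
DEFAULT_MEANS = {
    "distance": 20.0,  # metres travelled
    "wall_time": 300.0,  # seconds along the walls
    "corner_time": 150.0,  # seconds in the corners
    "center_time": 5.0,  # seconds crossing the centre
    "ir": 0.55,  # novel-object investigation ratio
    "tail_flick_latency": 8.0,  # seconds to withdraw
}

DEFAULT_SDS = {
    "distance": 4.0,
    "wall_time": 60.0,
    "corner_time": 50.0,
    "center_time": 3.0,
    "ir": 0.1,
    "tail_flick_latency": 1.5,
}

_BOUNDS = {
    "distance": (0.0, np.inf),
    "wall_time": (0.0, 600.0),
    "corner_time": (0.0, 600.0),
    "center_time": (0.0, 600.0),
    "ir": (0.0, 1.0),
    "tail_flick_latency": (0.0, 10.0),
}


def generate_behavior_table(
    groups: dict[str, int],
    effect_pattern: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    sds: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normal per-group draws of every behavioral measure plus ground truth.

    ``groups`` maps group label -> subject count; ``effect_pattern`` maps
    measure -> {group: mean} overriding the baseline means.  Standard
    deviations default to measure-typical values and are never zero unless
    explicitly requested via ``sds``.  Values are clipped to their physical
    bounds (session length, the 10 s tail-flick ceiling, IR in [0, 1]).
    Deterministic given ``seed``.
    """
    if any(n < 2 for n in groups.values()):
        raise ValueError("each group needs >= 2 subjects")
    effect_pattern = effect_pattern or {}
    unknown = set(effect_pattern) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures in effect pattern: {sorted(unknown)}")
    sds = {**DEFAULT_SDS, **(sds or {})}
    rng = np.random.default_rng(seed)
    records = []
    truth_rows = []
    for group, n in groups.items():
        for measure in MEASURES:
            mean = effect_pattern.get(measure, {}).get(group, DEFAULT_MEANS[measure])
            lo, hi = _BOUNDS[measure]
            values = np.clip(rng.normal(mean, sds[measure], n), lo, hi)
            truth_rows.append({"group": group, "measure": measure, "true_mean": mean, "sd": sds[measure]})
            for i in range(n):
                records.append(
                    {
                        "subject_id": f"{group}_{i + 1:02d}",
                        "group": group,
                        "measure": measure,
                        "value": float(values[i]),
                    }
                )
    table = pd.DataFrame(records)
    validate_behavior_table(table)
    return table, pd.DataFrame(truth_rows)
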