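"""Lipid concentration table generator: fold changes, censoring, outliers.

Concentrations are log-normal around the specified group means with a given
coefficient of variation, so cv = 0 reproduces the means exactly.  Records
can be left-censored (below the detection limit) with a given probability,
and gross outliers can be injected several true SDs above the group mean.
The true fold change per lipid x compartment is returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..lipidomics import COMPARTMENTS, validate_lipid_table

__all__ = ["LipidEffectSpec", "generate_lipid_table"]

#: injected outliers sit this many true SDs above the group mean
OUTLIER_SHIFT_SD = 4.0


@dataclass
class LipidEffectSpec:
    """Ground-truth generating model for one lipid in one compartment."""

    lipid: str
    compartment: str
    group_means: dict[str, float] = field(default_factory=dict)
    cv: float = 0.3
    p_below_detection: float = 0.0
    outlier_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if any(m < 0 for m in self.group_means.values()):
            raise ValueError("group means must be >= 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        for name, p in (("p_below_detection", self.p_below_detection), ("outlier_rate", self.outlier_rate)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if mean == 0 or cv == 0:
        return np.full(size, float(mean))
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def generate_lipid_table(
    specs: list[LipidEffectSpec],
    n_per_group: int = 5,
    seed: int = 0,
    detection_limit: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long-format lipid table plus its ground truth.

    Ground truth records, per lipid x compartment, the true group means and
    the true fold change of each non-reference group against the first
    group listed in ``group_means`` (by convention the vehicle group).
    Deterministic given ``seed``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    records = []
    truth_rows = []
    for spec in specs:
        groups = list(spec.group_means)
        ref = groups[0]
        for group in groups:
            mean = spec.group_means[group]
            values = _lognormal(rng, mean, spec.cv, n_per_group)
            censored = rng.random(n_per_group) < spec.p_below_detection
            true_sd = mean * spec.cv
            outliers = rng.random(n_per_group) < spec.outlier_rate
            values = np.where(outliers, mean + OUTLIER_SHIFT_SD * max(true_sd, mean * 0.5), values)
            values = np.where(censored | (values < detection_limit), 0.0, values)
            detected = values > detection_limit if detection_limit > 0 else values > 0
            for i in range(n_per_group):
                records.append(
                    {
                        "subject_id": f"{group}_{i + 1:02d}",
                        "group": group,
                        "compartment": spec.compartment,
                        "lipid": spec.lipid,
                        "concentration": float(values[i]),
                        "detected": bool(detected[i]),
                    }
                )
            if group != ref:
                ref_mean = spec.group_means[ref]
                fold = np.nan
                if mean > 0 and ref_mean > 0:
                    fold = max(mean, ref_mean) / min(mean, ref_mean)
                truth_rows.append(
                    {
                        "lipid": spec.lipid,
                        "compartment": spec.compartment,
                        "group": group,
                        "reference": ref,
                        "true_mean": mean,
                        "reference_mean": ref_mean,
                        "true_fold": fold,
                        "direction": "increase" if mean >= ref_mean else "decrease",
                    }
                )
    table = pd.DataFrame(records)
    validate_lipid_table(table)
    return table, pd.DataFrame(truth_rows)
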