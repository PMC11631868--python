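"""Dose-design BOLD generator with injected regional percent-change effects.

The design mirrors a typical awake-rodent pharmacological MRI session: 250
acquisitions at TR = 6 s (25 min), a pre-injection baseline window at
acquisitions 5-45 and a drug-response window at 150-200, with 4 dose groups.
Effects are injected as a step of the specified signed percent change over
the response window, carried by a configurable fraction of each region's
voxels (the responders), on a constant baseline of 100 arbitrary units with
i.i.d. Gaussian acquisition noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..types import AtlasLabels, Bold4D, Window, validate_windows, window_slice

__all__ = ["BoldDesign", "RegionEffectSpec", "generate_bold", "DEFAULT_GROUPS"]

BASELINE_LEVEL = 100.0

#: study-style 4-group dose design (label, dose mg/kg, subjects per group)
DEFAULT_GROUPS: tuple[tuple[str, float, int], ...] = (
    ("vehicle", 0.0, 4),
    ("3mg", 3.0, 4),
    ("10mg", 10.0, 6),
    ("30mg", 30.0, 5),
)


@dataclass
class BoldDesign:
    """Acquisition design for one synthetic imaging session."""

    n_acquisitions: int = 250
    tr: float = 6.0
    baseline_window: Window = (5, 45)
    response_window: Window = (150, 200)
    groups: tuple[tuple[str, float, int], ...] = DEFAULT_GROUPS
    seed: int = 0

    def __post_init__(self) -> None:
        validate_windows(self.baseline_window, self.response_window, self.n_acquisitions)
        if not self.groups:
            raise ValueError("design needs at least one group")
        for label, dose, n in self.groups:
            if n < 2:
                raise ValueError(f"group {label!r} needs n >= 2 subjects (got {n})")
            if dose < 0:
                raise ValueError(f"group {label!r} has negative dose")

    @property
    def duration_seconds(self) -> float:
        return self.n_acquisitions * self.tr

    @property
    def group_labels(self) -> list[str]:
        return [g[0] for g in self.groups]


@dataclass
class RegionEffectSpec:
    """Injected effect for one atlas region.

    ``percent_change`` maps group label -> signed percent change (negative =
    deactivation); ``responder_fraction`` is the fraction of region voxels
    carrying the effect; ``noise_sd`` is the acquisition noise SD in percent
    of the baseline level.
    """

    region_id: int
    percent_change: dict[str, float] = field(default_factory=dict)
    responder_fraction: float = 1.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_bold(
    design: BoldDesign,
    atlas: AtlasLabels,
    effects: list[RegionEffectSpec],
    global_noise_sd: float = 0.5,
) -> tuple[list[Bold4D], pd.DataFrame]:
    """Generate per-subject 4D BOLD volumes plus the injected ground truth.

    Every voxel's series is ``100 * (1 + pct/100 * step)`` over the response
    window for responder voxels of affected regions, plus Gaussian noise
    (``noise_sd`` percent of baseline inside affected regions,
    ``global_noise_sd`` elsewhere).  Responder voxels are drawn once per
    region from the design seed, so the injected responder count is shared
    by all subjects.  Deterministic given ``design.seed``.
    """
    known = set(atlas.region_ids)
    for spec in effects:
        if spec.region_id not in known:
            raise ValueError(f"effect references unknown region id {spec.region_id}")
        unknown_groups = set(spec.percent_change) - set(design.group_labels)
        if unknown_groups:
            raise ValueError(f"effect references unknown groups {sorted(unknown_groups)}")

    root = np.random.SeedSequence(design.seed)
    layout_rng = np.random.default_rng(root.spawn(1)[0])
    shape = atlas.labels.shape
    n_t = design.n_acquisitions

    step = np.zeros(n_t)
    step[window_slice(design.response_window)] = 1.0

    responder_masks: dict[int, np.ndarray] = {}
    noise_map = np.full(shape, global_noise_sd)
    truth_rows = []
    for spec in effects:
        region_mask = atlas.labels == spec.region_id
        voxel_idx = np.flatnonzero(region_mask)
        n_resp = int(round(spec.responder_fraction * voxel_idx.size))
        chosen = layout_rng.choice(voxel_idx, size=n_resp, replace=False)
        mask = np.zeros(shape, dtype=bool)
        mask.ravel()[chosen] = True
        responder_masks[spec.region_id] = mask
        noise_map[region_mask] = spec.noise_sd
        for group in design.group_labels:
            truth_rows.append(
                {
                    "region_id": spec.region_id,
                    "group": group,
                    "injected_pct": spec.percent_change.get(group, 0.0),
                    "n_responders": n_resp,
                    "n_region_voxels": int(voxel_idx.size),
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["region_id", "group", "injected_pct", "n_responders", "n_region_voxels"],
    )

    subjects: list[Bold4D] = []
    subject_seeds = iter(root.spawn(sum(n for _, _, n in design.groups) + 1)[1:])
    for label, _dose, n_subjects in design.groups:
        amplitude = np.zeros(shape)
        for spec in effects:
            pct = spec.percent_change.get(label, 0.0)
            if pct:
                amplitude[responder_masks[spec.region_id]] = pct
        clean = BASELINE_LEVEL * (
            1.0 + amplitude[..., None] / 100.0 * step[None, None, None, :]
        )
        for s in range(n_subjects):
            rng = np.random.default_rng(next(subject_seeds))
            noise = rng.standard_normal(clean.shape) * (
                BASELINE_LEVEL * noise_map[..., None] / 100.0
            )
            subjects.append(
                Bold4D(clean + noise, design.tr, f"{label}_{s + 1:02d}", label)
            )
    return subjects, truth
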