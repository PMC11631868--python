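"""Voxel-wise BOLD dose-response scoring and regional volume-of-activation tables.

The analysis chain per subject is:

1. ``percent_change_map`` — signed percent change of the response-window mean
   relative to the baseline-window mean, per voxel.
2. ``voxel_ttest`` — Welch (heteroscedastic) two-tailed t-test of response vs
   baseline acquisitions, per voxel.
3. ``ranked_p_filter`` — per-region ranked-p false-positive filter: within a
   region of V voxels the i-th smallest p passes when p_i <= (i/V) * q * c(V),
   applied as a step-up rule (the largest satisfying rank admits all smaller
   ranks).  Defaults q = 0.2, c(V) = 1.
4. ``classify_voxels`` — surviving voxels with |dPct| >= 1% become positive or
   negative activation voxels; the rest are null.
5. ``region_voxel_counts`` — per-region signed voxel counts (the volume of
   activation), compared across dose groups with a Kruskal-Wallis test and a
   rank-based omega-squared effect size, and ranked by significance.

``composite_map`` assembles group-mean percent-change volumes by pulling each
subject's map through the inverse of its subject-to-composite affine with
trilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .types import AtlasLabels, Bold4D, SubjectTransform, Window, validate_windows, window_slice

__all__ = [
    "percent_change_map",
    "voxel_ttest",
    "ranked_p_filter",
    "classify_voxels",
    "region_voxel_counts",
    "composite_map",
    "kruskal_wallis",
    "omega_squared",
    "region_activation_table",
    "rank_table",
    "subject_voxel_stats",
    "VoxelStatMap",
]

DEFAULT_BASELINE: Window = (5, 45)
DEFAULT_RESPONSE: Window = (150, 200)
DEFAULT_Q = 0.2
DEFAULT_CV = 1.0
DEFAULT_THRESHOLD_PCT = 1.0


@dataclass
class VoxelStatMap:
    """Per-voxel statistics for one subject: dPct, p, pass flag, sign class."""

    percent_change: np.ndarray
    p_values: np.ndarray
    passed: np.ndarray
    sign_class: np.ndarray  # +1 positive, -1 negative, 0 null
    invalid: np.ndarray  # voxels excluded (zero baseline mean)
    subject_id: str = ""
    group: str = ""
    qc: dict = field(default_factory=dict)


def percent_change_map(
    bold: Bold4D,
    baseline_window: Window = DEFAULT_BASELINE,
    response_window: Window = DEFAULT_RESPONSE,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed percent change of response-window mean vs baseline-window mean.

    Returns ``(dpct, invalid)`` where ``dpct`` is the percent-change volume and
    ``invalid`` marks voxels whose baseline mean is zero (these are excluded
    downstream rather than failing the run; their dpct is set to 0).
    """
    validate_windows(baseline_window, response_window, bold.n_acquisitions)
    base = bold.data[..., window_slice(baseline_window)].mean(axis=3)
    resp = bold.data[..., window_slice(response_window)].mean(axis=3)
    invalid = base == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dpct = 100.0 * (resp - base) / base
    dpct[invalid] = 0.0
    return dpct, invalid


def voxel_ttest(
    bold: Bold4D,
    baseline_window: Window = DEFAULT_BASELINE,
    response_window: Window = DEFAULT_RESPONSE,
) -> np.ndarray:
    """Welch two-sample two-tailed t-test per voxel: response vs baseline.

    Degenerate voxels where both windows have zero variance get p = 1 when the
    means agree and p = 0 when they differ (documented convention; such voxels
    carry no sampling noise so the decision is exact).
    """
    validate_windows(baseline_window, response_window, bold.n_acquisitions)
    base = bold.data[..., window_slice(baseline_window)]
    resp = bold.data[..., window_slice(response_window)]
    if base.shape[3] < 2 or resp.shape[3] < 2:
        raise ValueError("each window needs at least 2 acquisitions")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance voxels are handled by the explicit conventions below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(resp, base, axis=3, equal_var=False)
    p = np.asarray(p)
    degenerate = (base.var(axis=3) == 0) & (resp.var(axis=3) == 0)
    equal_means = np.isclose(base.mean(axis=3), resp.mean(axis=3))
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0
    p = np.nan_to_num(p, nan=1.0)
    return np.clip(p, 0.0, 1.0)


def ranked_p_filter(
    p_values: np.ndarray, q: float = DEFAULT_Q, c_v: float = DEFAULT_CV
) -> np.ndarray:
    """Ranked-p false-positive filter over one region's voxel p-values.

    Sort the V p-values ascending with rank i = 1..V and find the largest i
    with p_(i) <= (i/V) * q * c_v; all voxels with p <= p_(i) pass (step-up,
    so tied p-values share the better rank).  If no rank satisfies the
    inequality nothing passes.  Returns a boolean mask in input order.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if c_v <= 0:
        raise ValueError("c(V) must be positive")
    v = p.size
    order = np.argsort(p, kind="stable")
    thresholds = (np.arange(1, v + 1) / v) * q * c_v
    satisfied = p[order] <= thresholds
    if not satisfied.any():
        return np.zeros(v, dtype=bool)
    cutoff = p[order][np.nonzero(satisfied)[0].max()]
    return p <= cutoff


def classify_voxels(
    dpct: np.ndarray,
    passed: np.ndarray,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> np.ndarray:
    """Sign-classify voxels: +1 / -1 for filter survivors beyond +-threshold.

    The magnitude threshold is inclusive: |dPct| exactly at the threshold
    qualifies.  Voxels that failed the ranked-p filter are null regardless of
    magnitude.
    """
    if dpct.shape != passed.shape:
        raise ValueError("percent-change map and pass flags must be congruent")
    sign = np.zeros(dpct.shape, dtype=np.int8)
    sign[passed & (dpct >= threshold_pct)] = 1
    sign[passed & (dpct <= -threshold_pct)] = -1
    return sign


def subject_voxel_stats(
    bold: Bold4D,
    atlas: AtlasLabels,
    baseline_window: Window = DEFAULT_BASELINE,
    response_window: Window = DEFAULT_RESPONSE,
    q: float = DEFAULT_Q,
    c_v: float = DEFAULT_CV,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> VoxelStatMap:
    """Run the full per-subject voxel chain with the ranked-p filter per region."""
    if bold.grid != atlas.labels.shape:
        raise ValueError(
            f"BOLD grid {bold.grid} does not match atlas grid {atlas.labels.shape}"
        )
    dpct, invalid = percent_change_map(bold, baseline_window, response_window)
    p = voxel_ttest(bold, baseline_window, response_window)
    passed = np.zeros(dpct.shape, dtype=bool)
    for region_id in atlas.region_ids:
        mask = (atlas.labels == region_id) & ~invalid
        if not mask.any():
            continue
        passed[mask] = ranked_p_filter(p[mask], q=q, c_v=c_v)
    sign = classify_voxels(dpct, passed, threshold_pct)
    sign[invalid] = 0
    qc = {"n_invalid_voxels": int(invalid.sum())}
    return VoxelStatMap(dpct, p, passed, sign, invalid, bold.subject_id, bold.group, qc)


def region_voxel_counts(sign_class: np.ndarray, atlas: AtlasLabels) -> pd.DataFrame:
    """Count negative and positive activation voxels per atlas region."""
    if sign_class.shape != atlas.labels.shape:
        raise ValueError("sign-class map grid does not match atlas grid")
    rows = []
    for region_id in atlas.region_ids:
        mask = atlas.labels == region_id
        region_sign = sign_class[mask]
        rows.append(
            {
                "region_id": region_id,
                "region": atlas.region_name(region_id),
                "n_voxels": int(mask.sum()),
                "negative": int(np.count_nonzero(region_sign == -1)),
                "positive": int(np.count_nonzero(region_sign == 1)),
            }
        )
    return pd.DataFrame(rows)


def composite_map(
    maps: list[np.ndarray],
    transforms: list[SubjectTransform],
    composite_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Group-mean percent-change volume on the composite grid.

    Each composite voxel coordinate is mapped into every subject's grid via
    the inverse subject transform, the subject map is sampled there with
    trilinear interpolation, and the composite value is the mean of the
    contributions.  Composite voxels falling outside a subject's grid receive
    no contribution from that subject.
    """
    if len(maps) != len(transforms):
        raise ValueError("one transform required per subject map")
    if not maps:
        raise ValueError("no subject maps supplied")
    shape = composite_shape or maps[0].shape
    grid = np.indices(shape, dtype=float).reshape(3, -1)
    homog = np.vstack([grid, np.ones((1, grid.shape[1]))])
    total = np.zeros(shape, dtype=float).ravel()
    count = np.zeros(shape, dtype=float).ravel()
    for subject_map, transform in zip(maps, transforms):
        coords = (transform.inverse @ homog)[:3]
        dims = np.array(subject_map.shape, dtype=float)
        inside = np.all((coords >= 0) & (coords <= dims[:, None] - 1), axis=0)
        sampled = ndimage.map_coordinates(
            np.asarray(subject_map, dtype=float), coords, order=1, mode="constant", cval=0.0
        )
        total[inside] += sampled[inside]
        count[inside] += 1
    with np.errstate(invalid="ignore"):
        composite = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return composite.reshape(shape)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction, p from chi-square on k-1 df.

    H is computed from mid-ranks of the pooled sample:
    H = (12 / (N (N+1))) * sum_g R_g^2 / n_g - 3 (N+1), divided by the tie
    correction 1 - sum(t^3 - t) / (N^3 - N).  When every observation is
    identical the tie correction degenerates; H is defined as 0 with p = 1.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 groups each with >= 1 observation")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    h = 12.0 / (n_total * (n_total + 1))
    start = 0
    accum = 0.0
    for g in groups:
        r_sum = ranks[start : start + g.size].sum()
        accum += r_sum**2 / g.size
        start += g.size
    h = h * accum - 3 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    if correction <= 0:  # all observations identical
        return 0.0, 1.0
    h /= correction
    h = max(h, 0.0)
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def omega_squared(h: float, k: int, n: int) -> float:
    """Rank-based effect size for a Kruskal-Wallis H: (H - k + 1) / (n - k).

    This is the rank-epsilon-squared form, floored at 0; H at its null
    expectation k - 1 maps to 0.
    """
    if n <= k:
        raise ValueError("effect size undefined for n <= k")
    return max((h - k + 1) / (n - k), 0.0)


def region_activation_table(
    counts_by_subject: list[pd.DataFrame],
    groups: list[str],
    measure: str = "negative",
) -> pd.DataFrame:
    """Assemble the per-region volume-of-activation table across subjects.

    ``counts_by_subject`` holds one ``region_voxel_counts`` frame per subject
    and ``groups`` the matching group labels.  For each region the table
    carries per-group mean and standard error of the chosen count plus the
    Kruskal-Wallis H, p and omega-squared across groups.
    """
    if len(counts_by_subject) != len(groups):
        raise ValueError("one group label required per subject")
    if measure not in ("negative", "positive"):
        raise ValueError("measure must be 'negative' or 'positive'")
    group_order = list(dict.fromkeys(groups))
    rows = []
    regions = counts_by_subject[0][["region_id", "region"]]
    for _, reg in regions.iterrows():
        values_by_group = {g: [] for g in group_order}
        for frame, g in zip(counts_by_subject, groups):
            row = frame.loc[frame["region_id"] == reg["region_id"], measure]
            values_by_group[g].append(float(row.iloc[0]))
        record: dict = {"region_id": int(reg["region_id"]), "region": reg["region"]}
        samples = []
        for g in group_order:
            vals = np.asarray(values_by_group[g])
            record[f"{g}_mean"] = vals.mean()
            record[f"{g}_se"] = (
                vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            )
            samples.append(vals)
        h, p = kruskal_wallis(samples)
        n_total = sum(s.size for s in samples)
        record["H"] = h
        record["p_value"] = p
        record["omega_sq"] = omega_squared(h, len(samples), n_total)
        rows.append(record)
    return pd.DataFrame(rows)


def rank_table(
    table: pd.DataFrame, alpha: float = 0.05, p_column: str = "p_value"
) -> tuple[pd.DataFrame, dict]:
    """Rank regions by significance and summarise the across-region FDR.

    Rows are sorted ascending by p (ties broken by region name for
    deterministic output); the significant view keeps rows with p < alpha
    (strict).  The FDR summary reports the Benjamini-Hochberg step-up
    threshold over all tested regions: the largest p_(i) <= (i/m) * alpha,
    with the number of discoveries at that threshold.
    """
    if table.empty:
        return table.copy(), {"fdr_threshold": np.nan, "n_discoveries": 0}
    sort_cols = [p_column] + (["region"] if "region" in table.columns else [])
    ranked = table.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    significant = ranked[ranked[p_column] < alpha].reset_index(drop=True)
    p_sorted = np.sort(ranked[p_column].to_numpy(dtype=float))
    m = p_sorted.size
    ok = p_sorted <= (np.arange(1, m + 1) / m) * alpha
    if ok.any():
        idx = np.nonzero(ok)[0].max()
        summary = {"fdr_threshold": float(p_sorted[idx]), "n_discoveries": int(idx + 1)}
    else:
        summary = {"fdr_threshold": np.nan, "n_discoveries": 0}
    return significant, summary
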