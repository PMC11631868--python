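"""Differential lipidomics and the rule-based heatmap encoding.

A long-format concentration table (subject x group x compartment x lipid,
moles/g tissue or pmol/mL plasma, with a detection flag) is reduced, per
lipid x compartment cell, to:

* outlier exclusion — single pass, values > 2 sample SDs from their group
  mean are omitted;
* detection status — ok / BDL (no detectable sample anywhere) / BAL (some
  detectable, but fewer than the analytic minimum per group);
* a two-tailed pooled-variance Student t-test (spreadsheet "type 2");
* fold change expressed as a magnitude >= 1 plus a direction flag;
* arrow bins 1-5 for the fold magnitude and a significance shade
  (p < 0.05 dark, 0.05 <= p < 0.1 light).

``cns_combined`` sums a lipid across the six CNS compartments per subject
before testing; ``dose_anova_lsd`` runs the one-way ANOVA with Fisher-LSD
post hocs used for plasma dose curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CNS_COMPARTMENTS",
    "exclude_outliers",
    "two_sample_t",
    "cns_combined",
    "fold_change",
    "arrow_bin",
    "shade_bin",
    "detection_status",
    "HeatmapCell",
    "build_heatmap",
    "heatmap_frame",
    "dose_anova_lsd",
    "validate_lipid_table",
]

CNS_COMPARTMENTS = ("HYP", "CER", "STR", "THAL", "CTX", "HIPP")
COMPARTMENTS = ("plasma",) + CNS_COMPARTMENTS

#: fold-magnitude bin edges; bin i covers [edge_i, edge_{i+1})
ARROW_EDGES = (1.0, 1.5, 2.0, 3.0, 10.0)

REQUIRED_COLUMNS = ("subject_id", "group", "compartment", "lipid", "concentration", "detected")


def validate_lipid_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format lipid concentration table.

    Requires one record per subject x compartment x lipid, non-negative
    concentrations for detected records, and known compartment labels.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"lipid table missing columns: {missing}")
    bad_comp = set(table["compartment"]) - set(COMPARTMENTS)
    if bad_comp:
        raise ValueError(f"unknown compartments: {sorted(bad_comp)}")
    detected = table[table["detected"].astype(bool)]
    if (detected["concentration"] < 0).any():
        raise ValueError("detected concentrations must be >= 0")
    dupes = table.duplicated(subset=["subject_id", "compartment", "lipid"])
    if dupes.any():
        raise ValueError("duplicate subject x compartment x lipid records")
    return table


def exclude_outliers(values: np.ndarray) -> tuple[np.ndarray, dict]:
    """Drop values more than 2 sample SDs from the group mean (single pass).

    Mean and SD include the candidate values themselves and the rule is not
    re-applied to the survivors.  Groups of fewer than 3 values are returned
    unchanged with a QC note, and a zero-SD group is vacuously kept.
    """
    x = np.asarray(values, dtype=float).ravel()
    log: dict = {"n_in": int(x.size), "excluded": []}
    if x.size < 3:
        log["note"] = "n < 3: outlier rule not applied"
        return x, log
    sd = x.std(ddof=1)
    if sd == 0:
        return x, log
    keep = np.abs(x - x.mean()) <= 2.0 * sd
    log["excluded"] = [float(v) for v in x[~keep]]
    return x[keep], log


def two_sample_t(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-tailed pooled-variance Student t-test (spreadsheet TTEST type 2).

    Degenerate zero-variance cases: equal means give p = 1, unequal means
    p = 0 (no sampling noise, so the decision is exact).
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values after exclusion")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def cns_combined(
    table: pd.DataFrame, lipid: str, group_a: str, group_b: str
) -> tuple[pd.DataFrame, tuple[float, float], dict]:
    """Per-subject sum of a lipid across the six CNS compartments + group test.

    Subjects missing any of the six compartments are dropped with a QC note;
    sums are then compared between the two groups with the pooled t-test.
    Returns (per-subject sums frame, (t, p), qc log).
    """
    sub = table[(table["lipid"] == lipid) & table["compartment"].isin(CNS_COMPARTMENTS)]
    qc: dict = {"dropped_subjects": []}
    rows = []
    for (subject, group), block in sub.groupby(["subject_id", "group"]):
        if set(block["compartment"]) != set(CNS_COMPARTMENTS):
            qc["dropped_subjects"].append(str(subject))
            continue
        rows.append(
            {"subject_id": subject, "group": group, "total": float(block["concentration"].sum())}
        )
    sums = pd.DataFrame(rows, columns=["subject_id", "group", "total"])
    a = sums.loc[sums["group"] == group_a, "total"].to_numpy()
    b = sums.loc[sums["group"] == group_b, "total"].to_numpy()
    return sums, two_sample_t(a, b), qc


def fold_change(mean_treated: float, mean_vehicle: float) -> tuple[float, str]:
    """Fold difference expressed as a magnitude >= 1 plus a direction.

    Direction is "increase" iff the treated mean exceeds the vehicle mean;
    equal means give fold 1 with the tie broken as "increase".  Zero means
    have no defined fold (handled by the detection-status pathway).
    """
    if mean_treated <= 0 or mean_vehicle <= 0:
        raise ValueError("fold change requires both means > 0")
    if mean_treated >= mean_vehicle:
        return mean_treated / mean_vehicle, "increase"
    return mean_vehicle / mean_treated, "decrease"


def arrow_bin(fold: float) -> int:
    """Map a fold magnitude to 1-5 arrows.

    [1, 1.5) -> 1; [1.5, 2) -> 2; [2, 3) -> 3; [3, 10) -> 4; >= 10 -> 5.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1 (normalize direction first)")
    arrows = int(np.searchsorted(ARROW_EDGES, fold, side="right"))
    return min(arrows, 5)


def shade_bin(p: float) -> str:
    """Significance shade: p < 0.05 dark, 0.05 <= p < 0.1 light, else none."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.05:
        return "dark"
    if p < 0.1:
        return "light"
    return "none"


def detection_status(detected_flags: np.ndarray, n_required: int = 3) -> str:
    """ok / BDL / BAL for one cell's pooled records (both groups).

    BDL when no sample anywhere is detectable; BAL when some are but fewer
    than ``n_required`` detectable samples remain in at least one group
    (callers pass per-group flag arrays via ``detection_status_groups``).
    """
    flags = np.asarray(detected_flags, dtype=bool).ravel()
    if flags.size == 0 or not flags.any():
        return "BDL"
    if flags.sum() < n_required:
        return "BAL"
    return "ok"


def detection_status_groups(
    flags_by_group: list[np.ndarray], n_required: int = 3
) -> str:
    """Cell-level status across groups: BDL if nothing detected anywhere,
    BAL if any group has fewer than ``n_required`` detectable samples."""
    all_flags = np.concatenate([np.asarray(f, dtype=bool).ravel() for f in flags_by_group])
    if all_flags.size == 0 or not all_flags.any():
        return "BDL"
    for flags in flags_by_group:
        flags = np.asarray(flags, dtype=bool).ravel()
        if flags.sum() < n_required:
            return "BAL"
    return "ok"


@dataclass
class HeatmapCell:
    """Encoded differential result for one lipid x compartment cell."""

    lipid: str
    compartment: str
    status: str  # ok | BDL | BAL
    direction: str | None = None  # increase | decrease
    shade: str | None = None  # dark | light | none
    arrows: int | None = None
    fold: float | None = None
    p_value: float | None = None
    qc: dict = field(default_factory=dict)


def _cell(
    lipid: str,
    compartment: str,
    treated: pd.DataFrame,
    vehicle: pd.DataFrame,
    n_required: int,
) -> HeatmapCell:
    status = detection_status_groups(
        [treated["detected"].to_numpy(), vehicle["detected"].to_numpy()], n_required
    )
    if status != "ok":
        return HeatmapCell(lipid, compartment, status)
    t_vals, t_log = exclude_outliers(
        treated.loc[treated["detected"].astype(bool), "concentration"].to_numpy()
    )
    v_vals, v_log = exclude_outliers(
        vehicle.loc[vehicle["detected"].astype(bool), "concentration"].to_numpy()
    )
    qc = {"treated_outliers": t_log["excluded"], "vehicle_outliers": v_log["excluded"]}
    if t_vals.size < 2 or v_vals.size < 2 or t_vals.mean() <= 0 or v_vals.mean() <= 0:
        return HeatmapCell(lipid, compartment, "BAL", qc=qc)
    _, p = two_sample_t(t_vals, v_vals)
    fold, direction = fold_change(float(t_vals.mean()), float(v_vals.mean()))
    return HeatmapCell(
        lipid,
        compartment,
        "ok",
        direction=direction,
        shade=shade_bin(p),
        arrows=arrow_bin(fold),
        fold=fold,
        p_value=p,
        qc=qc,
    )


def build_heatmap(
    table: pd.DataFrame,
    treated_group: str,
    vehicle_group: str,
    n_required: int = 3,
) -> list[HeatmapCell]:
    """Encode every lipid x compartment cell of a validated lipid table.

    Per cell: detection status, then outlier exclusion per group, pooled
    t-test, fold change, arrow and shade bins.  Record order in the input
    table does not affect the result.
    """
    validate_lipid_table(table)
    cells = []
    lipids = sorted(table["lipid"].unique())
    compartments = [c for c in COMPARTMENTS if c in set(table["compartment"])]
    for lipid in lipids:
        for compartment in compartments:
            block = table[(table["lipid"] == lipid) & (table["compartment"] == compartment)]
            treated = block[block["group"] == treated_group].sort_values("subject_id")
            vehicle = block[block["group"] == vehicle_group].sort_values("subject_id")
            if treated.empty and vehicle.empty:
                continue
            cells.append(_cell(lipid, compartment, treated, vehicle, n_required))
    return cells


def heatmap_frame(cells: list[HeatmapCell]) -> pd.DataFrame:
    """Flatten heatmap cells into a tidy frame (one row per lipid x compartment)."""
    return pd.DataFrame(
        [
            {
                "lipid": c.lipid,
                "compartment": c.compartment,
                "status": c.status,
                "direction": c.direction,
                "shade": c.shade,
                "arrows": c.arrows,
                "fold": c.fold,
                "p_value": c.p_value,
            }
            for c in cells
        ]
    )


def dose_anova_lsd(
    values_by_group: dict[str, np.ndarray], alpha: float = 0.05
) -> dict:
    """One-way ANOVA with Fisher-LSD post hocs over dose groups.

    Pairwise LSD t-tests use the pooled within-group mean square (MSE) with
    n - k degrees of freedom and are reported only when the omnibus p is
    below ``alpha`` (gated, as is conventional for LSD).
    """
    labels = list(values_by_group)
    groups = [np.asarray(values_by_group[g], dtype=float).ravel() for g in labels]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n_total = sum(g.size for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    result = {"F": float(f), "df": (df_b, df_w), "p_value": p, "pairwise": {}}
    if p < alpha and ss_within > 0:
        mse = ss_within / df_w
        for i in range(k):
            for j in range(i + 1, k):
                gi, gj = groups[i], groups[j]
                se = np.sqrt(mse * (1 / gi.size + 1 / gj.size))
                t = (gi.mean() - gj.mean()) / se
                p_ij = float(2 * stats.t.sf(abs(t), df_w))
                result["pairwise"][(labels[i], labels[j])] = {"t": float(t), "p_value": p_ij}
    return result


def render_heatmap(cells: list[HeatmapCell], path) -> None:
    """Render the encoded grid as a figure (green increases, orange decreases,
    shade by significance, arrow count annotated; BDL/BAL cells greyed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lipids = sorted({c.lipid for c in cells})
    comps = [c for c in COMPARTMENTS if c in {x.compartment for x in cells}]
    colors = {
        ("increase", "dark"): "#1a7a1a",
        ("increase", "light"): "#8fce8f",
        ("decrease", "dark"): "#d2691e",
        ("decrease", "light"): "#f2c49b",
    }
    fig, ax = plt.subplots(figsize=(1.2 * len(comps) + 2, 0.45 * len(lipids) + 1.5))
    for cell in cells:
        i, j = lipids.index(cell.lipid), comps.index(cell.compartment)
        if cell.status != "ok":
            face, text = "#cccccc", cell.status
        else:
            face = colors.get((cell.direction, cell.shade), "#ffffff")
            glyph = "↑" if cell.direction == "increase" else "↓"
            text = glyph * int(cell.arrows or 0)
        ax.add_patch(plt.Rectangle((j, i), 1, 1, facecolor=face, edgecolor="black"))
        ax.text(j + 0.5, i + 0.5, text, ha="center", va="center", fontsize=8)
    ax.set_xlim(0, len(comps))
    ax.set_ylim(0, len(lipids))
    ax.set_xticks(np.arange(len(comps)) + 0.5, comps)
    ax.set_yticks(np.arange(len(lipids)) + 0.5, lipids)
    ax.invert_yaxis()
    ax.set_title("Lipid fold-change / significance heatmap")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
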