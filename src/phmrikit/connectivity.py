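"""Resting-state region-to-region functional connectivity.

Preprocessing contracts (band-pass, nuisance regression, motion scrubbing)
operate on node-by-time matrices; connectivity proper builds Pearson
correlation matrices, Fisher-Z transforms them, aggregates subjects into
group-level Z matrices via edge-wise one-sample t-tests, binarises at
|Z| >= 2.3, and derives degree centrality and mutual-kNN node clusters.
Group degree comparisons are normality-gated: Shapiro-Wilk on the paired
differences routes to a paired t-test (p > 0.05) or a Wilcoxon signed-rank
test otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.spatial.distance import cdist

from .types import ConnectivityMatrix, NodeTimeSeries

__all__ = [
    "bandpass",
    "nuisance_regress",
    "scrub_motion",
    "pearson_matrix",
    "fisher_z",
    "group_edge_z",
    "threshold_matrix",
    "degree_centrality",
    "knn_cluster",
    "compare_degree",
    "DegreeComparison",
]

DEFAULT_BAND = (0.01, 0.1)
DEFAULT_ZCUT = 2.3
#: |Z| assigned to zero-variance (infinitely significant) group edges
GROUP_Z_CAP = 10.0
#: Fisher transform clip: |r| = 1 is pulled to 1 - 1e-7 before atanh
R_CLIP = 1.0 - 1e-7


def bandpass(
    series: np.ndarray,
    sampling_interval: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis (last axis).

    The series is demeaned first, then filtered forward-backward
    (``filtfilt``) so no phase shift is introduced.  Defaults pass
    0.01-0.1 Hz with a 4th-order filter.
    """
    fs = 1.0 / sampling_interval
    nyquist = fs / 2.0
    if not 0 < low < high < nyquist:
        raise ValueError(
            f"band {low}-{high} Hz infeasible at sampling rate {fs} Hz (Nyquist {nyquist})"
        )
    x = np.asarray(series, dtype=float)
    x = x - x.mean(axis=-1, keepdims=True)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def _design_matrix(regressors: np.ndarray, n_frames: int) -> np.ndarray:
    reg = np.asarray(regressors, dtype=float)
    if reg.ndim == 1:
        reg = reg[:, None]
    if reg.shape[0] != n_frames:
        raise ValueError(
            f"regressors have {reg.shape[0]} rows for {n_frames} time points"
        )
    design = np.column_stack([np.ones(n_frames), reg])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "nuisance design is rank deficient; collinear columns are ignored",
            stacklevel=3,
        )
    return design


def nuisance_regress(series: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """OLS residual of each node series after projecting out regressors + intercept.

    Rank-deficient designs are handled with a pseudoinverse (collinear
    columns contribute nothing) and trigger a warning.
    """
    x = np.asarray(series, dtype=float)
    design = _design_matrix(regressors, x.shape[-1])
    beta = np.linalg.pinv(design) @ x.T
    return x - (design @ beta).T


def scrub_motion(series: np.ndarray, outlier_indices: list[int]) -> tuple[np.ndarray, dict]:
    """Censor motion-contaminated frames via spike regressors.

    One indicator regressor per outlier frame is added to an intercept-only
    model, so the residual at each censored frame is exactly zero while the
    remaining frames are merely demeaned.  Censoring more than half of the
    frames raises a QC flag (and a warning) but does not fail.
    """
    x = np.asarray(series, dtype=float)
    n_frames = x.shape[-1]
    idx = sorted(set(int(i) for i in outlier_indices))
    if any(i < 0 or i >= n_frames for i in idx):
        raise ValueError("outlier index outside the series")
    qc = {"n_censored": len(idx), "frac_censored": len(idx) / n_frames}
    if not idx:
        return x.copy(), qc
    if qc["frac_censored"] > 0.5:
        qc["excess_censoring"] = True
        warnings.warn("more than 50% of frames censored", stacklevel=2)
    spikes = np.zeros((n_frames, len(idx)))
    spikes[idx, np.arange(len(idx))] = 1.0
    return nuisance_regress(x, spikes), qc


def pearson_matrix(series: NodeTimeSeries) -> ConnectivityMatrix:
    """Pearson correlations over all unordered node pairs.

    Zero-variance nodes cannot be correlated; their edges are set to NaN and
    recorded in the QC flags instead of failing the subject.
    """
    if series.n_nodes < 2:
        raise ValueError("need at least 2 nodes to correlate")
    x = series.data
    variances = x.var(axis=1)
    degenerate = np.nonzero(variances == 0)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, 0.0)
    qc = {"zero_variance_nodes": [int(i) for i in degenerate]}
    return ConnectivityMatrix(r, list(series.node_ids), "pearson_r", qc)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher Z transform, atanh(r); |r| = 1 is clipped to 1 - 1e-7 first."""
    arr = np.asarray(r, dtype=float)
    clipped = np.clip(arr, -R_CLIP, R_CLIP)
    z = np.arctanh(clipped)
    z = np.where(np.isnan(arr), np.nan, z)
    return float(z) if np.isscalar(r) else z


def fisher_z_matrix(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher-Z transform of a Pearson connectivity matrix."""
    if matrix.kind != "pearson_r":
        raise ValueError("expected a pearson_r matrix")
    z = np.asarray(fisher_z(matrix.values))
    np.fill_diagonal(z, 0.0)
    qc = dict(matrix.qc_flags)
    if np.any(np.abs(matrix.values) >= 1.0 - 1e-12):
        qc["clipped_unit_r"] = True
    return ConnectivityMatrix(z, list(matrix.node_ids), "fisher_z", qc)


def group_edge_z(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Group-level Z matrix from edge-wise one-sample t-tests against zero.

    Each edge's subject Fisher-Z values are t-tested against 0; the t is
    converted to a standard-normal-equivalent Z through the two-tailed
    p-value with the sign of the mean preserved.  Edges with zero
    across-subject variance but a nonzero mean are capped at |Z| = 10 and
    QC-flagged.
    """
    if len(matrices) < 2:
        raise ValueError("need >= 2 subjects for a group t-test")
    if any(m.kind != "fisher_z" for m in matrices):
        raise ValueError("group_edge_z expects fisher_z matrices")
    node_ids = matrices[0].node_ids
    if any(m.node_ids != node_ids for m in matrices):
        raise ValueError("subject matrices have mismatched node registries")
    stack = np.stack([m.values for m in matrices])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    n = stack.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
        z = np.sign(mean) * stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    degenerate = (sd == 0) & (mean != 0)
    z[degenerate] = np.sign(mean[degenerate]) * GROUP_Z_CAP
    z[(sd == 0) & (mean == 0)] = 0.0
    z = np.clip(z, -GROUP_Z_CAP, GROUP_Z_CAP)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    qc = {"capped_edges": int(degenerate.sum())}
    return ConnectivityMatrix(z, list(node_ids), "group_z", qc)


def threshold_matrix(matrix: ConnectivityMatrix, zcut: float = DEFAULT_ZCUT) -> np.ndarray:
    """Binary undirected adjacency: A_ij = 1 iff |Z_ij| >= zcut, i != j.

    The threshold is inclusive; NaN edges never survive.
    """
    with np.errstate(invalid="ignore"):
        a = (np.abs(np.nan_to_num(matrix.values, nan=0.0)) >= zcut).astype(np.int8)
    np.fill_diagonal(a, 0)
    return a


def degree_centrality(adjacency: np.ndarray, node_ids: list[int] | None = None) -> pd.DataFrame:
    """Degree centrality CD_j = sum_i A_ij per node of a binary adjacency."""
    a = np.asarray(adjacency)
    n = a.shape[0]
    if a.shape != (n, n) or not np.array_equal(a, a.T):
        raise ValueError("adjacency must be square and symmetric")
    if not np.isin(a, (0, 1)).all() or np.any(np.diag(a) != 0):
        raise ValueError("adjacency must be binary with a zero diagonal")
    ids = node_ids if node_ids is not None else list(range(n))
    return pd.DataFrame({"node_id": ids, "degree": a.sum(axis=1).astype(int)})


def knn_cluster(
    matrix: ConnectivityMatrix, k: int = 5, metric: str = "euclidean"
) -> np.ndarray:
    """Cluster nodes by their connectivity profiles with a mutual-kNN graph.

    Each node's profile is its row of the connectivity matrix.  Two nodes are
    linked when each is among the other's k nearest neighbours (Euclidean by
    default, ties included); nodes left without any reciprocated neighbour
    are attached to their single nearest neighbour, and clusters are the
    connected components of the resulting graph.
    Returns integer cluster labels in node order (labelled by order of first
    appearance, so permuting nodes permutes labels consistently).
    """
    n = matrix.n_nodes
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the node count {n}")
    profiles = np.nan_to_num(matrix.values, nan=0.0)
    dists = cdist(profiles, profiles, metric=metric)
    np.fill_diagonal(dists, np.inf)
    # tie-inclusive k-th neighbour distance, so identical profiles are all
    # mutual neighbours instead of being split by arbitrary tie-breaking
    kth = np.partition(dists, k - 1, axis=1)[:, k - 1]
    neighbors = dists <= kth[:, None] + 1e-12
    mutual = neighbors & neighbors.T
    # a node whose k-neighbourhood is never reciprocated would become a
    # spurious singleton; attach it to its single nearest neighbour
    isolated = ~mutual.any(axis=1)
    if n > 1:
        for i in np.flatnonzero(isolated):
            j = int(np.argmin(dists[i]))
            mutual[i, j] = mutual[j, i] = True
    from scipy.sparse.csgraph import connected_components

    _, labels = connected_components(mutual, directed=False)
    # relabel by first appearance for deterministic, permutation-consistent labels
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


@dataclass
class DegreeComparison:
    """Result of a normality-gated paired comparison of node degrees."""

    test: str  # "paired_t" | "wilcoxon" | "no_difference"
    statistic: float
    p_value: float
    shapiro_p: float


def compare_degree(
    degrees_a: np.ndarray, degrees_b: np.ndarray, alpha_normality: float = 0.05
) -> DegreeComparison:
    """Compare two paired degree vectors (same node set, two conditions).

    Shapiro-Wilk assesses normality of the paired differences; p > alpha
    routes to a paired t-test, otherwise to a Wilcoxon signed-rank test.
    All-zero differences short-circuit to a no-difference report with p = 1.
    """
    a = np.asarray(degrees_a, dtype=float).ravel()
    b = np.asarray(degrees_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired degree vectors must have equal length")
    diff = a - b
    if np.all(diff == 0):
        return DegreeComparison("no_difference", 0.0, 1.0, 1.0)
    if np.ptp(diff) == 0:  # constant nonzero shift: zero-variance difference
        return DegreeComparison("paired_t", float(np.sign(diff[0]) * np.inf), 0.0, 1.0)
    shapiro_p = float(stats.shapiro(diff).pvalue)
    if shapiro_p > alpha_normality:
        t_stat, p = stats.ttest_rel(a, b)
        return DegreeComparison("paired_t", float(t_stat), float(p), shapiro_p)
    w_stat, p = stats.wilcoxon(a, b)
    return DegreeComparison("wilcoxon", float(w_stat), float(p), shapiro_p)
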