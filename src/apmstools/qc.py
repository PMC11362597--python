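"""Quality-control battery and hierarchical clustering for LFQ experiments.

Covers sample-level PCA, the all-pairs Pearson correlation matrix,
per-sample detected-protein counts with a between-group t-test, the
detection-overlap partition between two conditions, normality summaries of
log2 intensity distributions, and average-linkage hierarchical clustering of
the (usually Z-scored) expression matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .core import Condition, DesignError, ProteinQuantTable, StudyDesign

__all__ = [
    "run_pca",
    "pearson_matrix",
    "compare_detected_counts",
    "overlap_partition",
    "partition_percentages",
    "hierarchical_cluster",
    "ClusterResult",
    "gaussian_check",
    "qc_report",
]


def run_pca(
    table: ProteinQuantTable,
    n_components: int = 2,
    scale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-level PCA of an imputed log2 table.

    Proteins are features, samples are observations; data are centered
    (and unit-scaled if ``scale``). Returns the sample scores and the
    fractions of variance explained (descending).
    """
    if table.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if table.missing_mask.any():
        raise ValueError("PCA expects an imputed table")
    n_components = min(n_components, table.n_samples - 1, table.n_proteins)
    X = table.intensities.T.copy()  # samples x proteins
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    coords = pd.DataFrame(
        scores,
        index=table.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return coords, pca.explained_variance_ratio_.copy()


def pearson_matrix(table: ProteinQuantTable) -> pd.DataFrame:
    """All-pairs Pearson correlation of samples over proteins."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if table.missing_mask.any():
        raise ValueError("pearson_matrix expects an imputed table")
    sds = table.intensities.std(axis=0)
    constant = [table.sample_ids[j] for j in np.flatnonzero(sds == 0)]
    if constant:
        raise ValueError(f"constant samples have undefined correlation: {constant}")
    r = np.corrcoef(table.intensities.T)
    return pd.DataFrame(r, index=table.sample_ids, columns=table.sample_ids)


def compare_detected_counts(
    table: ProteinQuantTable,
    design: StudyDesign,
    cond_a: "str | Condition",
    cond_b: "str | Condition",
) -> dict:
    """Per-sample detected-protein counts and an unpaired two-sided t-test.

    Counts come from the pre-imputation missingness mask.
    """
    cond_a, cond_b = Condition.parse(cond_a), Condition.parse(cond_b)
    detected = ~table.missing_mask
    counts = {s: int(detected[:, j].sum()) for j, s in enumerate(table.sample_ids)}
    a = [counts[s] for s in design.samples_in(cond_a) if s in counts]
    b = [counts[s] for s in design.samples_in(cond_b) if s in counts]
    if len(a) < 2 or len(b) < 2:
        raise DesignError("both conditions need >= 2 samples for the count comparison")
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        p = 1.0
    else:
        p = float(stats.ttest_ind(a, b).pvalue)
    return {
        "counts": counts,
        "mean_a": float(np.mean(a)),
        "mean_b": float(np.mean(b)),
        "mean_diff": float(np.mean(a) - np.mean(b)),
        "p_value": p,
    }


def partition_percentages(a_only: int, b_only: int, shared: int) -> dict:
    """Percentages (2 decimals) of the detection-overlap partition.

    Largest-remainder rounding, so the three displayed percentages always
    sum to exactly 100.00.
    """
    total = a_only + b_only + shared
    if total == 0:
        raise ValueError("empty union of detected proteins")
    exact = np.array([a_only, b_only, shared], dtype=float) * 100.0 / total
    floored = np.floor(exact * 100.0) / 100.0
    shortfall = int(round((100.0 - floored.sum()) * 100.0))
    for i in np.argsort(-(exact - floored))[:shortfall]:
        floored[i] = round(floored[i] + 0.01, 2)
    return {
        "a_only_pct": round(floored[0], 2),
        "b_only_pct": round(floored[1], 2),
        "shared_pct": round(floored[2], 2),
    }


def overlap_partition(
    table: ProteinQuantTable,
    design: StudyDesign,
    cond_a: "str | Condition",
    cond_b: "str | Condition",
) -> dict:
    """Partition detected proteins into condition-exclusive and shared sets.

    A protein counts as detected in a condition when it is non-missing in at
    least one sample of that condition.
    """
    cond_a, cond_b = Condition.parse(cond_a), Condition.parse(cond_b)
    detected = ~table.missing_mask
    cols_a = [table.col_index(s) for s in design.samples_in(cond_a) if s in table.sample_ids]
    cols_b = [table.col_index(s) for s in design.samples_in(cond_b) if s in table.sample_ids]
    in_a = detected[:, cols_a].any(axis=1)
    in_b = detected[:, cols_b].any(axis=1)
    a_only = int((in_a & ~in_b).sum())
    b_only = int((~in_a & in_b).sum())
    shared = int((in_a & in_b).sum())
    out = {"a_only": a_only, "b_only": b_only, "shared": shared,
           "total": a_only + b_only + shared}
    out.update(partition_percentages(a_only, b_only, shared))
    return out


@dataclass
class ClusterResult:
    order: np.ndarray          # leaf permutation
    linkage: np.ndarray        # scipy linkage matrix
    clusters: Optional[np.ndarray] = None  # flat assignment at k, 1-based


def hierarchical_cluster(
    matrix: np.ndarray,
    axis: int = 0,
    metric: str = "euclidean",
    linkage: str = "average",
    k: Optional[int] = None,
) -> ClusterResult:
    """Agglomerative clustering of rows (axis=0) or columns (axis=1).

    Euclidean distance with average linkage by default, matching the usual
    expression-heatmap convention; pass the Z-scored matrix to emulate a
    clustered heatmap. Leaf order follows the standard dendrogram
    convention.
    """
    X = np.asarray(matrix, dtype=float)
    if axis == 1:
        X = X.T
    n = X.shape[0]
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds the {n} items being clustered")
    Z = hierarchy.linkage(X, method=linkage, metric=metric)
    order = np.asarray(hierarchy.leaves_list(Z))
    clusters = hierarchy.fcluster(Z, t=k, criterion="maxclust") if k is not None else None
    return ClusterResult(order=order, linkage=Z, clusters=clusters)


def gaussian_check(values: np.ndarray) -> dict:
    """Moments and an omnibus normality test of a value set.

    Returns skewness, excess kurtosis and the D'Agostino–Pearson p-value.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 8:
        raise ValueError("need at least 8 values for the normality test")
    if values.std() == 0:
        raise ValueError("constant input has no distribution shape to test")
    return {
        "skewness": float(stats.skew(values)),
        "excess_kurtosis": float(stats.kurtosis(values)),
        "p_value": float(stats.normaltest(values).pvalue),
    }


def qc_report(
    raw_table: ProteinQuantTable,
    imputed_table: ProteinQuantTable,
    design: StudyDesign,
    cond_a: "str | Condition",
    cond_b: "str | Condition",
    n_components: int = 2,
) -> dict:
    """Assemble the full QC battery for a two-condition experiment.

    ``raw_table`` (log2, pre-imputation) feeds the detection-based pieces;
    ``imputed_table`` feeds PCA and correlations.
    """
    coords, varexp = run_pca(imputed_table, n_components=n_components)
    pearson = pearson_matrix(imputed_table)
    counts = compare_detected_counts(raw_table, design, cond_a, cond_b)
    overlap = overlap_partition(raw_table, design, cond_a, cond_b)
    obs = ~raw_table.missing_mask
    normality = {}
    for cond in (Condition.parse(cond_a), Condition.parse(cond_b)):
        cols = [raw_table.col_index(s) for s in design.samples_in(cond)
                if s in raw_table.sample_ids]
        vals = raw_table.intensities[:, cols][obs[:, cols]]
        normality[cond.value] = gaussian_check(vals)
    return {
        "pca": {"coords": coords, "variance_explained": varexp.tolist()},
        "pearson": pearson,
        "detected_counts": counts,
        "overlap": overlap,
        "normality": normality,
    }
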