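"""Phosphosite co-regulation across perturbation conditions.

The pipeline mirrors standard phosphoproteomics practice: keep the
phosphosites that respond strongly (|log2 fold change| > 1) in at least
three conditions, correlate every pair of retained sites across the
condition panel (pairwise-complete Pearson), cluster the sites by their
correlation profiles (Ward linkage on Euclidean distances between rows
of the correlation matrix, flat clusters by a dendrogram cut), then ask
per cluster which conditions drive it — a one-sided Z-test of the
cluster's fold changes against the condition's full fold-change
distribution, signed by whether the cluster median is above or below the
background — and which annotation terms are over-represented among its
proteins (one-sided hypergeometric with Benjamini-Hochberg correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ClusterResult",
    "filter_regulated",
    "correlation_matrix",
    "cluster_sites",
    "cluster_condition_test",
    "over_representation",
    "read_fc_matrix",
]


@dataclass
class ClusterResult:
    labels: pd.Series  # site -> cluster id, ids contiguous from 1
    linkage: np.ndarray
    cut_height: float | None
    n_clusters: int


def read_fc_matrix(path) -> pd.DataFrame:
    """Read a sites x conditions log2-fold-change TSV.

    The first two columns (protein, position) index the rows; remaining
    columns are conditions.  Empty cells are missing measurements.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError("matrix needs protein, position and >= 1 condition column")
    return df.set_index([df.columns[0], df.columns[1]])


def filter_regulated(
    matrix: pd.DataFrame, log2fc_threshold: float = 1.0, min_conditions: int = 3
) -> pd.DataFrame:
    """Retain sites with |log2FC| strictly above the threshold in at least
    *min_conditions* conditions (twofold regulation in more than two
    conditions by default)."""
    qualifying = (matrix.abs() > log2fc_threshold).sum(axis=1)
    out = matrix.loc[qualifying >= min_conditions]
    if out.empty:
        warnings.warn("no sites pass the regulation filter", stacklevel=2)
    return out


def correlation_matrix(matrix: pd.DataFrame, min_overlap: int = 5) -> pd.DataFrame:
    """Site x site Pearson correlations over pairwise-complete conditions.

    Pairs observed together in fewer than *min_overlap* conditions, and
    pairs involving a constant profile, are undefined; they are imputed
    as 0 so the matrix stays usable for clustering.  Diagonal is 1.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    corr = matrix.T.corr(method="pearson", min_periods=min_overlap)
    if corr.isna().any().any():
        warnings.warn(
            "undefined correlations (low overlap or constant profile) imputed as 0",
            stacklevel=2,
        )
        corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def cluster_sites(
    correlations: pd.DataFrame,
    cut_height: float | None = None,
    n_clusters: int | None = None,
) -> ClusterResult:
    """Ward clustering of sites by their correlation profiles.

    Each site is represented by its row of the correlation matrix;
    distances are Euclidean and linkage is Ward's minimum-variance on
    them (the ward.D2 convention).  Flat clusters come from cutting the
    dendrogram at *cut_height*, or from requesting *n_clusters* directly.
    """
    if (cut_height is None) == (n_clusters is None):
        raise ValueError("give exactly one of cut_height or n_clusters")
    if correlations.shape[0] != correlations.shape[1]:
        raise ValueError("correlation matrix must be square")
    X = correlations.values
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="ward")
    if cut_height is not None:
        root_height = Z[-1, 2] if len(Z) else 0.0
        if cut_height > root_height:
            warnings.warn(
                f"cut height {cut_height} above dendrogram root {root_height:.3g}; "
                "single cluster",
                stacklevel=2,
            )
        raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    else:
        raw = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    # relabel contiguously from 1 in order of first appearance
    mapping: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        labels.append(mapping[lab])
    series = pd.Series(labels, index=correlations.index, name="cluster")
    return ClusterResult(
        labels=series, linkage=Z, cut_height=cut_height, n_clusters=len(mapping)
    )


def cluster_condition_test(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per (cluster, condition) regulation: one-sided Z-test against background.

    For each condition the background is the full distribution of fold
    changes in that condition (cluster members included); the statistic is

        z = (mean_cluster - mean_background) / (sd_background / sqrt(n)),

    tested one-sided on the side of the observed deviation.  The reported
    score is -log10(p), signed positive when the cluster median exceeds
    the background median.  Clusters with fewer than 2 measured values in
    a condition give NA.
    """
    if not labels.index.equals(matrix.index):
        labels = labels.reindex(matrix.index)
    if labels.isna().any():
        raise ValueError("labels must cover every row of the matrix")
    rows = []
    for condition in matrix.columns:
        background = matrix[condition].dropna()
        bg_mean = background.mean()
        bg_median = background.median()
        bg_sd = background.std(ddof=1)
        for cluster_id in sorted(labels.unique()):
            values = matrix.loc[labels == cluster_id, condition].dropna()
            n = len(values)
            if n < 2 or len(background) < 2 or not np.isfinite(bg_sd) or bg_sd == 0:
                z = p = score = np.nan
            else:
                z = (values.mean() - bg_mean) / (bg_sd / np.sqrt(n))
                p = stats.norm.sf(abs(z)) if z != 0 else 0.5
                sign = 1.0 if values.median() > bg_median else -1.0
                score = sign * (-np.log10(p))
            rows.append(
                {
                    "cluster": cluster_id,
                    "condition": condition,
                    "n_sites": n,
                    "z": z,
                    "p_value": p,
                    "signed_minus_log10_p": score,
                }
            )
    return pd.DataFrame(rows)


def over_representation(
    selected_set: set,
    annotation_table: dict[str, set],
    population: set,
) -> pd.DataFrame:
    """Term over-representation in *selected_set* versus *population*.

    One-sided upper-tail hypergeometric p per term (terms with no members
    in the population are skipped), with Benjamini-Hochberg adjusted
    q-values across the tested terms.
    """
    selected = set(selected_set)
    population = set(population)
    if not selected:
        raise ValueError("selection is empty")
    if not selected <= population:
        raise ValueError("selection must be a subset of the population")
    M, n = len(population), len(selected)
    rows = []
    for term, members in annotation_table.items():
        K = len(members & population)
        if K == 0:
            continue
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        expected = n * K / M
        rows.append(
            {
                "term": term,
                "n_selected_in_term": k,
                "n_population_in_term": K,
                "fold_enrichment": (k / expected) if expected > 0 else np.nan,
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "n_selected_in_term", "n_population_in_term",
                 "fold_enrichment", "p_value"],
    )
    if not df.empty:
        df["q_value"] = stats.false_discovery_control(df["p_value"], method="bh")
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df
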