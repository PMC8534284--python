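"""Unsupervised exploration and correlation analyses.

Spearman correlation heatmaps over samples or features, Ward hierarchical
clustering on Euclidean distances, PCA of the log/Pareto-scaled matrix,
coefficient-of-variation heterogeneity profiling, plasma-tissue overlap
of significant metabolites, and the cfDNA-metabolite correlation network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .containers import FeatureMatrix, SampleMetadata
from .differential import adjust_fdr

__all__ = [
    "CorrelationMatrix",
    "spearman_matrix",
    "hierarchical_cluster",
    "PCAResult",
    "pca_scores",
    "CVProfile",
    "cv_profile",
    "overlap_lists",
    "cfdna_network",
]


@dataclass
class CorrelationMatrix:
    """Spearman rho grid with companion raw and adjusted p-value grids."""

    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    axis: str


def spearman_matrix(
    matrix: FeatureMatrix, axis: str = "samples", fdr_method: str = "BH"
) -> CorrelationMatrix:
    """All-pairs Spearman correlation over samples or features.

    Ties get average ranks; p-values use the t approximation and are FDR-
    adjusted over the upper triangle. Constant vectors give undefined rho,
    recorded as NaN.
    """
    if axis not in ("samples", "features"):
        raise ValueError("axis must be 'samples' or 'features'")
    data = matrix.values if axis == "features" else matrix.values.T
    labels = list(data.columns)
    n_obs = data.shape[0]
    if n_obs < 3:
        raise ValueError("need >= 3 observations per correlated pair")
    rho, p = stats.spearmanr(data.to_numpy(dtype=float))
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    iu = np.triu_indices(len(labels), k=1)
    p_flat = p[iu]
    ok = ~np.isnan(p_flat)
    adj_flat = np.full_like(p_flat, np.nan)
    if ok.any():
        adj_flat[ok] = adjust_fdr(p_flat[ok], method=fdr_method)
    p_adj = np.zeros_like(p)
    p_adj[iu] = adj_flat
    p_adj = p_adj + p_adj.T
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=labels, columns=labels),
        p_raw=pd.DataFrame(p, index=labels, columns=labels),
        p_adjusted=pd.DataFrame(p_adj, index=labels, columns=labels),
        axis=axis,
    )


def hierarchical_cluster(
    matrix: FeatureMatrix, n_clusters: int, linkage_method: str = "ward"
) -> Tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of samples on Euclidean distances.

    Returns integer cluster labels (1..n_clusters, scipy convention) and
    the linkage matrix for dendrogram rendering.
    """
    if matrix.has_missing():
        raise ValueError("matrix contains missing values")
    if n_clusters > matrix.n_samples:
        raise ValueError("n_clusters cannot exceed the number of samples")
    dist = pdist(matrix.values.to_numpy(dtype=float), metric="euclidean")
    linkage = hierarchy.linkage(dist, method=linkage_method)
    labels = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=matrix.values.index, name="cluster"), linkage


@dataclass
class PCAResult:
    """PCA scores, loadings, and explained-variance percentages."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_pct: np.ndarray


def pca_scores(matrix: FeatureMatrix, n_components: int = 2) -> PCAResult:
    """Principal components of the column-centred matrix via SVD."""
    if matrix.scale_state != "log-pareto":
        raise ValueError("PCA expects the log-transformed, Pareto-scaled matrix")
    if matrix.has_missing():
        raise ValueError("matrix contains missing values")
    if n_components > min(matrix.n_samples, matrix.n_features):
        raise ValueError("n_components exceeds matrix rank bound")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.values.to_numpy(dtype=float))
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.values.index, columns=comp_names),
        loadings=pd.DataFrame(
            pca.components_.T, index=matrix.values.columns, columns=comp_names
        ),
        explained_variance_pct=100.0 * pca.explained_variance_ratio_,
    )


@dataclass
class CVProfile:
    """Per-feature coefficient of variation (%) within one group."""

    cv_pct: pd.Series
    median_cv_pct: float
    n_undefined: int


def cv_profile(matrix: FeatureMatrix, metadata: SampleMetadata, group: str) -> CVProfile:
    """Raw-scale CV (100*sd/mean) per feature over one group's samples.

    Features with mean 0 have undefined CV and are excluded from the
    median, with the exclusion count reported.
    """
    if matrix.scale_state != "raw":
        raise ValueError("CV is computed on the raw intensity scale")
    samples = metadata.samples_in_group(group)
    if len(samples) < 3:
        raise ValueError(f"group {group!r} has {len(samples)} samples; >= 3 required")
    sub = matrix.values.loc[samples]
    mean = sub.mean(axis=0, skipna=True)
    sd = sub.std(axis=0, ddof=1, skipna=True)
    cv = pd.Series(np.nan, index=sub.columns, name="cv_pct")
    ok = mean > 0
    cv[ok] = 100.0 * sd[ok] / mean[ok]
    n_undefined = int((~ok).sum())
    return CVProfile(
        cv_pct=cv, median_cv_pct=float(cv.dropna().median()), n_undefined=n_undefined
    )


def overlap_lists(
    plasma_significant: Iterable[str], tissue_significant: Iterable[str]
) -> Dict[str, Set[str]]:
    """Venn decomposition of the two significant-metabolite lists."""
    p, t = set(plasma_significant), set(tissue_significant)
    return {"overlap": p & t, "plasma_only": p - t, "tissue_only": t - p}


def cfdna_network(
    matrix: FeatureMatrix,
    metadata: SampleMetadata,
    p_cut: float = 0.05,
    rho_cut: float = 0.25,
    fdr_method: str = "BH",
) -> pd.DataFrame:
    """Metabolite-cfDNA Spearman edges surviving both strict cutoffs.

    Per metabolite, Spearman rho against the cfDNA concentration over
    samples with both measurements; p-values FDR-adjusted across all
    metabolites; edges kept iff adjusted p < ``p_cut`` and
    |rho| > ``rho_cut`` (both strict). Returns the retained edges sorted
    by |rho| descending, with columns rho, p_raw, p_adjusted, sign.
    """
    cfdna = metadata.cfdna
    if cfdna is None or cfdna.dropna().empty:
        raise ValueError("metadata has no cfDNA measurements")
    cfdna = cfdna.reindex(matrix.sample_ids)
    usable = cfdna.dropna().index
    if len(usable) < 10:
        raise ValueError("cfDNA present for fewer than 10 samples")
    rows = []
    for fid in matrix.feature_ids:
        col = matrix.values[fid].reindex(usable)
        mask = col.notna()
        if mask.sum() < 3 or col[mask].nunique() < 2:
            rows.append((fid, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(col[mask], cfdna.loc[usable][mask])
        rows.append((fid, float(rho), float(p)))
    edges = pd.DataFrame(rows, columns=["metabolite", "rho", "p_raw"]).set_index("metabolite")
    ok = edges["p_raw"].notna()
    edges["p_adjusted"] = np.nan
    edges.loc[ok, "p_adjusted"] = adjust_fdr(edges.loc[ok, "p_raw"], method=fdr_method)
    kept = edges[
        ok & (edges["p_adjusted"] < p_cut) & (edges["rho"].abs() > rho_cut)
    ].copy()
    kept["sign"] = np.where(kept["rho"] > 0, "positive", "negative")
    return kept.reindex(kept["rho"].abs().sort_values(ascending=False).index)
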