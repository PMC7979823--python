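"""Unbiased single-cell phenotyping: arcsinh transform, PCA, t-SNE,
clustering, expression heat-map, and agreement with threshold gating.

MFIs on the 0-1 scale are variance-stabilized with the cytometry-standard
hyperbolic arcsine, x -> asinh(x / scale) with scale 0.2, optionally
dropping cells that express none of the markers (0.1 MFI cut-off, as used
for colon data).  The transformed matrix is reduced by PCA (52 components
for tonsil panels, 48 for colon; capped at the available dimensionality)
and embedded by t-SNE (perplexity 30, 1000 iterations, fixed seed).
Clusters come from k-means on the embedding with silhouette-based model
selection, replacing the manual polygon selection of an interactive
workflow with a reproducible algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .io import CellTable, ConfigError, ValidationError


@dataclass
class ClusterParams:
    arcsinh_scale: float = 0.2
    n_components: int = 52          # 48 for the colon panel
    perplexity: float = 30.0
    n_iterations: int = 1000
    expression_cutoff: float | None = None   # 0.1 in colon mode
    seed: int = 0
    k_range: tuple[int, ...] = tuple(range(2, 13))

    def __post_init__(self) -> None:
        if self.arcsinh_scale <= 0:
            raise ConfigError("arcsinh_scale must be > 0")


def transform_expression(
    table: CellTable, params: ClusterParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Arcsinh-transformed cells x markers matrix.

    Returns (matrix, kept) where ``kept`` is the boolean row filter: with an
    expression cut-off, only cells whose maximum raw MFI reaches the cut-off
    are retained ("cells expressing at least one marker").
    """
    params = params or ClusterParams()
    raw = table.mfi_matrix()
    if raw.size and (raw.min() < -1e-9 or raw.max() > 1 + 1e-9):
        raise ValidationError("MFIs must be on the 0-1 scale")
    kept = np.ones(len(raw), dtype=bool)
    if params.expression_cutoff is not None:
        kept = raw.max(axis=1) >= params.expression_cutoff
    return np.arcsinh(raw[kept] / params.arcsinh_scale), kept


def embed_tsne(matrix: np.ndarray, params: ClusterParams | None = None) -> np.ndarray:
    """PCA (centered, unscaled) to ``n_components`` then t-SNE to 2D.

    When the matrix has fewer dimensions or observations than requested
    components, all available components are used.  Deterministic for a
    fixed seed.
    """
    params = params or ClusterParams()
    matrix = np.asarray(matrix, dtype=np.float64)
    n_cells, n_markers = matrix.shape
    if params.perplexity >= n_cells / 3:
        raise ConfigError(
            f"perplexity {params.perplexity} too large for {n_cells} cells"
        )
    n_comp = min(params.n_components, n_markers, n_cells - 1)
    reduced = PCA(n_components=n_comp, random_state=params.seed % (2**31)).fit_transform(matrix)
    tsne = TSNE(
        n_components=2,
        perplexity=params.perplexity,
        max_iter=params.n_iterations,
        random_state=params.seed % (2**31),
        init="pca",
    )
    return tsne.fit_transform(reduced)


def cluster_cells(
    embedding: np.ndarray,
    k: int | str = "auto",
    seed: int = 0,
    k_range: tuple[int, ...] = tuple(range(2, 13)),
) -> np.ndarray:
    """K-means partition of the embedding; k selected by silhouette when
    "auto".  Returns one integer cluster id per cell (0-based).
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    n = len(embedding)
    if k == "auto":
        best_k, best_s = None, -np.inf
        for kk in k_range:
            if kk >= n:
                continue
            labels = KMeans(n_clusters=kk, n_init=10, random_state=seed % (2**31)).fit_predict(embedding)
            s = silhouette_score(embedding, labels)
            if s > best_s:
                best_k, best_s = kk, s
        if best_k is None:
            raise ValidationError("no feasible k in range")
        k = best_k
    k = int(k)
    if k > n:
        raise ValidationError(f"k={k} exceeds {n} cells")
    if k == 1:
        return np.zeros(n, dtype=int)
    return KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31)).fit_predict(embedding)


def cluster_heatmap(table: CellTable, cluster_id: np.ndarray) -> pd.DataFrame:
    """Mean relative expression per cluster: per-cluster mean MFI, each
    marker rescaled to [0, 1] across clusters (constant markers become 0).
    """
    cluster_id = np.asarray(cluster_id)
    if len(cluster_id) != len(table):
        raise ValidationError("cluster_id length must match table")
    mfi = pd.DataFrame(table.mfi_matrix(), columns=table.markers)
    mfi["cluster"] = cluster_id
    means = mfi.groupby("cluster").mean()
    lo = means.min(axis=0)
    span = means.max(axis=0) - lo
    rel = (means - lo).div(span.where(span > 0, 1.0), axis=1)
    rel[means.columns[span <= 0]] = 0.0
    return rel


def gate_cluster_agreement(
    table: CellTable,
    cluster_id: np.ndarray,
    focus_cluster: int,
    focus_type: str,
) -> tuple[float, pd.DataFrame]:
    """Fraction of the focus cluster carrying the focus gated type, plus the
    full cluster x gated-type confusion table (rows sum to cluster sizes).
    """
    if "gated_type" not in table.df.columns:
        raise ValidationError("table is not gated")
    cluster_id = np.asarray(cluster_id)
    if len(cluster_id) != len(table):
        raise ValidationError("cluster_id length must match table")
    df = pd.DataFrame({
        "cluster": cluster_id,
        "gated_type": table.df["gated_type"].to_numpy(),
    })
    confusion = pd.crosstab(df["cluster"], df["gated_type"])
    if focus_cluster not in confusion.index:
        raise ValidationError(f"cluster {focus_cluster} is empty")
    row = confusion.loc[focus_cluster]
    fraction = float(row.get(focus_type, 0) / row.sum())
    return fraction, confusion


def cluster_purity(cluster_id: np.ndarray, true_labels) -> float:
    """Purity of a partition against reference labels: each cluster votes
    for its majority label; purity = fraction of cells matching the vote.
    """
    cluster_id = np.asarray(cluster_id)
    true_labels = np.asarray(true_labels)
    correct = 0
    for c in np.unique(cluster_id):
        members = true_labels[cluster_id == c]
        _, counts = np.unique(members, return_counts=True)
        correct += counts.max()
    return correct / len(cluster_id)
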