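"""Transcriptomic phenotype definition.

Spots are clustered with k-means on median-depth-normalized,
log1p-transformed counts; the number of phenotypes is chosen by
scanning the mean silhouette coefficient over k.  Marker genes per
cluster are ranked by a z-score of the cluster mean against the spread
of all cluster means, and the top 50 over-/under-expressed genes are
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .spatial_io import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeAssignment:
    """Spot -> cluster labels (1..k) plus clustering diagnostics."""

    barcodes: list[str]
    labels: np.ndarray           # 1-based cluster ids
    k: int
    inertia: float
    silhouette: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.barcodes):
            raise ValueError("labels must align with barcodes")
        if set(np.unique(self.labels)) - set(range(1, self.k + 1)):
            raise ValueError("labels must lie in 1..k")

    @property
    def cluster_sizes(self) -> dict[int, int]:
        out = {c: int((self.labels == c).sum()) for c in range(1, self.k + 1)}
        assert sum(out.values()) == len(self.labels)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"barcode": self.barcodes, "cluster": self.labels})


@dataclass
class DEGReport:
    """Per-cluster gene ranking: z-score matrix and top-50 lists."""

    zscores: pd.DataFrame                 # genes x clusters
    top_up: dict[int, list[str]]
    top_down: dict[int, list[str]]


def normalize_counts(
    counts: CountMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Median-depth library-size normalization followed by log1p.

    Each spot's counts are scaled so its total equals the median input
    depth, then log(1 + x) is applied.  All-zero spots are excluded
    with a warning.  Returns (normalized matrix, boolean keep-mask over
    input spots).
    """
    x = counts.counts.astype(float)
    depths = x.sum(axis=1)
    keep = depths > 0
    if not keep.all():
        logger.warning("%d all-zero spot(s) excluded", int((~keep).sum()))
    x = x[keep]
    depths = depths[keep]
    median_depth = np.median(depths)
    scaled = x * (median_depth / depths)[:, None]
    return np.log1p(scaled), keep


def kmeans_phenotypes(
    x: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    barcodes: list[str] | None = None,
    with_silhouette: bool = False,
) -> PhenotypeAssignment:
    """Lloyd's k-means with k-means++ init and ``n_init`` restarts."""
    x = np.asarray(x, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(x) < k:
        raise ValueError("need at least k spots")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x) + 1
    sil = float(silhouette_score(x, labels)) if with_silhouette else None
    if barcodes is None:
        barcodes = [f"SPOT-{i:05d}" for i in range(len(x))]
    return PhenotypeAssignment(
        barcodes=list(barcodes), labels=labels, k=k,
        inertia=float(km.inertia_), silhouette=sil,
    )


def silhouette_scan(
    x: np.ndarray, k_range, seed: int = 0, n_init: int = 10
) -> pd.DataFrame:
    """Mean silhouette coefficient (Euclidean) for each candidate k."""
    x = np.asarray(x, float)
    rows = []
    for k in k_range:
        if not 2 <= k <= len(x) - 1:
            raise ValueError(f"k={k} outside [2, n-1]")
        pa = kmeans_phenotypes(x, k, seed=seed, n_init=n_init, with_silhouette=True)
        rows.append({"k": k, "silhouette": pa.silhouette, "inertia": pa.inertia})
    return pd.DataFrame(rows)


def deg_zscores(
    xnorm: np.ndarray,
    assignment: PhenotypeAssignment,
    genes: list[str] | None = None,
    top_n: int = 50,
) -> DEGReport:
    """Cluster-vs-dataset marker z-scores.

    For gene g and cluster c,
    ``z(g, c) = (mean_c(g) - mean_k(g)) / sd_k(g)`` where the mean and
    standard deviation run over the k cluster means (ddof 0).  Genes
    whose cluster means have zero variance get z = 0.  Top lists take
    the ``top_n`` largest (up) and smallest (down) z per cluster, ties
    broken lexicographically by gene id.
    """
    x = np.asarray(xnorm, float)
    labels = assignment.labels
    if len(x) != len(labels):
        raise ValueError("matrix rows must align with assignment")
    k = assignment.k
    if k < 2:
        raise ValueError("need >= 2 clusters")
    if genes is None:
        genes = [f"GENE-{j:04d}" for j in range(x.shape[1])]
    cluster_means = np.stack(
        [x[labels == c].mean(axis=0) for c in range(1, k + 1)]
    )  # (k, genes)
    center = cluster_means.mean(axis=0)
    sd = cluster_means.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (cluster_means - center) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(z.T, index=genes, columns=range(1, k + 1))
    top_up, top_down = {}, {}
    gene_arr = np.asarray(genes)
    for c in range(1, k + 1):
        order_up = sorted(range(len(genes)), key=lambda j: (-zdf[c].iloc[j], gene_arr[j]))
        order_dn = sorted(range(len(genes)), key=lambda j: (zdf[c].iloc[j], gene_arr[j]))
        top_up[c] = list(gene_arr[order_up[:top_n]])
        top_down[c] = list(gene_arr[order_dn[:top_n]])
    return DEGReport(zscores=zdf, top_up=top_up, top_down=top_down)
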