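"""Statistical comparison suite for per-cluster channel abundances.

Spots are treated as independent samples.  The protocol: Shapiro–Wilk
normality screening, Kruskal–Wallis omnibus test per channel, then all
pairwise two-sided Mann–Whitney U tests with Bonferroni correction
over the whole family (channels x cluster pairs; 4 channels and 6
clusters give the multiplier 60).  Significance is called at corrected
p < 0.001 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 1e-3


@dataclass
class ComparisonResult:
    """Per-channel omnibus + pairwise results.

    ``pairwise`` columns: cluster_a, cluster_b, U, p_raw, p_corrected,
    significant.
    """

    channel: str
    kruskal_h: float
    kruskal_p: float
    pairwise: pd.DataFrame
    multiplier: int
    alpha: float


def interchannel_correlation(
    abundances: np.ndarray | pd.DataFrame,
) -> np.ndarray:
    """Pearson correlation matrix across spots between channel
    abundance vectors.  Zero-variance channels give NaN rows/columns.
    """
    a = np.asarray(abundances, float)
    if a.ndim != 2 or a.shape[0] < 3:
        raise ValueError("need a (spots >= 3, channels) abundance matrix")
    sd = a.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(a, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    return corr


def mean_abs_offdiag(corr: np.ndarray) -> float:
    """Mean absolute off-diagonal entry, ignoring NaNs."""
    c = np.asarray(corr, float)
    mask = ~np.eye(len(c), dtype=bool)
    vals = c[mask]
    return float(np.nanmean(np.abs(vals)))


def shapiro_wilk(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk W statistic and p-value."""
    sample = np.asarray(sample, float)
    if len(sample) < 3:
        raise ValueError("Shapiro–Wilk needs n >= 3")
    if np.ptp(sample) == 0:
        raise ValueError("constant sample")
    w, p = sps.shapiro(sample)
    return float(w), float(p)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square approximation."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def mann_whitney_u(
    a: np.ndarray, b: np.ndarray, exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (U of the first sample).

    Exact null distribution when both groups have at most
    ``exact_max_n`` observations and no ties; otherwise the normal
    approximation with tie and continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    small = len(a) <= exact_max_n and len(b) <= exact_max_n
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if small and not ties else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bonferroni_multiplier(n_clusters: int, n_channels: int) -> int:
    """Family size: channels x cluster pairs.  6 clusters and 4
    channels give 4 * 15 = 60."""
    return n_channels * n_clusters * (n_clusters - 1) // 2


def pairwise_mwu_bonferroni(
    data: pd.DataFrame,
    channels: list[str],
    cluster_col: str = "cluster",
    alpha: float = DEFAULT_ALPHA,
) -> list[ComparisonResult]:
    """Kruskal–Wallis omnibus plus Bonferroni-corrected pairwise
    Mann–Whitney U tests for each channel.

    ``data`` holds one row per spot with a cluster label column and one
    column per channel.  The correction multiplier is the whole family
    size, len(channels) * C(k, 2); corrected p = min(1, m * p_raw).
    Groups with fewer than 2 spots are skipped with a warning.
    """
    clusters = sorted(pd.unique(data[cluster_col]))
    m = bonferroni_multiplier(len(clusters), len(channels))
    results = []
    for ch in channels:
        groups = {c: data.loc[data[cluster_col] == c, ch].to_numpy(float)
                  for c in clusters}
        h, p_omni = kruskal_wallis(*groups.values())
        rows = []
        for ca, cb in combinations(clusters, 2):
            if len(groups[ca]) < 2 or len(groups[cb]) < 2:
                logger.warning(
                    "channel %s: pair (%s, %s) skipped, group too small",
                    ch, ca, cb,
                )
                continue
            u, p = mann_whitney_u(groups[ca], groups[cb])
            p_corr = min(1.0, m * p)
            rows.append(
                {
                    "cluster_a": ca,
                    "cluster_b": cb,
                    "U": u,
                    "p_raw": p,
                    "p_corrected": p_corr,
                    "significant": p_corr < alpha,
                }
            )
        results.append(
            ComparisonResult(
                channel=str(ch),
                kruskal_h=h,
                kruskal_p=p_omni,
                pairwise=pd.DataFrame(rows),
                multiplier=m,
                alpha=alpha,
            )
        )
    return results


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten ComparisonResults into one tidy frame."""
    frames = []
    for r in results:
        df = r.pairwise.copy()
        df.insert(0, "channel", r.channel)
        df["kruskal_h"] = r.kruskal_h
        df["kruskal_p"] = r.kruskal_p
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def plot_violin(data: pd.DataFrame, channel: str, cluster_col: str, path) -> None:
    """Violin plot of one channel's abundance per cluster (KDE with
    Scott's-rule bandwidth, matplotlib's default)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clusters = sorted(pd.unique(data[cluster_col]))
    samples = [data.loc[data[cluster_col] == c, channel].to_numpy(float)
               for c in clusters]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.violinplot(samples, showmedians=True)
    ax.set_xticks(range(1, len(clusters) + 1), [str(c) for c in clusters])
    ax.set_xlabel("cluster")
    ax.set_ylabel(channel)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_correlation_heatmap(corr: np.ndarray, labels, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(corr, vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(len(labels)), labels)
    ax.set_yticks(range(len(labels)), labels)
    for i in range(len(labels)):
        for j in range(len(labels)):
            ax.text(j, i, f"{corr[i, j]:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
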