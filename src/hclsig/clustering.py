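"""Unsupervised hierarchical clustering of lanes and genes with heatmap export.

Expression is log2(x+1)-transformed and z-scored per gene before distance
computation; the default distance is 1 - Pearson correlation with average
linkage, the usual choice for expression heatmaps of panel data.  Both the
lane (sample) axis and the gene axis are clustered, and a group-purity score
summarizes how well the dendrogram separates the biological groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .panel_io import CountMatrix

logger = logging.getLogger("hclsig")

DISTANCES = ("correlation", "euclidean")
LINKAGES = ("average", "complete", "ward")


class ClusteringError(ValueError):
    pass


@dataclass
class ClusteringResult:
    sample_order: list[str]
    gene_order: list[str]
    sample_tree: np.ndarray  # scipy linkage matrix over lanes
    gene_tree: np.ndarray    # scipy linkage matrix over genes
    distance_metric: str
    linkage: str
    group_purity: float
    zmatrix: pd.DataFrame    # z-scored log2 matrix (genes x lanes), input order


def _zscore_log2(values: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score of log2(x+1) counts; zero-variance rows dropped."""
    lg = np.log2(values + 1.0)
    sd = lg.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = lg.index[~keep]
    if len(dropped):
        logger.warning("dropping %d zero-variance gene(s) from clustering", len(dropped))
    lg = lg.loc[keep]
    return lg.sub(lg.mean(axis=1), axis=0).div(sd[keep], axis=0)


def _cluster_axis(mat: np.ndarray, distance: str, linkage: str) -> tuple[np.ndarray, np.ndarray]:
    """Cluster the rows of ``mat``; returns (linkage matrix, condensed distances)."""
    d = pdist(mat, metric=distance)
    d = np.clip(d, 0.0, None)  # correlation distance can go -eps numerically
    z = hierarchy.linkage(d, method=linkage)
    return z, d


def hierarchical_cluster(
    norm: CountMatrix,
    gene_subset: Sequence[str] | None = None,
    distance: str = "correlation",
    linkage: str = "average",
) -> ClusteringResult:
    """Agglomerative clustering of lanes and of genes.

    ``gene_subset`` is a collection of gene symbols (case-insensitive);
    ``None`` clusters on all endogenous genes.  Group purity is the fraction
    of lanes whose nearest lane in cophenetic (dendrogram) distance carries
    the same group label.
    """
    if distance not in DISTANCES:
        raise ClusteringError(f"unknown distance {distance!r}")
    if linkage not in LINKAGES:
        raise ClusteringError(f"unknown linkage {linkage!r}")
    if len(norm.lanes) < 2:
        raise ClusteringError("clustering needs >= 2 lanes")
    panel = norm.panel.table
    probes = norm.panel.endogenous
    if gene_subset is not None:
        wanted = {g.upper() for g in gene_subset}
        if not wanted:
            raise ClusteringError("gene subset is empty")
        probes = probes[panel.loc[probes, "gene_symbol"].str.upper().isin(wanted)]
        if len(probes) == 0:
            raise ClusteringError("no panel genes match the requested subset")
    zm = _zscore_log2(norm.values.loc[probes])
    if zm.shape[0] < 2:
        raise ClusteringError("fewer than 2 informative genes after z-scoring")

    gene_z, _ = _cluster_axis(zm.to_numpy(), distance, linkage)
    sample_z, sample_d = _cluster_axis(zm.to_numpy().T, distance, linkage)

    gene_order = [zm.index[i] for i in hierarchy.leaves_list(gene_z)]
    sample_order = [zm.columns[i] for i in hierarchy.leaves_list(sample_z)]
    gene_symbols = panel.loc[gene_order, "gene_symbol"].tolist()

    purity = _group_purity(norm, zm.columns.tolist(), sample_z)
    return ClusteringResult(
        sample_order=sample_order,
        gene_order=gene_symbols,
        sample_tree=sample_z,
        gene_tree=gene_z,
        distance_metric=distance,
        linkage=linkage,
        group_purity=purity,
        zmatrix=zm,
    )


def _group_purity(norm: CountMatrix, lanes: list[str], sample_z: np.ndarray) -> float:
    if norm.lane_meta is None:
        return float("nan")
    coph = squareform(hierarchy.cophenet(sample_z))
    np.fill_diagonal(coph, np.inf)
    nearest = coph.argmin(axis=1)
    groups = norm.groups().loc[lanes].to_numpy()
    return float(np.mean(groups == groups[nearest]))


def heatmap_export(
    norm: CountMatrix,
    result: ClusteringResult,
    path: str | Path,
) -> tuple[Path, Path]:
    """Render the clustered heatmap (PNG/SVG) and write the ordered matrix TSV.

    The TSV rows/columns follow ``result.gene_order`` / ``result.sample_order``
    exactly.  Returns (image path, TSV path).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import gridspec

    path = Path(path)
    zm = result.zmatrix
    gene_leaf_probes = [zm.index[i] for i in hierarchy.leaves_list(result.gene_tree)]
    ordered = zm.loc[gene_leaf_probes, result.sample_order]
    out_tsv = path.with_suffix(".tsv")
    labelled = ordered.copy()
    labelled.index = norm.panel.table.loc[gene_leaf_probes, "gene_symbol"]
    labelled.index.name = "gene_symbol"
    labelled.to_csv(out_tsv, sep="\t", float_format="%.12g")

    fig = plt.figure(figsize=(8, 10))
    gs = gridspec.GridSpec(3, 2, height_ratios=[1.2, 0.25, 8], width_ratios=[1.5, 8],
                           hspace=0.02, wspace=0.02)
    ax_top = fig.add_subplot(gs[0, 1])
    hierarchy.dendrogram(result.sample_tree, ax=ax_top, no_labels=True,
                         color_threshold=0, above_threshold_color="black")
    ax_top.axis("off")
    if norm.lane_meta is not None:
        ax_grp = fig.add_subplot(gs[1, 1])
        groups = norm.groups().loc[result.sample_order]
        palette = {"cHCL": "#d62728", "vHCL": "#ff7f0e", "nMNC": "#1f77b4",
                   "nB": "#2ca02c", "other": "#7f7f7f"}
        colors = [palette.get(g, "#7f7f7f") for g in groups]
        ax_grp.imshow([list(range(len(colors)))], aspect="auto",
                      cmap=matplotlib.colors.ListedColormap(colors))
        ax_grp.axis("off")
    ax_left = fig.add_subplot(gs[2, 0])
    hierarchy.dendrogram(result.gene_tree, ax=ax_left, orientation="left",
                         no_labels=True, color_threshold=0,
                         above_threshold_color="black")
    ax_left.axis("off")
    ax = fig.add_subplot(gs[2, 1])
    # left-orientation dendrogram lists leaves bottom-to-top; flip rows to match
    ax.imshow(ordered.to_numpy()[::-1], aspect="auto", cmap="RdBu_r",
              vmin=-2.5, vmax=2.5, interpolation="nearest")
    ax.set_xticks(range(len(result.sample_order)))
    ax.set_xticklabels(result.sample_order, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.savefig(path, dpi=150, metadata={"Software": None} if path.suffix == ".png" else None)
    plt.close(fig)
    return path, out_tsv
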