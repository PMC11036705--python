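"""One-vs-rest differential expression across the gradient of regions.

Regions are ordered from the necrotic focus outward to the vessels.  For
each region a gene-wise linear model contrasts it against all other
regions (with optional cell-type-proportion adjustment, as in the niche
analysis).  Per region, up to the top 10 significantly enriched genes by
logFC are kept, ribosomal genes (RPL/RPS/MRPL/MRPS prefixes) are excluded,
and a gene enriched in several regions is shown only under the
most-necrotic one.  Heatmap matrices are z-scaled per row (mean 0, sd 1,
sd with n-1; constant rows dropped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .de import DesignMatrix, build_design, fit_deg
from .deconvolve import ProportionMatrix
from .io import RegionAnnotation
from .qc import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GradientResult",
    "RIBOSOMAL_PREFIXES",
    "region_one_vs_rest",
    "top_genes",
    "zscale_rows",
    "celltype_gradient",
    "gradient_analysis",
]

RIBOSOMAL_PREFIXES: tuple[str, ...] = ("RPL", "RPS", "MRPL", "MRPS")


@dataclass
class GradientResult:
    region_order: list[str]
    tables: dict[str, pd.DataFrame]          # region -> one-vs-rest DEG table
    top_genes: dict[str, list[str]]          # region -> <= n enriched genes
    gene_heatmap: pd.DataFrame               # genes x spots, z-scaled, spots grouped by region
    celltype_heatmap: pd.DataFrame           # types x regions, z-scaled mean proportions
    spot_order: list[str] = field(default_factory=list)


def region_one_vs_rest(
    expr: NormalizedMatrix,
    regions: RegionAnnotation,
    props: ProportionMatrix | pd.DataFrame | None = None,
    region_order: Sequence[str] | None = None,
    alpha: float = 0.05,
    moderation: str = "eb",
) -> dict[str, pd.DataFrame]:
    """Fit region-vs-rest DE for every region, in gradient order."""
    labels = regions.labels
    order = [r for r in (region_order or pd.unique(labels)) if r in set(labels)]
    if len(order) < 2:
        raise ValueError("need at least 2 regions")
    for r in order:
        if (labels == r).sum() < 2:
            raise ValueError(f"region {r!r} has fewer than 2 spots")
    tables = {}
    for r in order:
        design = build_design(RegionAnnotation(labels), niche_label=r, props=props)
        tables[r] = fit_deg(expr, design, alpha=alpha, moderation=moderation)
    return tables


def top_genes(
    tables: Mapping[str, pd.DataFrame],
    region_order: Sequence[str],
    n: int = 10,
    alpha: float = 0.05,
    ribosomal_prefixes: Sequence[str] = RIBOSOMAL_PREFIXES,
) -> dict[str, list[str]]:
    """Up to n positively enriched significant genes per region, deduplicated.

    A gene qualifying in several regions is kept only under the first
    (most-necrotic) region in ``region_order``.
    """
    seen: set[str] = set()
    out: dict[str, list[str]] = {}
    for r in region_order:
        t = tables[r]
        mask = (t["adj_p"] < alpha) & (t["logFC"] > 0)
        cand = t[mask].copy()
        cand = cand[~cand.index.str.startswith(tuple(ribosomal_prefixes))]
        cand = cand[~cand.index.isin(seen)]
        cand["_gene"] = cand.index
        cand = cand.sort_values(["logFC", "_gene"], ascending=[False, True])
        chosen = cand.index[:n].tolist()
        seen.update(chosen)
        out[r] = chosen
    return out


def zscale_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per row subtract the mean and divide by the sd (ddof=1); constant rows dropped."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns to scale")
    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("%d constant rows dropped before scaling", int((~keep).sum()))
    scaled = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.DataFrame(scaled, index=matrix.index[keep], columns=matrix.columns)


def celltype_gradient(
    props: ProportionMatrix | pd.DataFrame,
    regions: RegionAnnotation,
    region_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean proportion per (type, region), z-scaled per type across regions."""
    pdf = props.proportions if isinstance(props, ProportionMatrix) else props
    labels = regions.labels
    missing = set(labels.index) - set(pdf.index)
    if missing:
        raise ValueError(f"labeled spots without proportions: {sorted(missing)[:5]}")
    order = [r for r in (region_order or pd.unique(labels))]
    present = [r for r in order if (labels == r).any()]
    if len(present) < len(order):
        logger.warning("regions with no spots dropped: %s", sorted(set(order) - set(present)))
    means = pd.DataFrame(
        {r: pdf.loc[labels.index[labels == r]].mean(axis=0) for r in present}
    )
    return zscale_rows(means)


def gradient_analysis(
    expr: NormalizedMatrix,
    regions: RegionAnnotation,
    props: ProportionMatrix | pd.DataFrame | None = None,
    region_order: Sequence[str] | None = None,
    n_top: int = 10,
    alpha: float = 0.05,
) -> GradientResult:
    """Full gradient analysis: one-vs-rest DE, top genes, and both heatmaps."""
    labels = regions.labels
    order = [r for r in (region_order or pd.unique(labels)) if r in set(labels)]
    tables = region_one_vs_rest(expr, regions, props, order, alpha=alpha)
    tops = top_genes(tables, order, n=n_top, alpha=alpha)
    genes = [g for r in order for g in tops[r]]
    spot_order = [s for r in order for s in labels.index[labels == r]]
    if genes:
        sub = expr.select_units(spot_order)
        gpos = pd.Index(sub.gene_ids).get_indexer(genes)
        heat = pd.DataFrame(sub.values[gpos], index=genes, columns=spot_order)
        gene_heat = zscale_rows(heat)
    else:
        gene_heat = pd.DataFrame(columns=spot_order)
    ct_heat = (celltype_gradient(props, regions, order)
               if props is not None else pd.DataFrame())
    return GradientResult(order, tables, tops, gene_heat, ct_heat, spot_order)


def plot_gradient_heatmaps(result: GradientResult, path: str) -> None:
    """Render the gene and cell-type heatmaps to an image file (plumbing)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(10, 8),
                             gridspec_kw={"height_ratios": [3, 1]})
    if not result.gene_heatmap.empty:
        axes[0].imshow(result.gene_heatmap.to_numpy(), aspect="auto", cmap="RdBu_r")
        axes[0].set_yticks(range(len(result.gene_heatmap.index)))
        axes[0].set_yticklabels(result.gene_heatmap.index, fontsize=5)
    axes[0].set_title("top region-enriched genes (z-scaled)")
    if not result.celltype_heatmap.empty:
        axes[1].imshow(result.celltype_heatmap.to_numpy(), aspect="auto", cmap="RdBu_r")
        axes[1].set_yticks(range(len(result.celltype_heatmap.index)))
        axes[1].set_yticklabels(result.celltype_heatmap.index, fontsize=7)
        axes[1].set_xticks(range(len(result.celltype_heatmap.columns)))
        axes[1].set_xticklabels(result.celltype_heatmap.columns, rotation=45, fontsize=6, ha="right")
    axes[1].set_title("cell types across the gradient (z-scaled)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
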