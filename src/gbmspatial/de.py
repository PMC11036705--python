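"""Gene-wise linear-model differential expression between regions.

Each gene is fit by ordinary least squares against a design of intercept +
region indicator, optionally augmented with deconvolved cell-type
proportion columns in which the four tumor states are collapsed into a
single "tumor" column and each non-tumor type keeps its own column (one
dropped for simplex identifiability).  Residual variances are moderated by
an empirical-Bayes inverse-chi-square prior whose degrees of freedom and
scale are estimated by the method of moments on log s^2, and two-sided
p-values come from a t-distribution with d0 + d degrees of freedom;
Benjamini-Hochberg adjustment and an adjusted-p < alpha significance flag
complete the table.  A no-moderation mode (plain gene-wise t-tests) is kept
for oracle comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .deconvolve import ProportionMatrix
from .io import RegionAnnotation
from .niches import bh_adjust
from .qc import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = ["DesignMatrix", "build_design", "fit_deg", "compare_logfc", "select_top_genes"]

TUMOR_COLUMN = "tumor"


@dataclass
class DesignMatrix:
    matrix: pd.DataFrame          # spots x covariates (index: spot barcodes)
    coef: str                     # name of the contrast column
    dropped_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        x = self.matrix.to_numpy(dtype=float)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(f"design matrix is rank deficient; columns: {list(self.matrix.columns)}")
        if self.coef not in self.matrix.columns:
            raise ValueError(f"contrast column {self.coef!r} not in the design")


def build_design(
    region_labels: RegionAnnotation | pd.Series,
    niche_label: str,
    props: ProportionMatrix | pd.DataFrame | None = None,
    tumor_states: Sequence[str] = ("MES-like", "AC-like", "OPC-like", "NPC-like"),
    drop_type: str | None = None,
) -> DesignMatrix:
    """Intercept + 0/1 niche indicator, optionally + proportion covariates.

    ``region_labels`` must cover exactly the spots to fit (two groups:
    ``niche_label`` vs everything else, each with >= 2 spots).  When
    proportions are given, tumor-state columns are summed into one "tumor"
    column and one non-tumor column is dropped to avoid simplex collinearity.
    """
    labels = region_labels.labels if isinstance(region_labels, RegionAnnotation) else pd.Series(region_labels)
    indicator = (labels == niche_label).astype(float)
    if indicator.sum() < 2 or (1 - indicator).sum() < 2:
        raise ValueError("each group needs at least 2 spots")
    design = pd.DataFrame({"intercept": 1.0, niche_label: indicator}, index=labels.index)
    dropped: list[str] = []
    if props is not None:
        pdf = props.proportions if isinstance(props, ProportionMatrix) else props
        missing = set(labels.index) - set(pdf.index)
        if missing:
            raise ValueError(f"spots without proportion estimates: {sorted(missing)[:5]}")
        pdf = pdf.loc[labels.index]
        tumor_cols = [c for c in pdf.columns if c in set(tumor_states)]
        other_cols = [c for c in pdf.columns if c not in set(tumor_states)]
        if tumor_cols:
            design[TUMOR_COLUMN] = pdf[tumor_cols].sum(axis=1)
        if drop_type is None:
            drop_type = other_cols[-1] if other_cols else None
        for c in other_cols:
            if c == drop_type:
                dropped.append(c)
                continue
            design[c] = pdf[c]
        if dropped:
            logger.info("dropped proportion column %s for identifiability", dropped)
    # prune degenerate (constant or duplicate) covariate columns
    x = design.to_numpy(dtype=float)
    keep, pruned = [], []
    for j, col in enumerate(design.columns):
        sub = x[:, keep + [j]]
        if np.linalg.matrix_rank(sub) == len(keep) + 1:
            keep.append(j)
        else:
            pruned.append(col)
    if pruned:
        if niche_label in pruned:
            raise ValueError(f"contrast column {niche_label!r} is collinear with {list(design.columns)}")
        logger.warning("pruned degenerate design columns: %s", pruned)
        design = design.iloc[:, keep]
    return DesignMatrix(design, coef=niche_label, dropped_columns=dropped + pruned)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y (Newton, as in the moment estimator for d0)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def _estimate_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments fit of the inverse-chi-square prior on log s^2.

    Returns (d0, s0^2); d0 = inf when the observed spread of log s^2 is no
    larger than the chi-square sampling spread, and (0, nan) when the
    estimate is unusable (fallback: no moderation).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float("nan")
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2) + np.log(d / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2)
    if not np.isfinite(evar):
        return 0.0, float("nan")
    if evar > 0:
        d0 = 2 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        d0 = float("inf")
        s02 = float(np.exp(emean))
    if not (np.isfinite(s02) and s02 > 0):
        return 0.0, float("nan")
    return d0, s02


def fit_deg(
    expr: NormalizedMatrix,
    design: DesignMatrix,
    alpha: float = 0.05,
    moderation: str = "eb",
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-gene OLS + empirical-Bayes moderated t for the design's contrast column.

    ``moderation``: "eb" estimates the prior from the data; "none" uses the
    ordinary per-gene t.  ``prior`` = (d0, s0^2) overrides the estimate
    (d0 = inf forces full shrinkage to s0^2).
    Returns a DataFrame indexed by gene: logFC, t, p_value, adj_p, significant.
    """
    x = design.matrix.to_numpy(dtype=float)
    n, k = x.shape
    if n < k + 1:
        raise ValueError("need more spots than design columns")
    sub = expr.select_units(design.matrix.index.tolist())
    y = sub.values.T                                   # spots x genes
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y                           # k x genes
    resid = y - x @ beta
    d = n - k
    s2 = (resid**2).sum(axis=0) / d
    # genes that are constant up to floating-point noise have no real variance
    scale = np.maximum(1.0, np.abs(y).max(axis=0)) ** 2
    s2 = np.where(s2 <= 1e-24 * scale, 0.0, s2)
    j = design.matrix.columns.get_loc(design.coef)
    c = float(np.sqrt(xtx_inv[j, j]))                  # standard-error multiplier
    logfc = beta[j]

    zero_var = s2 <= 0
    if zero_var.any():
        logger.info("%d genes have zero residual variance; p set to 1", int(zero_var.sum()))

    if moderation == "none" and prior is None:
        d0, s02 = 0.0, float("nan")
    elif prior is not None:
        d0, s02 = prior
    elif moderation == "eb":
        d0, s02 = _estimate_prior(s2, d)
    else:
        raise ValueError(f"unknown moderation mode {moderation!r}")

    if d0 == 0 or not np.isfinite(s02):
        s2_post, df_total = s2, float(d)
    elif np.isinf(d0):
        s2_post, df_total = np.full_like(s2, s02), float("inf")
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(s2_post > 0, logfc / (np.sqrt(s2_post) * c), 0.0)
    if np.isinf(df_total):
        pvals = 2 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2 * stats.t.sf(np.abs(tstat), df_total)
    pvals = np.where(zero_var & (s2_post <= 0), 1.0, pvals)
    adj = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t": tstat,
            "p_value": pvals,
            "adj_p": adj,
            "significant": adj < alpha,
        },
        index=sub.gene_ids,
    )
    table.attrs["d0"] = d0
    table.attrs["s0_squared"] = s02
    table.attrs["residual_df"] = d
    table.attrs["alpha"] = alpha
    return table


def compare_logfc(deg_a: pd.DataFrame, deg_b: pd.DataFrame) -> tuple[float, int, pd.DataFrame]:
    """Pearson r of logFC over shared genes plus a 3x3 significance cross-table."""
    shared = deg_a.index.intersection(deg_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    r = float(np.corrcoef(deg_a.loc[shared, "logFC"], deg_b.loc[shared, "logFC"])[0, 1])

    def classify(t: pd.DataFrame) -> pd.Series:
        lab = np.where(~t["significant"], "ns",
                       np.where(t["logFC"] > 0, "sig_up", "sig_down"))
        return pd.Series(lab, index=t.index)
    ca, cb = classify(deg_a.loc[shared]), classify(deg_b.loc[shared])
    order = ["sig_up", "sig_down", "ns"]
    cross = pd.crosstab(ca, cb).reindex(index=order, columns=order, fill_value=0)
    cross.index.name, cross.columns.name = "a", "b"
    return r, int(len(shared)), cross


def select_top_genes(deg: pd.DataFrame, n: int = 100) -> tuple[list[str], list[str]]:
    """Top-n genes by |logFC| in the positive and negative directions.

    Ties in |logFC| break by gene id for a stable order.  Returns
    (upregulated, downregulated) lists for export to enrichment tools.
    """
    if deg.empty:
        raise ValueError("empty DEG table")
    df = deg.copy()
    df["_gene"] = df.index
    up = df[df["logFC"] > 0].sort_values(["logFC", "_gene"], ascending=[False, True])
    down = df[df["logFC"] < 0].sort_values(["logFC", "_gene"], ascending=[True, True])
    return up.index[:n].tolist(), down.index[:n].tolist()
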