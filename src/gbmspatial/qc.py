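"""Quality filters and normalization.

Cells are removed when they express fewer than ``min_genes`` genes or when
strictly more than ``max_mito_frac`` of their counts align to
mitochondrial genes (detected by a configurable symbol prefix); spots are
removed by the mitochondrial rule only.  Both boundaries are inclusive on
the keep side: a cell at exactly 500 expressed genes and exactly 5%
mitochondrial counts is retained.

Two normalizations are provided: library-size log-normalization
(ln(1 + count * scale / total)) and analytic Pearson residuals under a
fixed-dispersion negative-binomial null (a closed-form variance-stabilizing
transform for spot data).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, ValidationError

__all__ = [
    "NormalizedMatrix",
    "FilterResult",
    "filter_cells",
    "filter_spots",
    "lognormalize",
    "pearson_residual_normalize",
]


@dataclass
class NormalizedMatrix:
    """Real-valued genes x units expression with the normalization recorded."""

    values: np.ndarray
    gene_ids: list[str]
    unit_ids: list[str]
    unit_kind: str
    method: str  # "lognorm" | "pearson_residual"
    scale_factor: float | None = None
    theta: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("normalized matrix contains non-finite entries")
        if self.values.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise ValidationError("normalized matrix shape does not match id lists")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.unit_ids)

    def gene_values(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.values[i]

    def select_units(self, unit_ids: Sequence[str]) -> "NormalizedMatrix":
        pos = pd.Index(self.unit_ids).get_indexer(list(unit_ids))
        if np.any(pos < 0):
            raise KeyError("unknown unit barcodes requested")
        return NormalizedMatrix(self.values[:, pos], list(self.gene_ids), list(unit_ids),
                                self.unit_kind, self.method, self.scale_factor, self.theta)


@dataclass
class FilterResult:
    counts: CountMatrix
    removal_log: pd.DataFrame  # columns: barcode, reason


def _mito_fraction(counts: CountMatrix, mito_prefix: str) -> np.ndarray:
    is_mito = np.array([g.startswith(mito_prefix) for g in counts.gene_ids])
    totals = counts.values.sum(axis=0)
    mito = counts.values[is_mito].sum(axis=0) if is_mito.any() else np.zeros(counts.n_units)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    return frac


def filter_cells(
    counts: CountMatrix,
    min_genes: int = 500,
    max_mito_frac: float = 0.05,
    mito_prefix: str = "MT-",
) -> FilterResult:
    """Drop cells expressing < min_genes genes or with > max_mito_frac mitochondrial counts."""
    n_expressed = (counts.values > 0).sum(axis=0)
    mito_frac = _mito_fraction(counts, mito_prefix)
    too_few = n_expressed < min_genes
    too_mito = mito_frac > max_mito_frac
    keep = ~(too_few | too_mito)
    if not keep.any():
        raise ValidationError("all cells removed by the quality filters")
    reasons = []
    for bc, few, mito in zip(counts.unit_ids, too_few, too_mito):
        if few and mito:
            reasons.append((bc, "few_genes;high_mito"))
        elif few:
            reasons.append((bc, "few_genes"))
        elif mito:
            reasons.append((bc, "high_mito"))
    kept_ids = [bc for bc, k in zip(counts.unit_ids, keep) if k]
    log = pd.DataFrame(reasons, columns=["barcode", "reason"])
    return FilterResult(counts.select_units(kept_ids), log)


def filter_spots(
    counts: CountMatrix,
    max_mito_frac: float = 0.05,
    mito_prefix: str = "MT-",
) -> FilterResult:
    """Drop spots with strictly more than max_mito_frac mitochondrial counts."""
    mito_frac = _mito_fraction(counts, mito_prefix)
    keep = mito_frac <= max_mito_frac
    if not keep.any():
        raise ValidationError("all spots removed by the mitochondrial filter")
    kept_ids = [bc for bc, k in zip(counts.unit_ids, keep) if k]
    log = pd.DataFrame(
        [(bc, "high_mito") for bc, k in zip(counts.unit_ids, keep) if not k],
        columns=["barcode", "reason"],
    )
    return FilterResult(counts.select_units(kept_ids), log)


def lognormalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """entry = ln(1 + count * scale_factor / unit_total)."""
    totals = counts.values.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.any():
        bad = [u for u, z in zip(counts.unit_ids, zero) if z][:5]
        raise ValidationError(f"units with zero total counts cannot be normalized: {bad}")
    vals = np.log1p(counts.values * (scale_factor / totals)[None, :])
    return NormalizedMatrix(vals, list(counts.gene_ids), list(counts.unit_ids),
                            counts.unit_kind, "lognorm", scale_factor=scale_factor)


def pearson_residual_normalize(counts: CountMatrix, theta: float = 100.0) -> NormalizedMatrix:
    """Analytic Pearson residuals under a rank-1 NB null with fixed dispersion theta.

    mu_gu = gene_total * unit_total / grand_total;
    residual = (x - mu) / sqrt(mu + mu^2/theta), clipped to +/- sqrt(n_units).
    """
    grand = counts.values.sum()
    if grand == 0:
        raise ValidationError("cannot normalize an all-zero matrix")
    x = counts.values.astype(float)
    mu = np.outer(x.sum(axis=1), x.sum(axis=0)) / grand
    with np.errstate(invalid="ignore", divide="ignore"):
        res = np.where(mu > 0, (x - mu) / np.sqrt(mu + mu**2 / theta), 0.0)
    clip = np.sqrt(counts.n_units)
    res = np.clip(res, -clip, clip)
    return NormalizedMatrix(res, list(counts.gene_ids), list(counts.unit_ids),
                            counts.unit_kind, "pearson_residual", theta=theta)
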