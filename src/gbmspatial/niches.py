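"""Niche selection and cell-type colocalization statistics.

The palisading-necrosis niche is the set of spots whose normalized VEGFA
expression exceeds a threshold (strictly greater than 3 by default);
perivascular and generic-tumor niches are annotation inputs.  Spots falling
in more than one niche are removed from all niches before downstream
analysis.  Pairwise Pearson correlations of deconvolved proportions, with
t-distribution p-values and Benjamini-Hochberg adjustment across all pairs,
classify each cell-type pair as segregating (r < 0), colocalizing (r > 0),
or not significant.

Caveat reported in the output metadata: proportions summing to 1 induce
some negative correlation a priori; the test is nevertheless run on the
proportions as estimated.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deconvolve import ProportionMatrix
from .io import RegionAnnotation
from .qc import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "select_necrosis_niche",
    "resolve_niche_overlaps",
    "pairwise_proportion_correlation",
    "bh_adjust",
]

COMPOSITIONAL_CAVEAT = (
    "proportions sum to 1 per spot, which induces negative correlation between "
    "types a priori; verdicts are reported on the raw Pearson test"
)


def select_necrosis_niche(
    norm_spots: NormalizedMatrix,
    gene: str = "VEGFA",
    threshold: float = 3.0,
) -> list[str]:
    """Spots with normalized expression of ``gene`` strictly greater than ``threshold``."""
    vals = norm_spots.gene_values(gene)
    return [bc for bc, v in zip(norm_spots.unit_ids, vals) if v > threshold]


def resolve_niche_overlaps(
    niches: Mapping[str, Sequence[str]],
    precedence: Sequence[str] | None = None,
) -> RegionAnnotation:
    """Remove any spot claimed by two or more niches from all of them.

    ``precedence`` fixes the label order in the output; overlap handling is
    removal, not reassignment.
    """
    order = list(precedence) if precedence is not None else list(niches.keys())
    sets = {label: set(niches[label]) for label in order}
    for label, spots in sets.items():
        if not spots:
            raise ValueError(f"niche {label!r} covers no spots")
    counts: dict[str, int] = {}
    for spots in sets.values():
        for s in spots:
            counts[s] = counts.get(s, 0) + 1
    overlapping = {s for s, c in counts.items() if c > 1}
    if overlapping:
        logger.info("%d spots in >1 niche removed from all niches", len(overlapping))
    records = []
    for label in order:
        for s in sorted(sets[label] - overlapping):
            records.append((s, label))
    ser = pd.Series({s: lab for s, lab in records}, name="label")
    return RegionAnnotation(ser)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def pairwise_proportion_correlation(
    props: ProportionMatrix | pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of every unordered type pair across spots.

    Returns one row per pair: r, two-sided p (t-distribution, n-2 df),
    BH-adjusted p across all pairs jointly, and a verdict
    (segregate / colocalize / ns).  Zero-variance columns yield NA rows
    excluded from the BH family.
    """
    if isinstance(props, ProportionMatrix):
        df = props.proportions.drop(index=props.excluded_spots)
    else:
        df = props
    if df.shape[0] < 3:
        raise ValueError("need at least 3 spots")
    if df.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    n = df.shape[0]
    rows = []
    for a, b in itertools.combinations(df.columns, 2):
        xa, xb = df[a].to_numpy(), df[b].to_numpy()
        if np.all(xa == xa[0]) or np.all(xb == xb[0]):
            logger.warning("pair (%s, %s) has a zero-variance column; excluded from BH", a, b)
            rows.append((a, b, np.nan, np.nan, np.nan, n, "ns"))
            continue
        r, pval = stats.pearsonr(xa, xb)
        rows.append((a, b, float(r), float(pval), np.nan, n, None))
    table = pd.DataFrame(rows, columns=["type_a", "type_b", "pearson_r", "p_value",
                                        "adj_p", "n_spots", "verdict"])
    mask = table["p_value"].notna()
    table.loc[mask, "adj_p"] = bh_adjust(table.loc[mask, "p_value"].to_numpy())
    for i in table.index[mask]:
        r, q = table.at[i, "pearson_r"], table.at[i, "adj_p"]
        if q < alpha and r < 0:
            table.at[i, "verdict"] = "segregate"
        elif q < alpha and r > 0:
            table.at[i, "verdict"] = "colocalize"
        else:
            table.at[i, "verdict"] = "ns"
    table.attrs["caveat"] = COMPOSITIONAL_CAVEAT
    table.attrs["alpha"] = alpha
    return table
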