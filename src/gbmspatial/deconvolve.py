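"""Spot deconvolution against a matched single-cell reference.

Per-type signature profiles are normalized pseudo-bulk rates (types built
from fewer than ``min_cells`` cells are dropped, matching the 25-cell
reference minimum).  Each spot's type proportions maximize a Poisson
mixture likelihood on the simplex via multiplicative EM updates, which are
monotone in the log-likelihood by construction.  Platform effects,
type-specific dispersion and doublet modes are deliberately not modeled;
downstream analyses consume only the proportion estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["SignatureProfiles", "ProportionMatrix", "build_signatures", "deconvolve"]


@dataclass
class SignatureProfiles:
    """Types x genes mean expression rates; each row sums to 1."""

    profiles: pd.DataFrame
    cells_per_type: pd.Series
    dropped_types: list[str]

    def __post_init__(self) -> None:
        rowsum = self.profiles.to_numpy().sum(axis=1)
        if np.any(self.profiles.to_numpy() < 0) or np.any(np.abs(rowsum - 1) > 1e-9):
            raise ValueError("profile rows must be non-negative and sum to 1")


@dataclass
class ProportionMatrix:
    """Spots x types estimated mixing proportions (rows on the simplex)."""

    proportions: pd.DataFrame
    convergence: pd.DataFrame  # per spot: iterations, log_likelihood, converged
    excluded_spots: list[str]  # zero-total spots with undefined proportions

    def __post_init__(self) -> None:
        vals = self.proportions.to_numpy()
        if np.any(vals < -1e-12) or np.any(np.abs(vals.sum(axis=1) - 1) > 1e-6):
            raise ValueError("proportion rows must be non-negative and sum to 1")


def build_signatures(
    ref_counts: CountMatrix,
    type_labels: pd.Series | Mapping[str, str],
    min_cells: int = 25,
    pseudocount: float = 1e-9,
) -> SignatureProfiles:
    """Pseudo-bulk per-type rates; types with < min_cells cells are dropped."""
    labels = pd.Series(type_labels)
    missing = set(ref_counts.unit_ids) - set(labels.index)
    if missing:
        raise ValueError(f"cells without a type label: {sorted(missing)[:5]}")
    labels = labels.loc[ref_counts.unit_ids]
    counts_per_type = labels.value_counts()
    kept = counts_per_type[counts_per_type >= min_cells].index.tolist()
    dropped = sorted(set(counts_per_type.index) - set(kept))
    if dropped:
        logger.warning("types dropped for having < %d cells: %s", min_cells, dropped)
    if len(kept) < 2:
        raise ValueError("fewer than 2 cell types retained in the reference")
    rows = {}
    for t in kept:
        cells = labels.index[labels == t]
        pos = pd.Index(ref_counts.unit_ids).get_indexer(cells)
        summed = ref_counts.values[:, pos].sum(axis=1).astype(float) + pseudocount
        rows[t] = summed / summed.sum()
    profiles = pd.DataFrame(rows, index=ref_counts.gene_ids).T
    return SignatureProfiles(profiles, counts_per_type.loc[kept], dropped)


def deconvolve(
    spot_counts: CountMatrix,
    profiles: SignatureProfiles,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> ProportionMatrix:
    """Poisson-mixture maximum likelihood on the simplex via multiplicative EM.

    Per spot with counts y and profile rates mu_t, maximizes
    sum_g y_g log(sum_t w_t mu_tg) over the simplex; the second Poisson term
    is constant because profile rows sum to 1.  The update
    w_t <- w_t * sum_g y_g mu_tg / (sum_u w_u mu_ug) / sum_g y_g
    never decreases the log-likelihood (asserted on every run).
    """
    shared = [g for g in spot_counts.gene_ids if g in set(profiles.profiles.columns)]
    if not shared:
        raise ValueError("no shared genes between spots and reference profiles")
    if len(shared) < spot_counts.n_genes:
        logger.info("using %d/%d shared genes", len(shared), spot_counts.n_genes)
    gpos = pd.Index(spot_counts.gene_ids).get_indexer(shared)
    y = spot_counts.values[gpos, :].T.astype(float)                  # spots x genes
    mu = profiles.profiles[shared].to_numpy()                         # types x genes
    mu = np.maximum(mu, 1e-300)
    n_spots, n_types = y.shape[0], mu.shape[0]

    totals = y.sum(axis=1)
    zero = totals == 0
    excluded = [bc for bc, z in zip(spot_counts.unit_ids, zero) if z]
    if excluded:
        logger.warning("%d zero-total spots excluded from deconvolution", len(excluded))
    active_idx = (~zero).nonzero()[0]
    ya = y[active_idx]
    ta = totals[active_idx]

    w = np.full((len(active_idx), n_types), 1.0 / n_types)
    iters = np.zeros(len(active_idx), dtype=int)
    done = np.zeros(len(active_idx), dtype=bool)

    def loglik(wm: np.ndarray) -> np.ndarray:
        mix = wm @ mu
        return np.where(ya > 0, ya * np.log(np.maximum(mix, 1e-300)), 0.0).sum(axis=1) - ta

    ll = loglik(w)
    for it in range(1, max_iter + 1):
        if done.all():
            break
        act = ~done
        mix = w[act] @ mu
        ratio = ya[act] / np.maximum(mix, 1e-300)
        w_new = w[act] * (ratio @ mu.T) / ta[act][:, None]
        w_new /= w_new.sum(axis=1, keepdims=True)
        w[act] = w_new
        ll_new = loglik(w)
        if np.any(ll_new[act] < ll[act] - 1e-6 * np.abs(ll[act])):
            raise AssertionError("EM log-likelihood decreased")
        rel = np.abs(ll_new - ll) / np.maximum(np.abs(ll_new), 1e-300)
        newly = act & (rel < tol)
        iters[act] = it
        done |= newly
        ll = ll_new

    full_w = np.full((n_spots, n_types), np.nan)
    full_w[active_idx] = w
    # excluded rows are kept out of the simplex check by filling uniformly; they
    # are listed in excluded_spots and must be ignored downstream
    full_w[zero] = 1.0 / n_types
    props = pd.DataFrame(full_w, index=spot_counts.unit_ids, columns=profiles.profiles.index)
    conv = pd.DataFrame(
        {
            "iterations": pd.Series(iters, index=np.array(spot_counts.unit_ids)[active_idx]),
            "log_likelihood": pd.Series(ll, index=np.array(spot_counts.unit_ids)[active_idx]),
            "converged": pd.Series(done, index=np.array(spot_counts.unit_ids)[active_idx]),
        }
    )
    return ProportionMatrix(props, conv, excluded)
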