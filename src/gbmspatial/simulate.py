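"""Synthetic paired single-nucleus + spatial transcriptomics generator.

Generates a reference of single cells (four glioblastoma tumor states plus
non-tumor brain cell types) and a matched slide of spots, with known ground
truth for every quantity the pipeline estimates: per-cell type labels,
marker programs, chromosome-scale expression fold-changes (the canonical
chr7 gain / chr10 loss of glioblastoma), per-spot mixing proportions,
spatially segregated tumor-state territories, a necrotic focus with a VEGFA
expression gradient and macrophage enrichment, and vessel loci with
endothelial and OPC-like enrichment.

The noise model is negative binomial per cell (var = mu + mu^2/theta) and
spots are sums of per-cell draws; because i.i.d. negative-binomial draws
with a shared dispersion add (Gamma shapes add under a common scale), the
per-(spot, type) sum is drawn directly as NB(n * mu, n * theta).

Randomness comes from three named substreams derived deterministically from
the seed (model, reference, spatial), each consumed in a fixed documented
order, so a given seed + config always reproduces every output and the
spatial stage can be rerun without replaying the reference draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneMeta, RegionAnnotation, SpotGeometry, DEFAULT_CHROMOSOMES

__all__ = [
    "CNVEvent",
    "SimulationConfig",
    "GroundTruth",
    "GRADIENT_ORDER",
    "TUMOR_STATES",
    "simulate_reference",
    "simulate_spatial",
    "expression_model",
]

TUMOR_STATES: tuple[str, ...] = ("MES-like", "AC-like", "OPC-like", "NPC-like")

#: Ordered gradient-of-regions vocabulary, from the necrotic focus outward
#: to the vessels (eight bands).
GRADIENT_ORDER: tuple[str, ...] = (
    "necrosis",
    "palisade",
    "layer1_around_palisade",
    "layer2_around_palisade",
    "generic_tumor",
    "layer2_around_vessel",
    "layer1_around_vessel",
    "perivascular",
)


class CNVEvent(NamedTuple):
    chromosome: str
    fold_change: float
    affected_types: tuple[str, ...]


def _default_cells() -> dict[str, int]:
    return {
        "MES-like": 200, "AC-like": 200, "OPC-like": 200, "NPC-like": 200,
        "macrophage": 150, "oligodendrocyte": 120, "endothelial": 80, "neuron": 80,
    }


def _default_cnv() -> tuple[CNVEvent, ...]:
    return (
        CNVEvent("7", 1.5, TUMOR_STATES),
        CNVEvent("10", 0.5, TUMOR_STATES),
    )


def _default_background() -> dict[str, float]:
    return {"macrophage": 0.10, "oligodendrocyte": 0.10, "endothelial": 0.05, "neuron": 0.10}


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines every output."""

    n_genes: int = 2000
    cell_types: tuple[str, ...] = TUMOR_STATES + ("macrophage", "oligodendrocyte", "endothelial", "neuron")
    n_cells_per_type: Mapping[str, int] = field(default_factory=_default_cells)
    marker_genes_per_type: int = 25
    marker_fold_change: float = 4.0
    baseline_shape: float = 2.0      # Gamma shape of per-gene baseline means
    baseline_scale: float = 0.5      # Gamma scale; mean expression per gene = shape * scale
    nb_dispersion: float = 10.0      # NB theta; var = mu + mu^2 / theta
    libsize_sigma: float = 0.25      # lognormal sd of per-cell / per-spot size factors
    n_mito_genes: int = 10
    mito_fraction: float = 0.02      # expected fraction of counts on MT- genes
    n_ribosomal_genes: int = 8
    cnv_events: tuple[CNVEvent, ...] = field(default_factory=_default_cnv)
    # spatial layer
    grid_shape: tuple[int, int] = (24, 24)
    cells_per_spot: int | tuple[int, int] = 10
    territory_map: Mapping[tuple[tuple[int, int], tuple[int, int]], tuple[str, ...]] | None = None
    tumor_weight: float = 0.65
    background_weights: Mapping[str, float] = field(default_factory=_default_background)
    necrosis_center: tuple[float, float] | None = None  # defaults to grid center
    necrosis_radius: float = 3.0
    vessel_loci: tuple[tuple[float, float], ...] | None = None  # defaults to four off-center points
    macrophage_necrosis_boost: float = 0.6
    tau_necrosis: float = 3.0
    endothelial_vessel_boost: float = 0.5
    opc_vessel_boost: float = 0.35
    tau_vessel: float = 2.0
    vegfa_gain_at_necrosis: float = 8.0
    tau_vegfa: float = 3.0
    n_niche_effect_genes: int = 0    # genes with a planted per-cell necrosis-niche effect
    niche_effect_logfc: float = 1.0  # natural-log fold planted in those genes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_fold_change <= 0:
            raise ValueError("marker_fold_change must be > 0")
        for ev in self.cnv_events:
            if ev.fold_change <= 0:
                raise ValueError("CNV fold changes must be > 0")
        for t in self.cell_types:
            if self.n_cells_per_type.get(t, 0) < 1:
                raise ValueError(f"cell type {t!r} needs at least 1 cell")

    @property
    def tumor_states(self) -> tuple[str, ...]:
        return tuple(t for t in self.cell_types if t in TUMOR_STATES)

    def grid_center(self) -> tuple[float, float]:
        if self.necrosis_center is not None:
            return self.necrosis_center
        r, c = self.grid_shape
        return ((r - 1) / 2.0, (c - 1) / 2.0)

    def vessels(self) -> tuple[tuple[float, float], ...]:
        if self.vessel_loci is not None:
            return self.vessel_loci
        r, c = self.grid_shape
        dr, dc = max(2, r // 6), max(2, c // 6)
        return ((dr, dc), (dr, c - 1 - dc), (r - 1 - dr, dc), (r - 1 - dr, c - 1 - dc))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    cell_types: pd.Series | None = None            # cell barcode -> type
    markers: dict[str, list[str]] = field(default_factory=dict)
    cnv_truth: dict[tuple[str, str], float] = field(default_factory=dict)  # (type, chrom) -> fold
    niche_effect_genes: list[str] = field(default_factory=list)
    proportions: pd.DataFrame | None = None        # spots x types, rows on the simplex
    regions: pd.Series | None = None               # spot barcode -> gradient region label
    niches: pd.Series | None = None                # spot barcode -> niche label


# ---------------------------------------------------------------------------
# expression model


# approximate protein-coding gene counts per autosome (gene density is not
# proportional to chromosome length: 17/19/22 are gene-dense, 13/18/21 sparse)
_AUTOSOME_GENE_COUNTS = (
    2058, 1309, 1078, 752, 876, 1048, 989, 677, 786, 733, 1298,
    1034, 327, 830, 613, 873, 1197, 270, 1472, 544, 234, 488,
)


def _chromosome_sizes(n_genes: int) -> dict[str, int]:
    """Allocate autosomal genes proportional to real per-chromosome gene counts."""
    weights = np.array(_AUTOSOME_GENE_COUNTS, dtype=float)
    alloc = np.floor(weights / weights.sum() * n_genes).astype(int)
    alloc[0] += n_genes - alloc.sum()
    return {str(i + 1): int(alloc[i]) for i in range(22)}


@dataclass
class ExpressionModel:
    gene_ids: list[str]
    gene_meta: GeneMeta
    base_mean: np.ndarray                  # per-gene baseline
    type_means: pd.DataFrame               # genes x types mean expression
    markers: dict[str, list[str]]
    niche_effect_genes: list[str]
    vegfa_index: int
    mito_genes: list[str]
    ribosomal_genes: list[str]


def expression_model(config: SimulationConfig) -> ExpressionModel:
    """Deterministic (given seed) per-type mean-expression model."""
    rng = np.random.default_rng([config.seed, 0])
    n_auto = config.n_genes - config.n_mito_genes
    if n_auto < 50:
        raise ValueError("n_genes too small for the gene layout")
    sizes = _chromosome_sizes(n_auto)
    gene_ids, chroms, starts = [], [], []
    i = 0
    for chrom, size in sizes.items():
        for j in range(size):
            gene_ids.append(f"GENE{i:05d}")
            chroms.append(chrom)
            starts.append(j * 10_000)
            i += 1
    # name a VEGFA gene and a few ribosomal genes among the autosomal ones
    special = rng.choice(n_auto, size=1 + config.n_ribosomal_genes, replace=False)
    vegfa_index = int(special[0])
    gene_ids[vegfa_index] = "VEGFA"
    ribosomal = []
    for k, idx in enumerate(special[1:]):
        name = (f"RPL{k + 1}" if k % 2 == 0 else f"RPS{k + 1}")
        gene_ids[int(idx)] = name
        ribosomal.append(name)
    mito = [f"MT-G{k + 1}" for k in range(config.n_mito_genes)]
    gene_ids = gene_ids + mito
    chroms = chroms + ["MT"] * config.n_mito_genes
    starts = starts + [k * 1000 for k in range(config.n_mito_genes)]
    meta = GeneMeta(pd.DataFrame({"gene_id": gene_ids, "chromosome": chroms, "start": starts}))

    base = rng.gamma(config.baseline_shape, config.baseline_scale, size=config.n_genes)
    base = np.maximum(base, 1e-4)
    base[vegfa_index] = max(base[vegfa_index], 2.0)
    # MT- genes get a mean chosen so they carry ~mito_fraction of the counts
    f = config.mito_fraction
    auto_total = base[:n_auto].sum()
    base[n_auto:] = auto_total * f / ((1 - f) * config.n_mito_genes)

    eligible = [g for g in range(n_auto) if gene_ids[g] not in set(ribosomal) | {"VEGFA"}]
    need = config.marker_genes_per_type * len(config.cell_types)
    if need > len(eligible):
        raise ValueError("not enough genes for disjoint marker programs")
    picked = rng.choice(eligible, size=need, replace=False)
    markers: dict[str, list[str]] = {}
    fold = np.ones((config.n_genes, len(config.cell_types)))
    for ti, t in enumerate(config.cell_types):
        idx = picked[ti * config.marker_genes_per_type:(ti + 1) * config.marker_genes_per_type]
        markers[t] = [gene_ids[j] for j in idx]
        fold[idx, ti] = config.marker_fold_change
    for ev in config.cnv_events:
        on_chrom = np.array([c == ev.chromosome for c in chroms])
        for t in ev.affected_types:
            if t in config.cell_types:
                fold[on_chrom, list(config.cell_types).index(t)] *= ev.fold_change

    niche_genes: list[str] = []
    if config.n_niche_effect_genes:
        remaining = [g for g in eligible if g not in set(int(p) for p in picked)]
        chosen = rng.choice(remaining, size=config.n_niche_effect_genes, replace=False)
        niche_genes = [gene_ids[int(j)] for j in chosen]

    type_means = pd.DataFrame(base[:, None] * fold, index=gene_ids, columns=list(config.cell_types))
    return ExpressionModel(gene_ids, meta, base, type_means, markers, niche_genes, vegfa_index, mito, ribosomal)


# ---------------------------------------------------------------------------
# reference (single-nucleus) simulation


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, shape: np.ndarray | float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + mu^2/shape; shape may broadcast."""
    lam = rng.gamma(np.broadcast_to(shape, mean.shape), mean / shape)
    return rng.poisson(lam)


def simulate_reference(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw the single-nucleus reference: NB counts per cell with marker and CNV folds."""
    model = expression_model(config)
    rng = np.random.default_rng([config.seed, 1])
    blocks, labels, barcodes = [], [], []
    cell_i = 0
    for t in config.cell_types:
        n_t = config.n_cells_per_type[t]
        lib = rng.lognormal(-config.libsize_sigma**2 / 2, config.libsize_sigma, size=n_t)
        mu = model.type_means[t].to_numpy()[:, None] * lib[None, :]
        blocks.append(_nb_draw(rng, mu, config.nb_dispersion))
        labels.extend([t] * n_t)
        barcodes.extend(f"CELL{cell_i + k:05d}" for k in range(n_t))
        cell_i += n_t
    counts = CountMatrix(np.concatenate(blocks, axis=1), model.gene_ids, barcodes, "cell")
    truth = GroundTruth(
        cell_types=pd.Series(labels, index=barcodes, name="cell_type"),
        markers=model.markers,
        cnv_truth={(t, ev.chromosome): ev.fold_change
                   for ev in config.cnv_events for t in ev.affected_types if t in config.cell_types},
        niche_effect_genes=list(model.niche_effect_genes),
    )
    return counts, truth


# ---------------------------------------------------------------------------
# spatial simulation


def _default_territories(config: SimulationConfig):
    """Quadrant blocks assigned to the tumor states in declared order."""
    r, c = config.grid_shape
    states = config.tumor_states
    if not states:
        raise ValueError("no tumor states among the configured cell types")
    blocks = [((0, (r + 1) // 2), (0, (c + 1) // 2)),
              ((0, (r + 1) // 2), ((c + 1) // 2, c)),
              (((r + 1) // 2, r), (0, (c + 1) // 2)),
              (((r + 1) // 2, r), ((c + 1) // 2, c))]
    return {blocks[i]: (states[i % len(states)],) for i in range(4)}


def _territory_state(territories, row: int, col: int) -> tuple[str, ...]:
    for ((r0, r1), (c0, c1)), states in territories.items():
        if r0 <= row < r1 and c0 <= col < c1:
            return tuple(states) if isinstance(states, (tuple, list)) else (states,)
    raise ValueError(f"territory map does not cover grid position ({row}, {col})")


def _region_label(d_necrosis: float, d_vessel: float, config: SimulationConfig) -> str:
    r = config.necrosis_radius
    if d_necrosis <= r:
        return "necrosis"
    if d_necrosis <= r + 1.5:
        return "palisade"
    if d_necrosis <= r + 3.0:
        return "layer1_around_palisade"
    if d_necrosis <= r + 4.5:
        return "layer2_around_palisade"
    if d_vessel <= 1.2:
        return "perivascular"
    if d_vessel <= 2.4:
        return "layer1_around_vessel"
    if d_vessel <= 3.6:
        return "layer2_around_vessel"
    return "generic_tumor"


def _niche_label(d_necrosis: float, d_vessel: float, config: SimulationConfig) -> str:
    if d_necrosis <= config.necrosis_radius + 1.5:
        return "palisading_necrosis"
    if d_vessel <= 1.2:
        return "perivascular"
    return "generic_tumor"


def vegfa_multiplier(distance: np.ndarray | float, config: SimulationConfig) -> np.ndarray | float:
    """Hypoxia-driven VEGFA gain: `gain` at the necrotic focus decaying to 1 far away."""
    g = config.vegfa_gain_at_necrosis
    return 1.0 + (g - 1.0) * np.exp(-np.asarray(distance, dtype=float) / config.tau_vegfa)


def spot_composition_weights(config: SimulationConfig) -> pd.DataFrame:
    """Expected (pre-multinomial) cell-type weights per grid spot, rows normalized."""
    rows, cols = config.grid_shape
    territories = config.territory_map or _default_territories(config)
    center = config.grid_center()
    vessels = np.array(config.vessels(), dtype=float)
    types = list(config.cell_types)
    out = np.zeros((rows * cols, len(types)))
    for s, (i, j) in enumerate((i, j) for i in range(rows) for j in range(cols)):
        d_n = float(np.hypot(i - center[0], j - center[1]))
        d_v = float(np.min(np.hypot(vessels[:, 0] - i, vessels[:, 1] - j)))
        w = {t: 0.0 for t in types}
        states = _territory_state(territories, i, j)
        for st in states:
            if st not in w:
                raise ValueError(f"territory state {st!r} is not a configured cell type")
            w[st] += config.tumor_weight / len(states)
        for t, bw in config.background_weights.items():
            if t in w:
                w[t] += bw
        if "macrophage" in w:
            w["macrophage"] += config.macrophage_necrosis_boost * np.exp(-d_n / config.tau_necrosis)
        if "endothelial" in w:
            w["endothelial"] += config.endothelial_vessel_boost * np.exp(-d_v / config.tau_vessel)
        if "OPC-like" in w:
            w["OPC-like"] += config.opc_vessel_boost * np.exp(-d_v / config.tau_vessel)
        vec = np.array([w[t] for t in types])
        out[s] = vec / vec.sum()
    barcodes = [f"SPOT{i:03d}x{j:03d}" for i in range(rows) for j in range(cols)]
    return pd.DataFrame(out, index=barcodes, columns=types)


def simulate_spatial(
    config: SimulationConfig,
    reference_truth: GroundTruth | None = None,
) -> tuple[CountMatrix, SpotGeometry, GroundTruth]:
    """Draw the spatial slide: spots are sums of per-cell NB draws.

    Each in-tissue spot receives ``cells_per_spot`` cells whose types are
    multinomial in the territory- and niche-driven weights; the realized
    composition is recorded as the true proportion vector.  VEGFA's mean is
    multiplied by a gain decaying with distance from the necrotic focus, and
    planted niche-effect genes are upregulated in palisading-necrosis spots
    in every cell type.
    """
    model = expression_model(config)
    rng = np.random.default_rng([config.seed, 2])
    rows, cols = config.grid_shape
    n_spots = rows * cols
    types = list(config.cell_types)
    weights = spot_composition_weights(config)
    barcodes = weights.index.tolist()

    center = config.grid_center()
    vessels = np.array(config.vessels(), dtype=float)
    grid = np.array([(i, j) for i in range(rows) for j in range(cols)], dtype=float)
    d_n = np.hypot(grid[:, 0] - center[0], grid[:, 1] - center[1])
    d_v = np.min(np.hypot(vessels[None, :, 0] - grid[:, [0]], vessels[None, :, 1] - grid[:, [1]]), axis=1)

    if isinstance(config.cells_per_spot, tuple):
        lo, hi = config.cells_per_spot
        n_cells = rng.integers(lo, hi + 1, size=n_spots)
    else:
        n_cells = np.full(n_spots, int(config.cells_per_spot))
    comp = np.zeros((n_spots, len(types)), dtype=np.int64)
    for s in range(n_spots):
        comp[s] = rng.multinomial(n_cells[s], weights.iloc[s].to_numpy())
    props = comp / comp.sum(axis=1, keepdims=True)

    regions = pd.Series([_region_label(a, b, config) for a, b in zip(d_n, d_v)],
                        index=barcodes, name="region")
    niches = pd.Series([_niche_label(a, b, config) for a, b in zip(d_n, d_v)],
                       index=barcodes, name="niche")

    # per-spot expression means: linear in the realized composition
    mu_types = model.type_means.to_numpy()            # genes x types
    spot_sizes = rng.lognormal(-config.libsize_sigma**2 / 2, config.libsize_sigma, size=n_spots)
    counts = np.zeros((config.n_genes, n_spots), dtype=np.int64)
    vegfa_row = model.gene_ids.index("VEGFA")
    niche_rows = [model.gene_ids.index(g) for g in model.niche_effect_genes]
    in_niche = (niches == "palisading_necrosis").to_numpy()
    vegfa_gain = np.asarray(vegfa_multiplier(d_n, config))
    theta = config.nb_dispersion
    for ti in range(len(types)):
        n_t = comp[:, ti]
        active = n_t > 0
        if not active.any():
            continue
        mu = mu_types[:, [ti]] * (n_t[active] * spot_sizes[active])[None, :]
        mu = mu.copy()
        mu[vegfa_row, :] *= vegfa_gain[active]
        if niche_rows:
            boost = np.where(in_niche[active], np.exp(config.niche_effect_logfc), 1.0)
            mu[niche_rows, :] *= boost[None, :]
        counts[:, active] += _nb_draw(rng, mu, (theta * n_t[active])[None, :])

    geom = SpotGeometry(
        unit_ids=barcodes,
        array_row=grid[:, 0].astype(int),
        array_col=grid[:, 1].astype(int),
        x=grid[:, 1] * 100.0,
        y=grid[:, 0] * 100.0,
        in_tissue=np.ones(n_spots, dtype=bool),
    )
    truth = GroundTruth(
        cell_types=reference_truth.cell_types if reference_truth else None,
        markers=model.markers,
        cnv_truth={(t, ev.chromosome): ev.fold_change
                   for ev in config.cnv_events for t in ev.affected_types if t in config.cell_types},
        niche_effect_genes=list(model.niche_effect_genes),
        proportions=pd.DataFrame(props, index=barcodes, columns=types),
        regions=regions,
        niches=niches,
    )
    return CountMatrix(counts, model.gene_ids, barcodes, "spot"), geom, truth
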