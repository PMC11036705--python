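"""Configuration-driven orchestration of the full analysis flow.

simulate -> qc -> score -> cnv -> deconvolve -> niches -> coloc -> deg ->
gradient, with every printed constant of the analysis (500 expressed genes,
5% mitochondrial, VEGFA > 3, 25-cell reference minimum, alpha 0.05, top 10
gradient genes, top 100 enrichment genes) surfaced as a named config key.
Each run writes CSV/JSON artifacts plus a manifest recording the config
hash, seed, package versions, and per-step record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cellstate import SignatureSet, assign_cluster_states, lineage_score
from .cnv import call_chromosome_events, infer_cnv_profile
from .de import build_design, compare_logfc, fit_deg, select_top_genes
from .deconvolve import build_signatures, deconvolve
from .io import RegionAnnotation, write_counts_mtx, write_gene_meta, write_region_annotation, write_spot_positions
from .niches import pairwise_proportion_correlation, resolve_niche_overlaps, select_necrosis_niche
from .qc import filter_cells, filter_spots, lognormalize, pearson_residual_normalize
from .simulate import GRADIENT_ORDER, SimulationConfig, expression_model, simulate_reference, simulate_spatial
from . import gradient as _gradient_mod

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STEP_ORDER"]

STEP_ORDER = ("simulate", "qc", "score", "cnv", "deconvolve", "niches", "coloc", "deg", "gradient")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    steps: tuple[str, ...] = STEP_ORDER
    # qc
    min_genes: int = 500
    max_mito_frac: float = 0.05
    mito_prefix: str = "MT-"
    scale_factor: float = 1e4
    pearson_theta: float = 100.0
    # cnv
    cnv_window: int = 101
    cnv_clip: float = 3.0
    gain_thresh: float = 0.1
    loss_thresh: float = -0.1
    # deconvolution
    min_cells: int = 25
    max_iter: int = 500
    tol: float = 1e-8
    # niches / stats
    vegfa_gene: str = "VEGFA"
    vegfa_threshold: float = 3.0
    alpha: float = 0.05
    # gradient / enrichment exports
    n_top_gradient: int = 10
    n_top_enrichment: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.steps) - set(STEP_ORDER)
        if unknown:
            raise ValueError(f"unknown pipeline steps: {sorted(unknown)}")
        if self.simulation.seed != self.seed:
            self.simulation = replace(self.simulation, seed=self.seed)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, Mapping):
            sim = dict(sim)
            if "cnv_events" in sim:
                from .simulate import CNVEvent
                sim["cnv_events"] = tuple(
                    CNVEvent(str(c), float(f), tuple(t)) for c, f, t in sim["cnv_events"]
                )
            for key in ("cell_types", "grid_shape", "cells_per_spot", "vessel_loci", "necrosis_center"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(tuple(v) if isinstance(v, list) else v for v in sim[key]) \
                        if key == "vessel_loci" else tuple(sim[key])
            sim = SimulationConfig(**sim)
        if "steps" in d:
            d["steps"] = tuple(d["steps"])
        return cls(simulation=sim, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d, default=str))

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_jsonable(), sort_keys=True).encode()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the enabled steps in order, writing artifacts and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STEP_ORDER if s in set(config.steps)]
    state: dict[str, Any] = {}
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"gbmspatial": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "steps": {},
    }
    for step in enabled:
        t0 = time.perf_counter()
        try:
            records = _STEPS[step](config, state, outdir)
        except Exception as exc:  # noqa: BLE001 - abort naming the failing step
            manifest["steps"][step] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, outdir)
            raise RuntimeError(f"pipeline step {step!r} failed: {exc}") from exc
        manifest["steps"][step] = {
            "status": "complete",
            "seconds": round(time.perf_counter() - t0, 3),
            **records,
        }
        logger.info("step %s complete (%.1fs)", step, time.perf_counter() - t0)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# steps


def _step_simulate(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    ref_counts, ref_truth = simulate_reference(cfg.simulation)
    spot_counts, geom, truth = simulate_spatial(cfg.simulation, ref_truth)
    model = expression_model(cfg.simulation)
    st.update(ref_counts=ref_counts, ref_truth=ref_truth, spot_counts=spot_counts,
              geometry=geom, truth=truth, gene_meta=model.gene_meta, markers=model.markers)
    write_counts_mtx(ref_counts, outdir / "reference_counts")
    write_counts_mtx(spot_counts, outdir / "spatial_counts")
    write_spot_positions(geom, outdir / "spot_positions.csv")
    write_gene_meta(model.gene_meta, outdir / "gene_meta.csv")
    truth.proportions.to_csv(outdir / "true_proportions.csv")
    truth.regions.rename_axis("barcode").to_csv(outdir / "true_regions.csv")
    truth.niches.rename_axis("barcode").to_csv(outdir / "true_niches.csv")
    ref_truth.cell_types.rename_axis("barcode").to_csv(outdir / "cell_types.csv")
    return {"n_cells": ref_counts.n_units, "n_spots": spot_counts.n_units, "n_genes": ref_counts.n_genes}


def _step_qc(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    cells = filter_cells(st["ref_counts"], cfg.min_genes, cfg.max_mito_frac, cfg.mito_prefix)
    spots = filter_spots(st["spot_counts"], cfg.max_mito_frac, cfg.mito_prefix)
    cells.removal_log.to_csv(outdir / "removed_cells.csv", index=False)
    spots.removal_log.to_csv(outdir / "removed_spots.csv", index=False)
    st["cells"] = cells.counts
    st["spots"] = spots.counts
    st["ref_lognorm"] = lognormalize(cells.counts, cfg.scale_factor)
    st["spot_norm"] = pearson_residual_normalize(spots.counts, cfg.pearson_theta)
    return {"cells_removed": len(cells.removal_log), "spots_removed": len(spots.removal_log),
            "cells_kept": cells.counts.n_units, "spots_kept": spots.counts.n_units}


def _tumor_signatures(cfg: PipelineConfig, st: dict) -> SignatureSet:
    states = [t for t in cfg.simulation.tumor_states]
    return SignatureSet(tuple(states), {s: st["markers"][s] for s in states})


def _step_score(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    sigs = _tumor_signatures(cfg, st)
    table = lineage_score(st["ref_lognorm"], sigs)
    clusters = st["ref_truth"].cell_types.loc[table.scores.index]
    tumor_cells = clusters[clusters.isin(sigs.states)].index
    completed = assign_cluster_states(
        _subset_scores(table, tumor_cells), clusters.loc[tumor_cells])
    table.scores.rename_axis("barcode").to_csv(outdir / "lineage_scores.csv")
    out = completed.cluster_mean_scores.copy()
    out["assigned_state"] = completed.cluster_state
    out.rename_axis("cluster").to_csv(outdir / "cluster_states.csv")
    st["cluster_states"] = completed
    return {"n_clusters": len(out), "ties": len(completed.ties)}


def _subset_scores(table, cells):
    from .cellstate import LineageScoreTable
    return LineageScoreTable(scores=table.scores.loc[cells])


def _step_cnv(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    truth_types = st["ref_truth"].cell_types
    tumor = set(cfg.simulation.tumor_states)
    cells = st["ref_lognorm"].unit_ids
    normals = [c for c in cells if truth_types[c] not in tumor]
    profile = infer_cnv_profile(st["ref_lognorm"], st["gene_meta"], normals,
                                cfg.cnv_window, cfg.cnv_clip)
    # tumor vs pooled normal: individual normal types deviate from a mixed
    # reference through their own marker programs, which is not copy number
    groups = pd.Series(np.where(truth_types.loc[cells].isin(tumor), "tumor", "normal"),
                       index=cells)
    calls = call_chromosome_events(profile, groups, cfg.gain_thresh, cfg.loss_thresh)
    calls.to_csv(outdir / "cnv_calls.csv", index=False)
    st["cnv_profile"], st["cnv_calls"] = profile, calls
    return {"n_chromosomes": calls["chromosome"].nunique(),
            "gains": int((calls["call"] == "gain").sum()),
            "losses": int((calls["call"] == "loss").sum())}


def _step_deconvolve(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    labels = st["ref_truth"].cell_types.loc[st["cells"].unit_ids]
    profiles = build_signatures(st["cells"], labels, cfg.min_cells)
    props = deconvolve(st["spots"], profiles, cfg.max_iter, cfg.tol)
    props.proportions.rename_axis("barcode").to_csv(outdir / "proportions.csv")
    props.convergence.rename_axis("barcode").to_csv(outdir / "convergence.csv")
    st["profiles"], st["props"] = profiles, props
    return {"n_types": profiles.profiles.shape[0], "dropped_types": profiles.dropped_types,
            "excluded_spots": len(props.excluded_spots)}


def _step_niches(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    necrosis = select_necrosis_niche(st["spot_norm"], cfg.vegfa_gene, cfg.vegfa_threshold)
    truth_niches = st["truth"].niches.loc[[b for b in st["spots"].unit_ids]]
    perivascular = truth_niches.index[truth_niches == "perivascular"].tolist()
    generic = truth_niches.index[truth_niches == "generic_tumor"].tolist()
    ann = resolve_niche_overlaps(
        {"palisading_necrosis": necrosis, "perivascular": perivascular, "generic_tumor": generic},
        precedence=["palisading_necrosis", "perivascular", "generic_tumor"],
    )
    write_region_annotation(ann, outdir / "niche_annotation.csv")
    st["niche_annotation"] = ann
    return {"necrosis_spots": len(necrosis),
            "annotated_spots": len(ann.unit_ids)}


def _step_coloc(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    table = pairwise_proportion_correlation(st["props"], cfg.alpha)
    table.to_csv(outdir / "colocalization.csv", index=False)
    st["coloc"] = table
    return {"n_pairs": len(table),
            "segregating": int((table["verdict"] == "segregate").sum()),
            "colocalizing": int((table["verdict"] == "colocalize").sum())}


def _step_deg(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    ann = st["niche_annotation"]
    keep = [b for b in ann.unit_ids if ann.labels[b] in ("palisading_necrosis", "generic_tumor")]
    labels = ann.labels.loc[keep]
    results = {}
    for adjusted in (False, True):
        design = build_design(RegionAnnotation(labels), "palisading_necrosis",
                              props=st["props"].proportions.loc[keep] if adjusted else None,
                              tumor_states=cfg.simulation.tumor_states)
        deg = fit_deg(st["spot_norm"], design, alpha=cfg.alpha)
        tag = "adjusted" if adjusted else "unadjusted"
        deg.rename_axis("gene").to_csv(outdir / f"deg_necrosis_{tag}.csv")
        up, down = select_top_genes(deg, cfg.n_top_enrichment)
        pd.Series(up, name="gene").to_csv(outdir / f"top_up_{tag}.csv", index=False)
        pd.Series(down, name="gene").to_csv(outdir / f"top_down_{tag}.csv", index=False)
        results[tag] = deg
    st["deg"] = results
    return {"n_genes": len(results["adjusted"]),
            "significant_adjusted": int(results["adjusted"]["significant"].sum()),
            "significant_unadjusted": int(results["unadjusted"]["significant"].sum())}


def _step_gradient(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    regions = st["truth"].regions.loc[[b for b in st["spots"].unit_ids]]
    ann = RegionAnnotation(regions)
    order = [r for r in GRADIENT_ORDER if r in set(regions)]
    result = _gradient_mod.gradient_analysis(
        st["spot_norm"], ann, st["props"].proportions.loc[regions.index],
        region_order=order, n_top=cfg.n_top_gradient, alpha=cfg.alpha)
    for r, t in result.tables.items():
        t.rename_axis("gene").to_csv(outdir / f"gradient_deg_{r}.csv")
    pd.Series({r: ";".join(g) for r, g in result.top_genes.items()}, name="genes") \
        .rename_axis("region").to_csv(outdir / "gradient_top_genes.csv")
    result.gene_heatmap.rename_axis("gene").to_csv(outdir / "gradient_gene_heatmap.csv")
    result.celltype_heatmap.rename_axis("type").to_csv(outdir / "gradient_celltype_heatmap.csv")
    _gradient_mod.plot_gradient_heatmaps(result, str(outdir / "gradient_heatmap.png"))
    st["gradient"] = result
    return {"n_regions": len(result.region_order),
            "top_genes_total": sum(len(v) for v in result.top_genes.values())}


_STEPS = {
    "simulate": _step_simulate,
    "qc": _step_qc,
    "score": _step_score,
    "cnv": _step_cnv,
    "deconvolve": _step_deconvolve,
    "niches": _step_niches,
    "coloc": _step_coloc,
    "deg": _step_deg,
    "gradient": _step_gradient,
}
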