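"""Generator: determinism, planted structure, and agreement with the stated moments."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_sim_config
from gbmspatial.simulate import (
    SimulationConfig,
    expression_model,
    simulate_reference,
    simulate_spatial,
    spot_composition_weights,
    vegfa_multiplier,
)


def test_same_seed_is_bit_identical():
    cfg = small_sim_config(seed=3)
    ref_a, truth_a = simulate_reference(cfg)
    ref_b, truth_b = simulate_reference(cfg)
    np.testing.assert_array_equal(ref_a.values, ref_b.values)
    pd.testing.assert_series_equal(truth_a.cell_types, truth_b.cell_types)
    spa_a = simulate_spatial(cfg, truth_a)
    spa_b = simulate_spatial(cfg, truth_b)
    np.testing.assert_array_equal(spa_a[0].values, spa_b[0].values)
    pd.testing.assert_frame_equal(spa_a[2].proportions, spa_b[2].proportions)


def test_no_signal_null_types_exchangeable():
    """With marker fold 1 and no CNV, types are statistically indistinguishable:
    gene-wise two-sample tests between types reject at the nominal rate."""
    from scipy import stats
    from gbmspatial.qc import lognormalize

    cfg = small_sim_config(seed=5, marker_fold_change=1.0, cnv_events=(),
                           n_cells_per_type={t: 150 for t in
                                             ("MES-like", "AC-like", "OPC-like", "NPC-like",
                                              "macrophage", "oligodendrocyte", "endothelial",
                                              "neuron")})
    counts, truth = simulate_reference(cfg)
    expr = lognormalize(counts)
    labels = truth.cell_types
    for a, b in (("MES-like", "neuron"), ("AC-like", "macrophage")):
        ca = [i for i, u in enumerate(expr.unit_ids) if labels[u] == a]
        cb = [i for i, u in enumerate(expr.unit_ids) if labels[u] == b]
        p = stats.ttest_ind(expr.values[:, ca], expr.values[:, cb], axis=1).pvalue
        frac = (p < 0.05).mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(p)), (a, b, frac)


def test_planted_cnv_fold_recovered_in_raw_means(small_reference):
    """chr7 x1.5 in tumor cells: the raw tumor/normal chr7 mean ratio matches the model."""
    cfg, counts, truth = small_reference
    model = expression_model(cfg)
    markers = {g for v in truth.markers.values() for g in v}
    chr7 = [g for g in model.gene_meta.table.query("chromosome == '7'")["gene_id"]
            if g not in markers]
    rows = [counts.gene_ids.index(g) for g in chr7]
    labels = truth.cell_types
    tumor = [i for i, u in enumerate(counts.unit_ids) if labels[u] in cfg.tumor_states]
    normal = [i for i, u in enumerate(counts.unit_ids) if labels[u] not in cfg.tumor_states]
    ratio = counts.values[np.ix_(rows, tumor)].mean() / counts.values[np.ix_(rows, normal)].mean()
    # markers perturb individual genes; chromosome-wide the CNV fold dominates
    assert abs(ratio - 1.5) < 0.15


def test_type_count_below_one_rejected():
    with pytest.raises(ValueError):
        small_sim_config(n_cells_per_type={"MES-like": 0, "AC-like": 10, "OPC-like": 10,
                                           "NPC-like": 10, "macrophage": 10,
                                           "oligodendrocyte": 10, "endothelial": 10,
                                           "neuron": 10})


def test_true_proportions_on_simplex(small_spatial):
    _, _, _, truth = small_spatial
    np.testing.assert_allclose(truth.proportions.sum(axis=1), 1.0, atol=1e-9)
    assert (truth.proportions.to_numpy() >= 0).all()


def test_pure_territory_gives_indicator_proportions():
    cfg = small_sim_config(
        seed=2, grid_shape=(4, 4), cells_per_spot=5,
        territory_map={((0, 4), (0, 4)): ("AC-like",)},
        background_weights={}, macrophage_necrosis_boost=0.0,
        endothelial_vessel_boost=0.0, opc_vessel_boost=0.0,
    )
    _, _, truth = simulate_spatial(cfg)
    assert (truth.proportions["AC-like"] == 1.0).all()


def test_territory_map_must_cover_grid():
    cfg = small_sim_config(grid_shape=(4, 4),
                           territory_map={((0, 2), (0, 4)): ("AC-like",)})
    with pytest.raises(ValueError, match="territory map"):
        spot_composition_weights(cfg)


def test_vegfa_gain_ratio_matches_config():
    cfg = small_sim_config(vegfa_gain_at_necrosis=8.0, tau_vegfa=2.0)
    near = vegfa_multiplier(0.0, cfg)
    far = vegfa_multiplier(100.0, cfg)
    assert near / far == pytest.approx(8.0, rel=1e-6)


def test_vegfa_elevated_at_necrosis_in_counts(small_spatial):
    cfg, counts, _, truth = small_spatial
    vegfa = counts.values[counts.gene_ids.index("VEGFA")]
    by_region = pd.Series(vegfa, index=counts.unit_ids).groupby(truth.regions).mean()
    assert by_region["necrosis"] > 2 * by_region["generic_tumor"]


def test_total_counts_match_generative_moments():
    """Sum of spot totals agrees with the analytic NB mixture mean within 3 SE."""
    cfg = small_sim_config(seed=11, grid_shape=(8, 8), cells_per_spot=6)
    counts, _, truth = simulate_spatial(cfg)
    model = expression_model(cfg)
    mu = model.type_means.to_numpy()          # genes x types
    comp = truth.proportions.to_numpy() * 6   # realized cell counts per spot
    # conditional on composition, E[total] = sum_s sum_t n_st sum_g mu_gt (E[size] = 1)
    expected = float((comp @ mu.sum(axis=0)).sum())
    per_gene_mean = mu @ comp.T               # genes x spots, before size factors
    spot_mean = per_gene_mean.sum(axis=0)
    # conservative variance bound: lognormal size-factor term + NB terms with n_st >= 1
    var = ((np.exp(cfg.libsize_sigma**2) - 1) * spot_mean**2).sum() \
        + per_gene_mean.sum() + (per_gene_mean**2 / cfg.nb_dispersion).sum()
    observed = float(counts.values.sum())
    assert abs(observed - expected) < 3 * np.sqrt(var)


def test_disjoint_territories_anticorrelated(small_spatial):
    """Planted segregation: disjoint quadrant states have negative proportion correlation."""
    _, _, _, truth = small_spatial
    p = truth.proportions
    r = np.corrcoef(p["MES-like"], p["AC-like"])[0, 1]
    assert r < 0


def test_markers_disjoint_and_mito_fraction():
    cfg = small_sim_config(seed=9)
    counts, truth = simulate_reference(cfg)
    all_markers = [g for v in truth.markers.values() for g in v]
    assert len(all_markers) == len(set(all_markers))
    mito = [i for i, g in enumerate(counts.gene_ids) if g.startswith("MT-")]
    frac = counts.values[mito].sum() / counts.values.sum()
    assert frac == pytest.approx(cfg.mito_fraction, rel=0.25)


def test_gradient_regions_cover_grid(small_spatial):
    _, counts, geom, truth = small_spatial
    assert set(truth.regions.index) == set(counts.unit_ids)
    assert truth.regions.notna().all()
    assert {"necrosis", "generic_tumor", "perivascular"} <= set(truth.regions)
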