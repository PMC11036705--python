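"""Design construction, moderated-t limits vs closed forms, and a limma cross-check."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from conftest import as_normalized
from gbmspatial.de import DesignMatrix, build_design, compare_logfc, fit_deg, select_top_genes
from gbmspatial.io import RegionAnnotation


def _labels(n_niche=5, n_rest=5):
    names = [f"s{i}" for i in range(n_niche + n_rest)]
    return RegionAnnotation(pd.Series(["niche"] * n_niche + ["generic"] * n_rest, index=names))


def _props(index, rng, types=("MES-like", "AC-like", "OPC-like", "NPC-like",
                              "macrophage", "oligodendrocyte", "neuron")):
    vals = rng.dirichlet(np.ones(len(types)), size=len(index))
    return pd.DataFrame(vals, index=index, columns=types)


def test_design_without_props_has_two_columns():
    d = build_design(_labels(), "niche")
    assert list(d.matrix.columns) == ["intercept", "niche"]
    assert set(d.matrix["niche"]) == {0.0, 1.0}


def test_design_collapses_tumor_and_drops_one_type(rng):
    labels = _labels(6, 6)
    props = _props(labels.labels.index, rng)
    d = build_design(labels, "niche", props=props)
    # intercept, niche, tumor, and 2 of the 3 non-tumor types
    assert list(d.matrix.columns) == ["intercept", "niche", "tumor", "macrophage", "oligodendrocyte"]
    assert d.dropped_columns == ["neuron"]


def test_tumor_column_is_summed_states(rng):
    labels = _labels(4, 4)
    props = _props(labels.labels.index, rng)
    d = build_design(labels, "niche", props=props)
    expected = props[["MES-like", "AC-like", "OPC-like", "NPC-like"]].sum(axis=1)
    np.testing.assert_allclose(d.matrix["tumor"], expected, atol=1e-12)


def test_degenerate_covariate_pruned_and_logged(rng):
    labels = _labels(4, 4)
    props = _props(labels.labels.index, rng)
    # a proportion column identical to the niche indicator is degenerate;
    # the contrast (declared first) is kept and the duplicate is pruned
    props["macrophage"] = (labels.labels == "niche").astype(float)
    d = build_design(labels, "niche", props=props)
    assert "macrophage" not in d.matrix.columns
    assert "macrophage" in d.dropped_columns
    # a rank-deficient design handed over directly is rejected
    bad = d.matrix.copy()
    bad["dup"] = bad["niche"]
    with pytest.raises(ValueError, match="rank"):
        DesignMatrix(bad, coef="niche")


def test_too_small_groups_rejected():
    with pytest.raises(ValueError):
        build_design(_labels(1, 9), "niche")


def test_identical_values_give_null_result(rng):
    labels = _labels()
    vals = rng.normal(0, 1, size=(20, 10))
    vals[0] = 3.0  # constant gene
    expr = as_normalized(vals, unit_ids=labels.labels.index, unit_kind="spot")
    d = build_design(labels, "niche")
    table = fit_deg(expr, d, moderation="none")
    assert table.iloc[0]["logFC"] == pytest.approx(0.0, abs=1e-12)
    assert table.iloc[0]["p_value"] == 1.0


def test_unmoderated_equals_pooled_two_sample_t(rng):
    """With moderation off, the linear-model t is the pooled-variance two-sample t."""
    n1, n2 = 6, 8
    labels = _labels(n1, n2)
    vals = rng.normal(0, 1, size=(30, n1 + n2))
    expr = as_normalized(vals, unit_ids=labels.labels.index, unit_kind="spot")
    table = fit_deg(expr, build_design(labels, "niche"), moderation="none")
    g1, g2 = vals[:, :n1], vals[:, n1:]
    diff = g1.mean(axis=1) - g2.mean(axis=1)
    sp2 = ((n1 - 1) * g1.var(axis=1, ddof=1) + (n2 - 1) * g2.var(axis=1, ddof=1)) / (n1 + n2 - 2)
    t_ref = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    np.testing.assert_allclose(table["logFC"], diff, atol=1e-9)
    np.testing.assert_allclose(table["t"], t_ref, atol=1e-9)
    from scipy import stats
    np.testing.assert_allclose(table["p_value"], 2 * stats.t.sf(np.abs(t_ref), n1 + n2 - 2), atol=1e-9)


def test_forced_infinite_prior_gives_z_statistic(rng):
    labels = _labels(5, 5)
    vals = rng.normal(0, 1, size=(20, 10))
    expr = as_normalized(vals, unit_ids=labels.labels.index, unit_kind="spot")
    d = build_design(labels, "niche")
    s02 = 0.7
    table = fit_deg(expr, d, prior=(np.inf, s02))
    x = d.matrix.to_numpy()
    c = np.sqrt(np.linalg.inv(x.T @ x)[1, 1])
    np.testing.assert_allclose(table["t"], table["logFC"] / (np.sqrt(s02) * c), atol=1e-9)
    from scipy import stats
    np.testing.assert_allclose(table["p_value"], 2 * stats.norm.sf(np.abs(table["t"])), atol=1e-12)


def test_null_simulation_controls_fdr(rng):
    labels = _labels(20, 20)
    vals = rng.normal(0, 1, size=(2000, 40))
    expr = as_normalized(vals, unit_ids=labels.labels.index, unit_kind="spot")
    table = fit_deg(expr, build_design(labels, "niche"), moderation="eb")
    frac = table["significant"].mean()
    assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 2000)


def test_spot_order_and_shift_invariance(rng):
    labels = _labels(5, 7)
    idx = labels.labels.index
    vals = rng.normal(0, 1, size=(25, 12))
    expr = as_normalized(vals, unit_ids=idx, unit_kind="spot")
    d = build_design(labels, "niche")
    base = fit_deg(expr, d)
    perm = rng.permutation(12)
    expr_p = as_normalized(vals[:, perm], unit_ids=[idx[i] for i in perm], unit_kind="spot")
    pd.testing.assert_frame_equal(base, fit_deg(expr_p, d), atol=1e-10)
    shifted = fit_deg(as_normalized(vals + 100.0, unit_ids=idx, unit_kind="spot"), d)
    np.testing.assert_allclose(base["t"], shifted["t"], atol=1e-6)


def test_moderated_t_matches_limma(tmp_path, rng):
    """Independent oracle: limma's lmFit + eBayes on the same fixture via Rscript."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    n = 16
    labels = _labels(8, 8)
    idx = labels.labels.index
    vals = rng.normal(0, 1, size=(80, n)) * rng.uniform(0.5, 2.0, size=(80, 1))
    vals[:10] += 1.5 * (labels.labels == "niche").to_numpy()[None, :]
    expr = as_normalized(vals, gene_ids=[f"g{i}" for i in range(80)], unit_ids=idx, unit_kind="spot")
    covar = rng.uniform(0, 1, size=n)
    d = build_design(labels, "niche")
    d = DesignMatrix(d.matrix.assign(cov=covar), coef="niche")
    table = fit_deg(expr, d)

    pd.DataFrame(vals, index=expr.gene_ids, columns=idx).to_csv(tmp_path / "expr.csv")
    d.matrix.to_csv(tmp_path / "design.csv", index=False)
    script = tmp_path / "oracle.R"
    script.write_text(
        'suppressMessages(library(limma))\n'
        f'expr <- as.matrix(read.csv("{tmp_path}/expr.csv", row.names=1))\n'
        f'design <- as.matrix(read.csv("{tmp_path}/design.csv"))\n'
        'fit <- eBayes(lmFit(expr, design))\n'
        'out <- data.frame(gene=rownames(expr), logFC=fit$coefficients[, "niche"],\n'
        '                  t=fit$t[, "niche"], p=fit$p.value[, "niche"],\n'
        '                  d0=fit$df.prior, s02=fit$s2.prior)\n'
        f'write.csv(out, "{tmp_path}/out.csv", row.names=FALSE)\n'
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
    np.testing.assert_allclose(table["logFC"], ref["logFC"], atol=1e-8)
    assert table.attrs["d0"] == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
    assert table.attrs["s0_squared"] == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
    np.testing.assert_allclose(table["t"], ref["t"], rtol=1e-5, atol=1e-8)
    np.testing.assert_allclose(table["p_value"], ref["p"], rtol=1e-5, atol=1e-10)


def test_compare_logfc_identity_and_negation(rng):
    labels = _labels(5, 5)
    vals = rng.normal(0, 1, size=(50, 10))
    expr = as_normalized(vals, unit_ids=labels.labels.index, unit_kind="spot")
    deg = fit_deg(expr, build_design(labels, "niche"))
    r, n, cross = compare_logfc(deg, deg)
    assert r == pytest.approx(1.0, abs=1e-12)
    assert n == 50
    neg = deg.copy()
    neg["logFC"] = -neg["logFC"]
    r2, _, _ = compare_logfc(deg, neg)
    assert r2 == pytest.approx(-1.0, abs=1e-12)
    with pytest.raises(ValueError):
        compare_logfc(deg.iloc[:2], deg.iloc[:2])


def test_select_top_genes_rules():
    deg = pd.DataFrame({
        "logFC": [2.0, 1.5, -3.0, 0.5, -0.2],
        "t": 0.0, "p_value": 0.5, "adj_p": 0.5, "significant": False,
    }, index=["a", "b", "c", "d", "e"])
    up, down = select_top_genes(deg, n=2)
    assert up == ["a", "b"] and down == ["c", "e"]
    all_pos = deg[deg["logFC"] > 0]
    up2, down2 = select_top_genes(all_pos, n=10)
    assert down2 == []
    tied = pd.DataFrame({"logFC": [1.0, 1.0, 1.0], "t": 0.0, "p_value": 1.0,
                         "adj_p": 1.0, "significant": False}, index=["z", "a", "m"])
    up3, _ = select_top_genes(tied, n=2)
    assert up3 == ["a", "m"]  # ties break by gene id
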