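"""Bin aggregation, QC, normalization, clustering and marker selection,
with brute-force and hand-computed oracles."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp
import shapely

import histoexpr as hx
from histoexpr import expression as ex


def _cells(rows, genes=("mt-a", "g1", "g2"), areas=None):
    counts = sp.csr_matrix(np.asarray(rows))
    areas = np.full(counts.shape[0], 100.0) if areas is None else np.asarray(areas)
    return ex.CellCounts(cell_ids=[f"c{i}" for i in range(counts.shape[0])],
                         genes=list(genes), counts=counts, area_px=areas)


# ---- aggregation ------------------------------------------------------------

def test_aggregation_matches_generator_bookkeeping(small_sim):
    _, _, polygons, bins, truth = small_sim
    cells = hx.aggregate_bins_to_cells(bins, polygons)
    assert np.array_equal(np.asarray(cells.counts.todense()), truth.sampled_counts)
    assert np.array_equal(cells.total_umi, truth.sampled_counts.sum(axis=1))


def test_aggregation_matches_brute_force_point_in_polygon(small_sim):
    """Exclusive first-wins assignment reproduced by an O(bins x cells) scan."""
    _, _, polygons, bins, _ = small_sim
    cells = hx.aggregate_bins_to_cells(bins, polygons)
    n_cells = len(polygons)
    expected = np.zeros((n_cells, len(bins.genes)))
    shapes = [p.shapely for p in polygons]
    dense = np.asarray(bins.counts.todense())
    for b in range(len(bins.barcodes)):
        pt = shapely.Point(bins.bin_centers[b])
        for ci, s in enumerate(shapes):
            if s.intersects(pt):  # boundary counts as inside
                expected[ci] += dense[b]
                break  # first polygon wins
    assert np.array_equal(np.asarray(cells.counts.todense()), expected)


def test_polygon_without_bin_centers_gets_zero_row(small_sim):
    _, _, _, bins, _ = small_sim
    # a tiny triangle strictly between bin centers (centers at 2+4k px)
    tiny = hx.NucleusPolygon("empty", np.array([[3.0, 3.0], [3.8, 3.0], [3.4, 3.8]]))
    cells = hx.aggregate_bins_to_cells(bins, [tiny])
    assert cells.total_umi[0] == 0
    assert cells.counts[0].nnz == 0


def test_frame_mismatch_warns(small_sim):
    _, _, polygons, bins, _ = small_sim
    shifted = ex.BinTable(barcodes=bins.barcodes, genes=bins.genes,
                          counts=bins.counts,
                          bin_centers=bins.bin_centers + 10000.0)
    with pytest.warns(UserWarning, match="frame"):
        hx.aggregate_bins_to_cells(shifted, polygons)


# ---- QC filter --------------------------------------------------------------

def test_qc_filter_boundary_behavior_on_constructed_table():
    """Area < 2000 strict, UMI > 20 strict, mito < 15% strict: of five
    constructed cells exactly the two satisfying all three survive."""
    rows = [
        [2, 28],     # pass: area 1999.5, umi 30, mito 2/30
        [2, 28],     # fail: area exactly 2000
        [0, 20],     # fail: umi exactly 20 (needs > 20)
        [6, 24],     # fail: mito 6/30 = 0.20
        [1, 24],     # pass: area 500, umi 25, mito 0.04
    ]
    cells = _cells(rows, genes=("mt-a", "g1"),
                   areas=[1999.5, 2000.0, 100.0, 100.0, 500.0])
    kept = hx.qc_filter(cells)
    assert kept.cell_ids == ["c0", "c4"]


def test_qc_filter_monotone_in_thresholds():
    rng = np.random.default_rng(0)
    cells = _cells(rng.integers(0, 30, (40, 3)),
                   areas=rng.uniform(50, 3000, 40))
    tight = set(hx.qc_filter(cells, max_area=1000, min_umi=30, max_mito=0.10).cell_ids)
    loose = set(hx.qc_filter(cells, max_area=2500, min_umi=10, max_mito=0.30).cell_ids)
    assert tight <= loose


# ---- normalization ----------------------------------------------------------

def test_normalize_log1p_formula_and_conservation():
    cells = _cells([[0, 10, 90], [5, 5, 40]])
    norm, meta = hx.normalize_log1p(cells, target_sum=1e4)
    dense = np.asarray(norm.todense())
    # count 10 of total 100 at target 1e4 -> log(1 + 1000)
    assert dense[0, 1] == pytest.approx(np.log(1 + 1000))
    assert dense[0, 0] == 0.0
    assert np.allclose(np.expm1(dense).sum(axis=1), 1e4)
    assert meta == {"target_sum": 1e4, "log1p": True}


def test_normalize_zero_total_cell_is_named():
    cells = _cells([[0, 0, 0], [1, 2, 3]])
    with pytest.raises(ValueError, match="c0"):
        hx.normalize_log1p(cells)


# ---- HVG --------------------------------------------------------------------

def test_hvg_contains_spiked_gene():
    rng = np.random.default_rng(1)
    X = rng.poisson(1.0, (100, 30)).astype(float)
    X[:, 7] = rng.poisson(1.0, 100) * rng.integers(0, 2, 100) * 40  # huge dispersion
    genes = [f"g{i}" for i in range(30)]
    chosen = hx.select_hvg(sp.csr_matrix(np.log1p(X)), genes, n_top=10)
    assert "g7" in chosen
    assert len(chosen) == 10


def test_hvg_saturates_to_all_nonconstant_genes():
    rng = np.random.default_rng(2)
    X = np.log1p(rng.poisson(2.0, (50, 10)).astype(float))
    X[:, 0] = 1.0  # constant, zero variance
    genes = [f"g{i}" for i in range(10)]
    with pytest.warns(UserWarning, match="nonzero variance"):
        chosen = hx.select_hvg(sp.csr_matrix(X), genes, n_top=50)
    assert chosen == genes[1:]


# ---- clustering -------------------------------------------------------------

def test_leiden_same_seed_identical_labels(small_sim):
    _, _, polygons, bins, _ = small_sim
    cells = hx.qc_filter(hx.aggregate_bins_to_cells(bins, polygons))
    norm, _ = hx.normalize_log1p(cells)
    a = hx.cluster_cells(norm, neighbors_k=10, seed=3)
    b = hx.cluster_cells(norm, neighbors_k=10, seed=3)
    assert np.array_equal(a, b)


def test_min_cluster_size_saturation(small_sim):
    _, _, polygons, bins, _ = small_sim
    cells = hx.qc_filter(hx.aggregate_bins_to_cells(bins, polygons))
    norm, _ = hx.normalize_log1p(cells)
    labels = hx.cluster_cells(norm, neighbors_k=10, min_cluster_size=10 ** 6, seed=0)
    assert set(labels) == {"filtered"}


def test_two_programs_recovered_by_clustering():
    """Strong morphology-linked programs separate with high adjusted Rand."""
    from sklearn.metrics import adjusted_rand_score

    cfg = hx.SynthConfig(n_cells=400, n_genes=80, n_programs=2, seed=5,
                         morphology_effect=2.0)
    _, polygons, bins, truth = hx.simulate_slide(cfg)
    cells = hx.aggregate_bins_to_cells(bins, polygons)
    kept = hx.qc_filter(cells)
    keep_idx = [cells.cell_ids.index(c) for c in kept.cell_ids]
    norm, _ = hx.normalize_log1p(kept)
    labels = hx.cluster_cells(norm, seed=0)
    assert len(set(labels)) >= 2
    assert adjusted_rand_score(truth.programs[keep_idx], labels) >= 0.9


# ---- Wilcoxon markers -------------------------------------------------------

def _exact_ranksum_p(a, b):
    """Two-sided p by exhaustive enumeration of rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    w_obs = ranks[:len(a)].sum()
    n = len(pooled)
    mu = len(a) * (n + 1) / 2
    hits = total = 0
    for combo in itertools.combinations(range(n), len(a)):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def test_wilcoxon_close_to_exact_enumeration_on_4v4():
    """The normal-approximation p is within 0.05 of the exact rank-permutation
    p on a 2x4 instance (the approximation gap at n=4 is a few percent)."""
    a = np.array([1.2, 0.5, 0.9, 2.0])
    b = np.array([0.1, 0.3, 0.05, 0.7])
    rng = np.random.default_rng(0)
    X = np.zeros((8, 2))
    X[:, 0] = np.concatenate([a, b])
    X[:, 1] = rng.random(8)
    labels = np.array(["A"] * 4 + ["B"] * 4)
    stats = hx.rank_genes_wilcoxon(sp.csr_matrix(X), labels, ["target", "noise"])
    p_impl = stats[(stats.cluster == "A") & (stats.gene == "target")]["p"].iloc[0]
    p_exact = _exact_ranksum_p(a, b)
    assert p_impl == pytest.approx(p_exact, abs=0.05)
    # and matches scipy's asymptotic rank-sum test tightly
    from scipy.stats import ranksums
    assert p_impl == pytest.approx(ranksums(a, b).pvalue, abs=1e-6)


def test_constant_gene_gets_null_stats():
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(12), rng.random(12)])
    labels = np.array(["A"] * 6 + ["B"] * 6)
    stats = hx.rank_genes_wilcoxon(sp.csr_matrix(X), labels, ["flat", "g"])
    flat = stats[stats.gene == "flat"]
    assert np.allclose(flat["p"], 1.0, atol=1e-9)
    assert (flat["log2fc"].abs() < 1e-6).all()


def test_bh_adjustment_monotone_and_conservative():
    rng = np.random.default_rng(4)
    X = rng.poisson(2.0, (40, 25)).astype(float)
    X[:20, :5] += rng.poisson(4.0, (20, 5))
    labels = np.array(["A"] * 20 + ["B"] * 20)
    stats = hx.rank_genes_wilcoxon(sp.csr_matrix(np.log1p(X)), labels,
                                   [f"g{i}" for i in range(25)])
    grp = stats[stats.cluster == "A"].sort_values("p")
    assert (grp["p_adj"].to_numpy() >= grp["p"].to_numpy() - 1e-12).all()
    assert (np.diff(grp["p_adj"].to_numpy()) >= -1e-12).all()


def test_permuted_labels_give_uniformish_pvalues():
    """Under label permutation the marker test is null: its p-values pass a
    Kolmogorov-Smirnov uniformity check at alpha = 0.01."""
    from scipy.stats import kstest

    cfg = hx.SynthConfig(n_cells=200, n_genes=100, seed=9)
    _, polygons, bins, _ = hx.simulate_slide(cfg)
    cells = hx.qc_filter(hx.aggregate_bins_to_cells(bins, polygons))
    norm, _ = hx.normalize_log1p(cells)
    rng = np.random.default_rng(0)
    half = len(cells.cell_ids) // 2
    labels = rng.permutation(
        np.array(["a"] * half + ["b"] * (len(cells.cell_ids) - half)))
    stats = hx.rank_genes_wilcoxon(norm, labels, cells.genes)
    p = stats[stats.cluster == "a"]["p"].to_numpy()
    assert kstest(p, "uniform").pvalue > 0.01


# ---- panel ------------------------------------------------------------------

def _stats_frame(rows):
    import pandas as pd
    return pd.DataFrame(rows, columns=["cluster", "gene", "p", "p_adj", "log2fc"])


def test_panel_threshold_boundaries():
    stats = _stats_frame([
        ("0", "at_p_boundary", 0.001, 0.01, 2.0),     # p_adj == 0.01 -> excluded
        ("0", "at_fc_boundary", 0.001, 0.001, 1.0),   # |log2FC| == 1 -> included
        ("0", "down_marker", 0.001, 0.001, -1.5),     # negative FC qualifies
    ])
    panel = hx.build_panel(stats)
    assert "at_p_boundary" not in panel.genes
    assert "at_fc_boundary" in panel.genes
    assert "down_marker" in panel.genes


def test_panel_union_across_clusters():
    stats = _stats_frame([
        ("0", "g1", 1e-5, 1e-4, 2.0),
        ("0", "g2", 1e-5, 1e-4, 1.5),
        ("1", "g2", 1e-5, 1e-4, -2.0),  # shared marker counted once
        ("1", "g3", 1e-5, 1e-4, 3.0),
        ("1", "g4", 0.5, 0.9, 0.2),     # fails both thresholds
    ])
    panel = hx.build_panel(stats)
    assert sorted(panel.genes) == ["g1", "g2", "g3"]


def test_empty_panel_raises_with_advice():
    stats = _stats_frame([("0", "g1", 0.9, 0.99, 0.1)])
    with pytest.raises(ValueError, match="relax"):
        hx.build_panel(stats)


# ---- binary labels and QC metrics ------------------------------------------

def test_binary_labels_definition():
    y = np.array([[0.0, 0.3, 0.0], [0.0, 0.0, 0.0]])
    b = hx.binary_labels(y)
    assert b.tolist() == [[False, True, False], [False, False, False]]


def test_binary_labels_agree_with_raw_counts(small_sim):
    _, _, polygons, bins, _ = small_sim
    cells = hx.qc_filter(hx.aggregate_bins_to_cells(bins, polygons))
    norm, _ = hx.normalize_log1p(cells)
    b = hx.binary_labels(np.asarray(norm.todense()))
    assert np.array_equal(b, np.asarray(cells.counts.todense()) > 0)


def test_qc_metrics_hand_sums():
    X = sp.csr_matrix(np.array([[0, 0, 0], [1, 0, 4], [2, 2, 2]]))
    df = ex.qc_metrics(X)
    assert df["total_counts"].tolist() == [0, 5, 6]
    assert df["n_features"].tolist() == [0, 2, 3]


def test_clip_percentile_on_constants():
    lo, hi = ex.clip_percentile(np.full(50, 7.0), p=99)
    assert (lo, hi) == (0.0, 7.0)
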