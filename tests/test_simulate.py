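"""Ground-truth generator: determinism, identities, and distributional checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from spatlas.io import LRPair
from spatlas.simulate import (
    AttractionRule,
    ClusterSpec,
    DomainSpec,
    LRRule,
    SimulationConfig,
    SubclassSpec,
    apply_attraction,
    apply_lr_upregulation,
    simulate_cells,
    simulate_expression,
    simulate_reference,
)


def one_domain_config(**kw):
    defaults = dict(
        genes=["g0", "g1"],
        subclasses=[SubclassSpec("A", [ClusterSpec("A.0", np.array([5.0, 1.0]))])],
        domains=[DomainSpec("d", (0, 1000), (0, 1000), {"A": 1.0})],
        base_intensity=1000, seed=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_same_seed_gives_identical_tables_and_counts_are_poisson_scale():
    config = one_domain_config(base_intensity=100)
    cells1, _ = simulate_cells(config)
    cells2, _ = simulate_cells(config)
    pd.testing.assert_frame_equal(cells1, cells2)
    # intensity 100/mm^2 on 1 mm^2: count within 5 sd of Poisson(100)
    assert 50 <= len(cells1) <= 150


def test_disjoint_domain_compositions_do_not_mix():
    config = SimulationConfig(
        genes=["g0"],
        subclasses=[SubclassSpec("A", [ClusterSpec("A.0", np.ones(1))]),
                    SubclassSpec("B", [ClusterSpec("B.0", np.ones(1))])],
        domains=[DomainSpec("left", (0, 500), (0, 1000), {"A": 1.0}),
                 DomainSpec("right", (500, 1000), (0, 1000), {"B": 1.0})],
        base_intensity=2000, seed=0,
    )
    cells, truth = simulate_cells(config)
    assert (cells.loc[cells["subclass"] == "A", "x"] < 500).all()
    assert (cells.loc[cells["subclass"] == "B", "x"] >= 500).all()
    assert (truth.domain.loc[cells["cell_id"]].to_numpy()
            == np.where(cells["subclass"] == "A", "left", "right")).all()


def test_zero_area_domain_rejected():
    with pytest.raises(ValueError, match="zero area"):
        one_domain_config(
            domains=[DomainSpec("d", (0, 0), (0, 1000), {"A": 1.0})]
        )


def test_doublet_scores_straddle_threshold():
    config = one_domain_config(base_intensity=1000, doublet_fraction=0.1, seed=2)
    cells, truth = simulate_cells(config)
    flagged = cells["doublet_score"] > 0.25
    assert set(cells.loc[flagged, "cell_id"]) == set(truth.doublet_ids)
    # Binomial(n, 0.1) within 5 sd
    n = len(cells)
    assert abs(flagged.sum() - 0.1 * n) < 5 * np.sqrt(n * 0.1 * 0.9)


def two_type_config(seed=0, intensity=600):
    return SimulationConfig(
        genes=["g0", "g1"],
        subclasses=[SubclassSpec("A", [ClusterSpec("A.0", np.full(2, 5.0))]),
                    SubclassSpec("B", [ClusterSpec("B.0", np.full(2, 5.0))])],
        domains=[DomainSpec("d", (0, 1000), (0, 1000), {"A": 0.5, "B": 0.5})],
        base_intensity=intensity, seed=seed,
    )


def test_attraction_strength_zero_is_identity():
    cells, _ = simulate_cells(two_type_config())
    out = apply_attraction(cells, AttractionRule("A", "B", 10, 0.0), seed=1)
    pd.testing.assert_frame_equal(out, cells)


def test_attraction_strength_one_places_all_b_near_a():
    cells, _ = simulate_cells(two_type_config())
    out = apply_attraction(cells, AttractionRule("A", "B", 10, 1.0), seed=1)
    a = out[out["subclass"] == "A"][["x", "y"]].to_numpy()
    b = out[out["subclass"] == "B"][["x", "y"]].to_numpy()
    dist, _ = cKDTree(a).query(b)
    assert (dist <= 10 + 1e-9).all()
    # per-type counts are preserved: relocation, not thinning
    assert (out["subclass"].value_counts() == cells["subclass"].value_counts()).all()


def test_attraction_moves_binomial_fraction():
    moved_counts, totals = [], []
    for seed in range(8):
        cells, _ = simulate_cells(two_type_config(seed=seed))
        out = apply_attraction(cells, AttractionRule("A", "B", 10, 0.5), seed=seed)
        b_mask = cells["subclass"] == "B"
        moved = (cells.loc[b_mask, ["x", "y"]] != out.loc[b_mask, ["x", "y"]]).any(axis=1)
        moved_counts.append(moved.sum())
        totals.append(b_mask.sum())
    frac = np.sum(moved_counts) / np.sum(totals)
    n = np.sum(totals)
    assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / n)


def test_attraction_invalid_radius_rejected():
    cells, _ = simulate_cells(two_type_config())
    with pytest.raises(ValueError, match="radius"):
        apply_attraction(cells, AttractionRule("A", "B", -5, 0.5), seed=0)


def test_poisson_limit_mean_recovers_configured_mean():
    config = one_domain_config(
        subclasses=[SubclassSpec("A", [ClusterSpec(
            "A.0", np.array([5.0, 1.0]), dispersion=np.inf)])],
        base_intensity=10000, seed=4,
    )
    cells, _ = simulate_cells(config)
    expr = simulate_expression(cells, config)
    n = expr.n_cells
    mean = expr.layer("raw")[:, 0].mean()
    # volumes jitter the per-cell mean slightly; 4 s.e. of the count noise
    assert abs(mean - 5.0) < 4 * np.sqrt(5.0 / n) + 0.1


def test_zero_gradient_slope_leaves_expression_spatially_flat():
    config = one_domain_config(base_intensity=3000, seed=5)
    cells, _ = simulate_cells(config)
    expr = simulate_expression(cells, config)
    r = np.corrcoef(expr.layer("raw")[:, 0], cells["x"])[0, 1]
    assert abs(r) < 0.06


def test_orthogonal_cluster_means_are_separable_by_nearest_mean():
    m1 = np.array([20.0, 0.0, 0.0, 0.0])
    m2 = np.array([0.0, 0.0, 20.0, 0.0])
    config = SimulationConfig(
        genes=list("wxyz"),
        subclasses=[SubclassSpec("A", [ClusterSpec("A.0", m1),
                                       ClusterSpec("A.1", m2)])],
        domains=[DomainSpec("d", (0, 1000), (0, 1000), {"A": 1.0})],
        base_intensity=3000, seed=6,
    )
    cells, truth = simulate_cells(config)
    expr = simulate_expression(cells, config)
    vols = cells["volume"].to_numpy() / config.volume_mean[config.n_zplanes]
    x = expr.layer("raw") / vols[:, None]
    pred = np.where(
        np.linalg.norm(x - m1, axis=1) < np.linalg.norm(x - m2, axis=1),
        "A.0", "A.1",
    )
    assert (pred == truth.cluster.loc[expr.cells].to_numpy()).mean() > 0.99


LR = LRPair("L_R", ("g0",), ("g1",))


def test_lr_upregulation_identities():
    config = two_type_config()
    cells, _ = simulate_cells(config)
    expr = simulate_expression(cells, config)
    out = apply_lr_upregulation(expr, cells, LRRule("A", "B", LR, 1.0, 10))
    np.testing.assert_array_equal(out.layer("raw"), expr.layer("raw"))
    # disjoint (never proximal) types: also identity at any fold
    config2 = SimulationConfig(
        genes=["g0", "g1"],
        subclasses=[SubclassSpec("A", [ClusterSpec("A.0", np.ones(2))]),
                    SubclassSpec("B", [ClusterSpec("B.0", np.ones(2))])],
        domains=[DomainSpec("left", (0, 400), (0, 400), {"A": 1.0}),
                 DomainSpec("right", (600, 1000), (600, 1000), {"B": 1.0})],
        base_intensity=1000, seed=7,
    )
    cells2, _ = simulate_cells(config2)
    expr2 = simulate_expression(cells2, config2)
    out2 = apply_lr_upregulation(expr2, cells2, LRRule("A", "B", LR, 4.0, 10))
    np.testing.assert_array_equal(out2.layer("raw"), expr2.layer("raw"))


def test_lr_upregulation_scales_proximal_ligand_exactly():
    config = two_type_config()
    cells, _ = simulate_cells(config)
    cells = apply_attraction(cells, AttractionRule("A", "B", 10, 1.0), seed=0)
    expr = simulate_expression(cells, config)
    out = apply_lr_upregulation(expr, cells, LRRule("B", "A", LR, 4.0, 10))
    # ligand component (g0) scales exactly x4 in proximal B cells, receptor
    # component (g1) x4 in proximal A cells; nothing else moves
    raw0, raw1 = expr.layer("raw"), out.layer("raw")
    is_b = (cells.set_index("cell_id").loc[expr.cells, "subclass"] == "B").to_numpy()
    b_changed = is_b & (raw0[:, 0] != raw1[:, 0])
    assert b_changed.any()
    np.testing.assert_array_equal(raw1[b_changed, 0], raw0[b_changed, 0] * 4.0)
    np.testing.assert_array_equal(raw1[is_b, 1], raw0[is_b, 1])
    a_changed = ~is_b & (raw0[:, 1] != raw1[:, 1])
    assert a_changed.any()
    np.testing.assert_array_equal(raw1[a_changed, 1], raw0[a_changed, 1] * 4.0)
    np.testing.assert_array_equal(raw1[~is_b, 0], raw0[~is_b, 0])
    with pytest.raises(KeyError):
        apply_lr_upregulation(expr, cells, LRRule("A", "B", LRPair("X", ("nope",), ("g1",)), 2.0, 10))


def test_reference_shares_cluster_means_with_imaging_panel():
    rng = np.random.default_rng(8)
    genes = [f"g{i}" for i in range(50)]
    mean = rng.gamma(2.0, 2.0, size=50)
    config = SimulationConfig(
        genes=genes,
        subclasses=[SubclassSpec("A", [ClusterSpec("A.0", mean, dispersion=20.0)])],
        domains=[DomainSpec("d", (0, 100), (0, 100), {"A": 1.0})],
        panel_genes=genes[:20], base_intensity=1000, seed=8,
    )
    ref, labels = simulate_reference(config, n_cells_per_cluster=500)
    assert set(config.panel_genes) <= set(ref.genes)
    ref2, _ = simulate_reference(config, n_cells_per_cluster=500)
    np.testing.assert_array_equal(ref.layer("raw"), ref2.layer("raw"))
    sample_mean = ref.layer("raw").mean(axis=0)
    assert np.corrcoef(sample_mean, mean)[0, 1] > 0.99
    assert (labels["cluster"] == "A.0").all()
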