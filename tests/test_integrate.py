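"""Integration: normalization, partitioning, CCA, anchors, transfer, imputation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import NearestNeighbors

from spatlas.config import AnalysisConfig
from spatlas.integrate import (
    AnchorSet,
    CoEmbedding,
    cca_coembed,
    find_anchors,
    impute_expression,
    partition_reference,
    preprocess_for_integration,
    select_hvg,
    transfer_labels,
    two_round_transfer,
)
from spatlas.io import ExpressionMatrix


def test_preprocess_for_integration_arithmetic():
    expr = ExpressionMatrix(["c"], ["g1", "g2"], {"raw": np.array([[2.0, 8.0]])})
    out = preprocess_for_integration(expr, total=1000.0)
    np.testing.assert_allclose(out.layer("lognorm"),
                               [[np.log(201.0), np.log(801.0)]])


def test_scaled_layer_is_zscored_with_constant_genes_zero():
    rng = np.random.default_rng(0)
    raw = rng.poisson(5.0, size=(100, 3)).astype(float) + 1.0
    const = np.full(100, 2.0)
    filler = 60.0 - raw.sum(axis=1) - const  # equal per-cell totals
    raw = np.column_stack([raw, const, filler])
    expr = preprocess_for_integration(
        ExpressionMatrix([f"c{i}" for i in range(100)], list("vwxyz"), {"raw": raw})
    )
    scaled = expr.layer("scaled")
    np.testing.assert_allclose(scaled.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(scaled[:, :3].std(axis=0), 1.0, atol=1e-12)
    # gene constant across cells (totals equal, so also constant post-norm)
    np.testing.assert_array_equal(scaled[:, 3], 0.0)


def test_all_zero_cell_rejected():
    expr = ExpressionMatrix(["ok", "empty"], ["g"],
                            {"raw": np.array([[1.0], [0.0]])})
    with pytest.raises(ValueError, match="empty"):
        preprocess_for_integration(expr)


def blob_reference(n_per=80, seed=0):
    """4 subclasses forming two well-separated expression blobs."""
    rng = np.random.default_rng(seed)
    means = {"a1": [20, 20, 0, 0], "a2": [22, 18, 0, 0],
             "b1": [0, 0, 20, 20], "b2": [0, 0, 18, 22]}
    raws, labels = [], []
    for sub, mean in means.items():
        raws.append(rng.poisson(np.array(mean, float) + 0.2, size=(n_per, 4)))
        labels += [sub] * n_per
    raw = np.vstack(raws).astype(float)
    raw[raw.sum(axis=1) == 0, 0] = 1.0
    cells = [f"c{i}" for i in range(len(raw))]
    expr = preprocess_for_integration(
        ExpressionMatrix(cells, list("wxyz"), {"raw": raw})
    )
    return expr, pd.Series(labels, index=cells)


def test_partition_reference_recovers_expression_blobs():
    expr, subclasses = blob_reference()
    part = partition_reference(expr, subclasses, k_partitions=2, n_pca=3, seed=0)
    groups = part.partitions
    assert len(groups) == 2
    assert {frozenset(g) for g in groups.values()} == {
        frozenset({"a1", "a2"}), frozenset({"b1", "b2"})
    }
    # the blob split is the minimum cut among all balanced 2-partitions
    w = part.graph.to_numpy()
    names = list(part.graph.index)
    achieved = part.cut_weight
    for mask in range(1, 2 ** len(names) - 1):
        side = [bool(mask >> i & 1) for i in range(len(names))]
        if sum(side) != 2:
            continue
        cut = sum(w[i][j] for i in range(4) for j in range(4)
                  if side[i] and not side[j])
        assert achieved <= cut + 1e-9


def test_partition_singletons_when_k_equals_subclasses():
    expr, subclasses = blob_reference()
    part = partition_reference(expr, subclasses, k_partitions=4, n_pca=3, seed=0)
    assert sorted(len(v) for v in part.partitions.values()) == [1, 1, 1, 1]
    total = part.graph.to_numpy().sum() / 2
    assert part.cut_weight == pytest.approx(total)
    with pytest.raises(ValueError):
        partition_reference(expr, subclasses, k_partitions=5, n_pca=3)


def test_self_copy_cca_places_copies_as_cross_neighbours():
    rng = np.random.default_rng(1)
    raw = rng.poisson(4.0, size=(150, 30)).astype(float)
    raw[raw.sum(axis=1) == 0, 0] = 1.0
    expr = preprocess_for_integration(
        ExpressionMatrix([f"c{i}" for i in range(150)],
                         [f"g{i}" for i in range(30)], {"raw": raw})
    )
    x = expr.layer("scaled")
    emb = cca_coembed(x, x, n_dims=10, seed=0)
    nn = NearestNeighbors(n_neighbors=1).fit(emb.query)
    _, idx = nn.kneighbors(emb.ref)
    assert (idx.ravel() == np.arange(150)).mean() >= 0.99


def test_cca_permutation_equivariance_and_dim_guard():
    rng = np.random.default_rng(2)
    a = rng.normal(size=(50, 12))
    b = rng.normal(size=(40, 12))
    emb = cca_coembed(a, b, n_dims=5, seed=0)
    perm = rng.permutation(40)
    emb_p = cca_coembed(a, b[perm], n_dims=5, seed=0)
    np.testing.assert_allclose(emb_p.query, emb.query[perm], atol=1e-8)
    with pytest.raises(ValueError, match="n_dims"):
        cca_coembed(a, b, n_dims=13)


def test_anchors_mutual_and_symmetric():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(10, 4))
    emb = CoEmbedding(ref=pts, query=pts.copy())
    anchors = find_anchors(emb, k=1)
    assert anchors.pairs.tolist() == [[i, i] for i in range(10)]
    # an isolated query cell joins no anchor
    far = np.vstack([pts, [[100, 100, 100, 100]]])
    emb2 = CoEmbedding(ref=pts, query=far)
    anchors2 = find_anchors(emb2, k=1)
    assert 10 not in anchors2.pairs[:, 1]
    # swapping datasets yields the same (mirrored) pair set
    emb_swap = CoEmbedding(ref=far, query=pts)
    swapped = find_anchors(emb_swap, k=1)
    assert {(q, r) for r, q in swapped.pairs.tolist()} == set(
        map(tuple, anchors2.pairs.tolist())
    )
    with pytest.raises(ValueError):
        find_anchors(emb, k=10)


def test_transfer_confidence_is_plurality_fraction_with_lexical_ties():
    # anchor refs on a line; a query point equidistant from two labels
    ref = np.array([[0.0], [1.0], [2.0], [3.0]])
    query = np.array([[1.5]])
    emb = CoEmbedding(ref=ref, query=query)
    anchors = AnchorSet(pairs=np.array([[i, 0] for i in range(4)]), embedding=emb)
    out = transfer_labels(anchors, np.array(["x", "x", "y", "y"]), k_anchor=4)
    assert out["label"].iloc[0] == "x"  # 2-2 tie -> lexicographically smallest
    assert out["confidence"].iloc[0] == 0.5
    out2 = transfer_labels(anchors, np.array(["x", "x", "x", "y"]), k_anchor=4)
    assert out2["label"].iloc[0] == "x"
    assert out2["confidence"].iloc[0] == 0.75


def test_imputation_weighted_mean_and_convexity():
    ref = ExpressionMatrix(["r0", "r1"], ["g"],
                           {"raw": np.array([[4.0], [8.0]])})
    # query at distance d0 < d1 from the two anchors; sigma = d1
    emb = CoEmbedding(ref=np.array([[0.0], [2.0]]), query=np.array([[0.5]]))
    anchors = AnchorSet(pairs=np.array([[0, 0], [1, 0]]), embedding=emb)
    out = impute_expression(anchors, ref, k_impute=2)
    d = np.array([0.5, 1.5])
    w = np.exp(-((d / 1.5) ** 2))
    expected = (w * np.array([4.0, 8.0])).sum() / w.sum()
    assert out.layer("raw")[0, 0] == pytest.approx(expected)
    assert 4.0 <= out.layer("raw")[0, 0] <= 8.0
    # identical anchor expression -> imputed value regardless of weights
    ref_same = ExpressionMatrix(["r0", "r1"], ["g"],
                                {"raw": np.array([[6.0], [6.0]])})
    same = impute_expression(anchors, ref_same, k_impute=2)
    assert same.layer("raw")[0, 0] == pytest.approx(6.0)


def test_select_hvg_excludes_constant_keeps_bimodal():
    rng = np.random.default_rng(4)
    n = 200
    flat = rng.poisson(5.0, size=n).astype(float) + 1.0
    bimodal = np.where(rng.random(n) < 0.5, rng.poisson(1.0, n),
                       rng.poisson(30.0, n)).astype(float)
    const = np.full(n, 3.0)
    filler = 80.0 - flat - bimodal - const  # equal totals keep "const" constant
    raw = np.column_stack([flat, bimodal, const, filler])
    expr = preprocess_for_integration(
        ExpressionMatrix([f"c{i}" for i in range(n)],
                         ["flat", "bimodal", "constant", "filler"], {"raw": raw})
    )
    hvg = select_hvg(expr)
    assert "bimodal" in hvg
    assert "constant" not in hvg
    assert set(hvg) <= {"flat", "bimodal", "constant", "filler"}


@pytest.fixture(scope="module")
def transfer_result(integration_scenario):
    return two_round_transfer(
        integration_scenario["ref"], integration_scenario["ref_labels"],
        integration_scenario["query"],
        AnalysisConfig(n_partitions=3, n_cca_dims=50), seed=0,
    )


def test_two_round_recovery_on_paired_synthetic_data(integration_scenario, transfer_result):
    truth = integration_scenario["truth"]
    table = transfer_result.table
    sub_acc = (table["subclass"] == truth.subclass.loc[table.index]).mean()
    cl_acc = (table["cluster"] == truth.cluster.loc[table.index]).mean()
    assert sub_acc >= 0.95
    assert cl_acc >= 0.85


def test_adjusted_confidence_is_exact_product(transfer_result):
    table = transfer_result.table
    np.testing.assert_allclose(
        table["subclass_conf_adjusted"],
        table["subclass_conf"] * table["partition_conf"],
    )
    assert (table["subclass_conf_adjusted"]
            <= np.minimum(table["subclass_conf"], table["partition_conf"]) + 1e-12).all()
    # thresholds are inclusive
    at_boundary = pd.Series([0.8]) >= AnalysisConfig().subclass_conf_threshold
    assert bool(at_boundary.iloc[0])


def test_imputed_cluster_means_match_generating_means(integration_scenario, transfer_result):
    scenario = integration_scenario
    imp = impute_expression(transfer_result.anchors_round1, scenario["ref"],
                            k_impute=30)
    truth = scenario["truth"]
    frame = pd.DataFrame(imp.layer("raw"),
                         index=transfer_result.table.index,
                         columns=scenario["ref"].genes)
    means = frame.groupby(truth.cluster.loc[frame.index]).mean()
    true_means = {
        cl.name: cl.mean_expression
        for sub in scenario["config"].subclasses for cl in sub.clusters
    }
    for name, row in means.iterrows():
        assert np.corrcoef(row, true_means[name])[0, 1] > 0.9
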