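"""Weighted composition vectors, Leiden modules, and two-level recovery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from spatlas.config import AnalysisConfig
from spatlas.spatial_modules import (
    CompositionMatrix,
    cluster_compositions,
    local_composition,
    merge_indistinct_modules,
    merge_small_modules,
    module_composition_summary,
    two_level_modules,
)


def brute_force_composition(cells, k, bandwidth_multiplier, bandwidth_neighbor=5):
    """Direct double-loop evaluation of the weighted composition formula."""
    types = sorted(cells["subclass"].unique())
    out = np.zeros((len(cells), len(types)))
    for sec, section in cells.groupby("section_id"):
        coords = section[["x", "y"]].to_numpy()
        labels = section["subclass"].to_numpy()
        rows = section.index.to_numpy()
        for a, i in enumerate(rows):
            d = np.sqrt(((coords - coords[a]) ** 2).sum(axis=1))
            order = np.argsort(d, kind="stable")
            d0 = bandwidth_multiplier * d[order[bandwidth_neighbor]]
            for b in order[1:k + 1]:
                w = np.exp(-((d[b] / d0) ** 2))
                out[i, types.index(labels[b])] += w
    return CompositionMatrix(list(cells["cell_id"]), types, out)


def random_cells(n=400, n_types=4, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "section_id": rng.choice(["s1", "s2"], n),
        "x": rng.uniform(0, 500, n),
        "y": rng.uniform(0, 500, n),
        "subclass": rng.choice([f"T{t}" for t in range(n_types)], n),
    }).sort_values("section_id", ignore_index=True)


def test_weight_formula_reference_points():
    # one centre, 5 close spacers to pin the bandwidth, probes at D0 and 2*D0
    cells = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(12)],
        "section_id": "s1",
        "x": [0.0, 1.0, -1.0, 0.0, 0.0, 1.0, 2.0, 4.0, 50.0, 60.0, 70.0, 80.0],
        "y": [0.0, 0.0, 0.0, 1.0, -1.0, 1.0, 0.0, 0.0, 50.0, 60.0, 70.0, 80.0],
        "subclass": ["centre"] + ["S"] * 5 + ["P1", "P2"] + ["far"] * 4,
    })
    comp = local_composition(cells, k=7, bandwidth_multiplier=1.0,
                             bandwidth_neighbor=5)
    frame = comp.frame()
    # D_i0 = 1 x distance to 5th NN = sqrt(2); probes at 2 and 4
    assert frame.loc["c0", "P1"] == pytest.approx(np.exp(-(2.0 / np.sqrt(2)) ** 2))
    assert frame.loc["c0", "P2"] == pytest.approx(np.exp(-(4.0 / np.sqrt(2)) ** 2))


def test_single_type_neighbourhood_is_one_entry():
    rng = np.random.default_rng(1)
    cells = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(80)],
        "section_id": "s1",
        "x": rng.uniform(0, 100, 80),
        "y": rng.uniform(0, 100, 80),
        "subclass": "A",
    })
    comp = local_composition(cells, k=50, bandwidth_multiplier=2.0)
    assert comp.types == ["A"]
    assert (comp.values > 0).all()
    assert (comp.values.sum(axis=1) <= 50 + 1e-9).all()


@pytest.mark.parametrize("multiplier", [1.0, 2.0])
def test_composition_matches_brute_force(multiplier):
    cells = random_cells(n=400, seed=2)
    comp = local_composition(cells, k=50, bandwidth_multiplier=multiplier)
    oracle = brute_force_composition(cells, k=50, bandwidth_multiplier=multiplier)
    assert comp.types == oracle.types
    a = comp.frame().loc[oracle.cell_ids]
    np.testing.assert_allclose(a.to_numpy(), oracle.values, atol=1e-10)


def test_composition_scale_invariance():
    cells = random_cells(n=300, seed=3)
    comp = local_composition(cells, k=50, bandwidth_multiplier=2.0)
    doubled = cells.assign(x=cells["x"] * 2, y=cells["y"] * 2)
    comp2 = local_composition(doubled, k=50, bandwidth_multiplier=2.0)
    np.testing.assert_allclose(comp.values, comp2.values, atol=1e-10)


def test_excluded_types_absent_from_vectors_and_pool():
    cells = random_cells(n=400, seed=4)
    comp = local_composition(cells, k=50, bandwidth_multiplier=2.0,
                             exclude={"T0"})
    assert "T0" not in comp.types
    assert len(comp.cell_ids) == (cells["subclass"] != "T0").sum()


def test_coincident_points_rejected():
    cells = random_cells(n=200, seed=5)
    cells.loc[:6, "x"] = 1.0
    cells.loc[:6, "y"] = 1.0
    cells.loc[:6, "section_id"] = "s1"
    with pytest.raises(ValueError, match="bandwidth"):
        local_composition(cells, k=50, bandwidth_multiplier=2.0)


def test_clustering_is_scale_invariant_per_row_and_splits_domains(nested_domains):
    cells = nested_domains["cells"]
    comp = local_composition(cells, k=50, bandwidth_multiplier=2.0)
    labels = cluster_compositions(comp, resolution=0.3, seed=0)
    assert adjusted_rand_score(nested_domains["coarse"].loc[labels.index],
                               labels) == pytest.approx(1.0)
    # scaling any row by c > 0 leaves its normalized vector unchanged
    scaled = CompositionMatrix(comp.cell_ids, comp.types, comp.values * 7.5)
    labels2 = cluster_compositions(scaled, resolution=0.3, seed=0)
    assert (labels2 == labels).all()
    bad = CompositionMatrix(["a", "b"], ["t"], np.array([[0.0], [1.0]]))
    with pytest.raises(ValueError, match="zero"):
        cluster_compositions(bad, resolution=1.0)


def test_merge_small_modules_absorbs_and_reaches_fixed_point():
    rng = np.random.default_rng(6)
    n = 300
    cells = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "section_id": "s1",
        "x": rng.uniform(0, 100, n),
        "y": rng.uniform(0, 100, n),
    })
    labels = pd.Series(["big"] * (n - 3) + ["tiny"] * 3,
                       index=cells["cell_id"])
    merged = merge_small_modules(cells, labels, min_cells=10)
    assert (merged == "big").all()
    again = merge_small_modules(cells, merged, min_cells=10)
    assert (again == merged).all()
    # all modules above threshold: identity
    balanced = pd.Series(["a"] * 150 + ["b"] * 150, index=cells["cell_id"])
    assert (merge_small_modules(cells, balanced, min_cells=10) == balanced).all()


def test_merge_indistinct_modules_unifies_identical_profiles():
    values = np.vstack([np.tile([1.0, 0.0], (50, 1)),
                        np.tile([0.99, 0.01], (50, 1)),
                        np.tile([0.0, 1.0], (50, 1))])
    comp = CompositionMatrix([f"c{i}" for i in range(150)], ["A", "B"], values)
    labels = pd.Series([0] * 50 + [1] * 50 + [2] * 50, index=comp.cell_ids)
    merged = merge_indistinct_modules(comp, labels, cos_threshold=0.98)
    assert merged.nunique() == 2
    assert merged.iloc[0] == merged.iloc[60]
    assert merged.iloc[0] != merged.iloc[120]


def test_two_level_recovery_on_nested_domains(nested_domains):
    cells = nested_domains["cells"]
    modules = two_level_modules(cells, AnalysisConfig(min_module_cells=100), seed=0)
    ari1 = adjusted_rand_score(nested_domains["coarse"].loc[modules.index],
                               modules["level1"])
    assert ari1 >= 0.9
    fine = nested_domains["fine"].loc[modules.index]
    ari2 = adjusted_rand_score(fine, modules["level2"])
    assert ari2 >= 0.8
    # level-2 ids are nested within their level-1 parent
    with_l2 = modules[modules["level2"] != ""]
    assert (with_l2.apply(lambda r: r["level2"].startswith(f"{r['level1']}."),
                          axis=1)).all()


def test_non_neurons_get_level1_only(nested_domains):
    cells = nested_domains["cells"]
    modules = two_level_modules(
        cells, AnalysisConfig(min_module_cells=100), seed=0,
        neuronal_subclasses={"A"},
    )
    is_b = cells.set_index("cell_id").loc[modules.index, "subclass"] == "B"
    assert (modules.loc[is_b.to_numpy(), "level2"] == "").all()
    assert (modules["level1"] != "").all()


def test_module_composition_summary_rows_sum_to_one(nested_domains):
    cells = nested_domains["cells"]
    modules = two_level_modules(cells, AnalysisConfig(min_module_cells=100), seed=0)
    summary = module_composition_summary(cells, modules, "level1")
    np.testing.assert_allclose(summary.sum(axis=1), 1.0)
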