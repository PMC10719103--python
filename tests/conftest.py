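"""Shared synthetic fixtures for the test suite.

Everything is generated in-process from seeded configs; nothing is read
from disk.  Expensive scenario builds (the CSR interaction field, the
paired reference/query integration data) are session-scoped so unit and
acceptance tests share one realization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spatlas.simulate import (
    AttractionRule,
    ClusterSpec,
    DomainSpec,
    GradientRule,
    SimulationConfig,
    SubclassSpec,
    simulate_cells,
    simulate_expression,
    simulate_reference,
)

EIGHT_TYPES = list("ABCDEFGH")


def csr_interaction_config(seed: int) -> SimulationConfig:
    """Attraction-free field: 8 equally mixed types, 2 sections, ~5,000 cells."""
    subs = [
        SubclassSpec(t, [ClusterSpec(f"{t}.0", np.ones(1))]) for t in EIGHT_TYPES
    ]
    dom = [DomainSpec("field", (0, 1500), (0, 1500),
                      {t: 1 / 8 for t in EIGHT_TYPES})]
    return SimulationConfig(
        genes=["g0"], subclasses=subs, domains=dom,
        base_intensity=1200, n_sections=2, seed=seed,
    )


def csr_cells(seed: int) -> pd.DataFrame:
    cells, _ = simulate_cells(csr_interaction_config(seed))
    cells["subclass_confidence"] = 1.0
    return cells


def paired_integration_config(n_genes: int = 200, seed: int = 1) -> SimulationConfig:
    """5 subclasses x 3 clusters with subclass programs + cluster markers."""
    rng = np.random.default_rng(seed)
    subs = []
    for s in range(5):
        base = np.zeros(n_genes)
        base[rng.choice(n_genes, 20, replace=False)] = 6.0
        clusters = []
        for c in range(3):
            mean = base + 0.3
            mean[rng.choice(n_genes, 8, replace=False)] += 4.0
            clusters.append(ClusterSpec(f"S{s}.C{c}", mean, dispersion=10.0))
        subs.append(SubclassSpec(f"S{s}", clusters))
    dom = [DomainSpec("field", (0, 2000), (0, 2000),
                      {f"S{s}": 0.2 for s in range(5)})]
    return SimulationConfig(
        genes=[f"g{i}" for i in range(n_genes)], subclasses=subs,
        domains=dom, base_intensity=500, seed=seed,
    )


@pytest.fixture(scope="session")
def integration_scenario():
    """Paired query (spatial) and reference (dissociated) datasets + truth."""
    config = paired_integration_config()
    cells, truth = simulate_cells(config)
    query = simulate_expression(cells, config)
    ref, ref_labels = simulate_reference(config, n_cells_per_cluster=134)
    return {
        "config": config, "cells": cells, "truth": truth,
        "query": query, "ref": ref, "ref_labels": ref_labels,
    }


def nested_domain_cells(seed: int = 0):
    """Two coarse domains (distinct subclasses) each split in two by cluster.

    Domains are separated by margins well above the composition bandwidth
    so module boundaries are unambiguous.
    """
    genes = [f"g{i}" for i in range(5)]
    subs = [
        SubclassSpec("A", [ClusterSpec(f"A.{c}", np.ones(5)) for c in range(2)]),
        SubclassSpec("B", [ClusterSpec(f"B.{c}", np.ones(5)) for c in range(2)]),
    ]
    doms = [
        DomainSpec("L", (0, 925), (0, 1000), {"A": 1.0}),
        DomainSpec("R", (1075, 2000), (0, 1000), {"B": 1.0}),
    ]
    config = SimulationConfig(genes=genes, subclasses=subs, domains=doms,
                              base_intensity=1500, seed=seed)
    cells, truth = simulate_cells(config)
    # fine structure: cluster follows the y coordinate, with a carved margin
    cells["cluster"] = [
        f"{s}.{0 if y < 425 else (1 if y > 575 else 2)}"
        for s, y in zip(cells["subclass"], cells["y"])
    ]
    cells = cells[~cells["cluster"].str.endswith("2")].reset_index(drop=True)
    coarse = truth.domain.loc[cells["cell_id"]]
    fine = pd.Series(
        [f"{d}{0 if y < 500 else 1}" for d, y in zip(coarse, cells["y"])],
        index=cells["cell_id"],
    )
    return cells, coarse, fine


@pytest.fixture(scope="session")
def nested_domains():
    cells, coarse, fine = nested_domain_cells(seed=0)
    return {"cells": cells, "coarse": coarse, "fine": fine}


def gradient_config(slope: float, seed: int = 0, n_genes: int = 30,
                    n_gradient_genes: int = 12) -> SimulationConfig:
    """One subclass whose first genes drift log-linearly along x."""
    genes = [f"g{i}" for i in range(n_genes)]
    mean = np.full(n_genes, 4.0)
    subs = [SubclassSpec("S", [ClusterSpec("S.0", mean, dispersion=np.inf)])]
    dom = [DomainSpec("field", (0, 1000), (0, 1000), {"S": 1.0})]
    rules = (
        [GradientRule("S", (1.0, 0.0), genes[:n_gradient_genes], slope)]
        if slope else []
    )
    return SimulationConfig(genes=genes, subclasses=subs, domains=dom,
                            base_intensity=2000, gradient_rules=rules, seed=seed)
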