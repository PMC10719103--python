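"""Analysis configuration: every stage tunable, defaulted to the published values."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Flat bag of pipeline tunables with round-trippable YAML serialization.

    Defaults reproduce the published whole-brain MERFISH analysis settings;
    any field can be overridden per run.  All radii and thresholds must be
    strictly positive.
    """

    seed: int = 0

    # preprocessing
    volume_bounds_3z: tuple[float, float] = (50.0, 1500.0)
    volume_bounds_5z: tuple[float, float] = (80.0, 2500.0)
    volume_bounds_6z: tuple[float, float] = (100.0, 3000.0)
    mean_total_target: float = 250.0
    total_count_quantile: float = 0.01
    doublet_threshold: float = 0.25

    # panel selection
    deg_min_fold: float = 2.0
    deg_max_p: float = 0.01
    deg_min_fg_fraction: float = 0.5
    deg_min_fraction_ratio: float = 3.3
    deg_top_per_pair: int = 50
    deg_test: str = "wilcoxon"
    min_probe_capacity: int = 40
    max_cluster_mean: float = 3000.0
    panel_target_per_pair: int = 3

    # integration
    n_partitions: int = 50
    integration_total: float = 1000.0
    n_pca_dims: int = 100
    n_cca_dims: int = 100
    knn_subclass_graph: int = 15
    k_anchor_mnn: int = 5
    k_anchor_transfer: int = 100
    k_impute: int = 30
    max_fit_cells: int = 100000
    subclass_conf_threshold: float = 0.8
    cluster_conf_threshold: float = 0.5
    partition_balance_tol: float = 0.2

    # annotation
    nt_count_threshold: int = 2
    complexity_k: int = 50

    # spatial modules
    module_k: int = 50
    bandwidth_neighbor: int = 5
    level1_bandwidth_multiplier: float = 2.0
    level2_bandwidth_multiplier: float = 1.0
    leiden_knn: int = 15
    level1_resolution: float = 1.0
    level2_resolution: float = 2.0
    min_module_cells: int = 200

    # gradients
    purity_k: int = 50
    purity_pca_dims: int = 50

    # interactions
    r_proximal_strict: float = 15.0
    r_proximal_relaxed: float = 30.0
    r_randomization: float = 100.0
    n_randomization_rounds: int = 1000
    interaction_alpha: float = 0.05
    min_observed_pairs: int = 50
    enrichment_threshold_default: float = 2.0
    enrichment_threshold_stringent: float = 6.0
    enrichment_threshold_astrocyte: float = 1.0
    min_nonneuronal_cells: int = 50
    stringent_regions: tuple[str, ...] = (
        "anterior hypothalamus", "posterior hypothalamus",
        "anterior midbrain", "posterior midbrain", "pons", "medulla",
    )

    # signaling
    lr_min_fold: float = 2.0
    lr_max_padj: float = 0.01
    lr_min_nonzero_fraction: float = 0.4

    def __post_init__(self) -> None:
        positive = [
            self.mean_total_target, self.doublet_threshold, self.deg_min_fold,
            self.r_proximal_strict, self.r_proximal_relaxed, self.r_randomization,
            self.interaction_alpha, self.lr_min_fold,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("all radii and thresholds must be strictly positive")
        if self.r_proximal_relaxed >= self.r_randomization:
            raise ValueError("R_proximal must be smaller than R_randomization")

    def to_yaml(self, path: str | Path) -> None:
        data = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            data[f.name] = list(v) if isinstance(v, tuple) else v
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                v = data[f.name]
                if isinstance(getattr(cls(), f.name), tuple):
                    v = tuple(v)
                kwargs[f.name] = v
        return cls(**kwargs)
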