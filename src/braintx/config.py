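"""Pipeline configuration.

A flat dataclass holding every tunable parameter of the pipeline, with
domain validation, YAML round-trip, and rejection of unknown keys so a
typo in a config file fails loudly rather than silently using a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # synthetic inputs
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 4.0
    mask_kind: str = "ellipsoid"
    n_studies: int = 8
    peak_noise_sd: float = 0.1
    n_donors: int = 6
    n_samples_per_donor: int = 40
    n_genes: int = 120
    probes_per_gene: int = 3
    n_true_genes: int = 20
    target_r: float = 0.6
    pooled_effect: float = 0.8
    autocorr_length_mm: float = 15.0
    n_gene_sets: int = 20
    edge_density: float = 0.02
    n_terms: int = 5
    # meta-analysis
    fwhm_mm: float = 20.0
    p_voxel: float = 0.005
    extent: int = 20
    # expression preprocessing
    min_frac: float = 0.5
    min_r: float = 0.2
    top_frac_ds: float = 0.5
    per_donor: bool = True
    ds_method: str = "spearman"
    # association
    radius_mm: float = 3.0
    alpha: float = 0.05
    # surrogate null
    n_perm: int = 200
    surrogate_mode: str = "map_surrogate"
    k_grid: tuple[int, ...] | None = None
    rank_match: bool = True
    # annotation
    min_edge_score: float = 0.9
    hub_top_frac: float = 0.10
    behavior_threshold: float = 0.2
    # randomness
    seed: int = 0
    # paths
    outdir: str = "results/pipeline"

    def __post_init__(self) -> None:
        checks = [
            (self.voxel_size_mm > 0, "voxel_size_mm must be > 0"),
            (all(s >= 4 for s in self.grid_shape), "grid axes must be >= 4"),
            (self.fwhm_mm > 0, "fwhm_mm must be > 0"),
            (0 < self.p_voxel < 1, "p_voxel must lie in (0, 1)"),
            (self.extent >= 1, "extent must be >= 1"),
            (0 <= self.min_frac <= 1, "min_frac must lie in [0, 1]"),
            (-1 <= self.min_r <= 1, "min_r must lie in [-1, 1]"),
            (0 < self.top_frac_ds <= 1, "top_frac_ds must lie in (0, 1]"),
            (self.radius_mm > 0, "radius_mm must be > 0"),
            (0 < self.alpha < 1, "alpha must lie in (0, 1)"),
            (self.n_perm >= 1, "n_perm must be >= 1"),
            (self.surrogate_mode in ("map_surrogate", "per_gene_surrogates"),
             "unknown surrogate_mode"),
            (0 <= self.min_edge_score <= 1, "min_edge_score must lie in [0, 1]"),
            (0 < self.hub_top_frac <= 1, "hub_top_frac must lie in (0, 1]"),
            (abs(self.target_r) < 1, "|target_r| must be < 1"),
            (self.n_true_genes <= self.n_genes, "n_true_genes must be <= n_genes"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_shape", "k_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path!r} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        if self.k_grid is not None:
            d["k_grid"] = list(self.k_grid)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
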