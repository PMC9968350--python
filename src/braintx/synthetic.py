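"""Synthetic inputs with known ground truth.

Generates every input the pipeline consumes — a toy brain grid and mask,
study peak tables with a known pooled effect, a multi-donor spatially
autocorrelated expression dataset with planted target-correlated genes,
and annotation assets (gene sets, a PPI-style edge list, term activation
maps) — so every downstream stage can be tested end to end without any
external download.

Expression fields use an exponential spatial covariance exp(-d/lambda)
over Euclidean mm distance between sample locations, reflecting that
nearby tissue samples have more similar expression than distant ones.
A gene planted to correlate with a target map at population level r is
built as r*standardize(t) + sqrt(1-r^2)*standardize(e) where t holds the
sphere-sampled target values and e is an independent field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans

from .meta import Peak, StudyRecord, t_to_effect
from .volume import VolumeMap

__all__ = [
    "ToyBrainSpec",
    "SyntheticTruth",
    "ProbeTable",
    "SyntheticExpressionData",
    "DEFAULT_STUDY_SIZES",
    "gen_brain_grid",
    "gen_study_peaks",
    "gen_expression_dataset",
    "gen_annotation_assets",
]

#: (patients, controls) of the eight published resting-state studies in the
#: meta-analytic cohort; totals 500 patients and 469 controls.
DEFAULT_STUDY_SIZES: tuple[tuple[int, int], ...] = (
    (72, 79),
    (69, 74),
    (44, 26),
    (32, 32),
    (48, 31),
    (124, 102),
    (100, 100),
    (11, 25),
)


@dataclass(frozen=True)
class ToyBrainSpec:
    """Geometry of the synthetic analysis grid."""

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 4.0
    mask_kind: str = "ellipsoid"  # or "full_cube"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must have 3 axes, each >= 4")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.mask_kind not in ("full_cube", "ellipsoid"):
            raise ValueError(f"unknown mask_kind {self.mask_kind!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted into the synthetic inputs."""

    true_gene_ids: tuple[str, ...]
    target_r: float = 0.6
    pooled_effect: tuple[float, ...] = (0.8,)
    cluster_centers_mm: tuple[tuple[float, float, float], ...] = ((0.0, 0.0, 0.0),)
    autocorr_length_mm: float = 15.0

    def __post_init__(self) -> None:
        if not abs(self.target_r) < 1:
            raise ValueError("|target_r| must be < 1")
        if self.autocorr_length_mm < 0:
            raise ValueError("autocorr_length_mm must be >= 0")
        if len(self.pooled_effect) != len(self.cluster_centers_mm):
            raise ValueError("one pooled effect per cluster centre required")


@dataclass
class ProbeTable:
    """Probe-level expression with background flags and sample annotations."""

    probes: pd.DataFrame          # index probe_id, column gene_id
    expression: pd.DataFrame      # probes x samples
    above_background: pd.DataFrame  # bool, probes x samples
    samples: pd.DataFrame         # index sample_id: donor, region, hemisphere,
                                  # structure, x, y, z

    def __post_init__(self) -> None:
        if self.expression.shape != self.above_background.shape:
            raise ValueError("expression and above_background shapes must agree")
        if not self.expression.index.equals(self.probes.index):
            raise ValueError("expression rows must match the probe table")


@dataclass
class SyntheticExpressionData:
    """A full synthetic expression input plus its ground truth."""

    probe_table: ProbeTable
    rnaseq: pd.DataFrame          # genes x samples reference
    target_values: pd.Series      # per-sample sphere-sampled target map values
    truth: SyntheticTruth
    gene_signal: pd.DataFrame = field(repr=False, default=None)  # samples x genes


def gen_brain_grid(spec: ToyBrainSpec) -> VolumeMap:
    """Build the analysis grid: affine centred on the origin, cube or ellipsoid mask.

    The ellipsoid's semi-axes are half the grid extent along each axis, so
    it is the largest ellipsoid inscribed in the grid.
    """
    shape = np.array(spec.grid_shape)
    vs = spec.voxel_size_mm
    affine = np.eye(4)
    affine[:3, :3] *= vs
    affine[:3, 3] = -(shape - 1) / 2.0 * vs  # voxel-centre grid centred at 0 mm

    if spec.mask_kind == "full_cube":
        mask = np.ones(spec.grid_shape, dtype=bool)
    else:
        semi = shape * vs / 2.0
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        xyz = np.stack([ii, jj, kk], axis=-1) * vs + affine[:3, 3]
        mask = np.sum((xyz / semi) ** 2, axis=-1) <= 1.0
    return VolumeMap(np.zeros(spec.grid_shape), affine, mask)


def _snap_to_grid(grid: VolumeMap, xyz: np.ndarray) -> np.ndarray:
    """Nearest voxel-centre mm coordinate to each mm point."""
    ijk = np.rint(grid.mm_to_voxel(xyz)).astype(int)
    ijk = np.clip(ijk, 0, np.array(grid.shape) - 1)
    return grid.voxel_to_mm(ijk)


def gen_study_peaks(
    n_studies: int,
    truth: SyntheticTruth,
    grid: VolumeMap,
    noise_sd: float = 0.1,
    seed: int = 0,
    group_sizes: tuple[tuple[int, int], ...] | None = None,
) -> list[StudyRecord]:
    """Generate study peak tables around the planted cluster centres.

    Each study reports one peak per cluster centre with Hedges g drawn as
    pooled_effect + N(0, noise_sd^2); the stored t statistic is the exact
    back-conversion so the meta-analysis recovers the drawn g.  Group
    sizes default to the published eight-study cohort, cycled.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    centers = np.array(truth.cluster_centers_mm, dtype=float)
    if not np.all(grid.contains_mm(centers)):
        raise ValueError("all cluster centres must lie inside the mask")
    centers = _snap_to_grid(grid, centers)
    if group_sizes is None:
        group_sizes = DEFAULT_STUDY_SIZES
    rng = np.random.default_rng(seed)

    studies = []
    for s in range(n_studies):
        n1, n2 = group_sizes[s % len(group_sizes)]
        df = n1 + n2 - 2
        J = 1.0 - 3.0 / (4.0 * df - 1.0)
        scale = math.sqrt(1.0 / n1 + 1.0 / n2)
        peaks = []
        for c, eff in zip(centers, truth.pooled_effect):
            g = eff + rng.normal(0.0, noise_sd) if noise_sd > 0 else eff
            t = g / (J * scale)
            peaks.append(Peak(float(c[0]), float(c[1]), float(c[2]), float(t)))
        studies.append(
            StudyRecord(study_id=f"study_{s + 1:02d}", n_patients=n1, n_controls=n2,
                        peaks=peaks, measure="ALFF")
        )
    return studies


def _grf_cholesky(coords: np.ndarray, length_mm: float) -> np.ndarray:
    """Cholesky factor of the exponential covariance exp(-d/lambda)."""
    n = len(coords)
    if length_mm <= 0:
        return np.eye(n)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cov = np.exp(-d / length_mm)
    cov[np.diag_indices(n)] += 1e-8  # numerical jitter
    return np.linalg.cholesky(cov)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardise a constant vector")
    return (x - x.mean()) / sd


def gen_expression_dataset(
    grid: VolumeMap,
    target_map: VolumeMap,
    n_donors: int = 6,
    n_samples_per_donor: int = 50,
    n_genes: int = 200,
    probes_per_gene: int = 3,
    truth: SyntheticTruth | None = None,
    seed: int = 0,
    n_regions: int = 12,
    probe_noise_sd: float = 0.2,
    donor_offset_sd: float = 0.3,
    donor_scale_sd: float = 0.1,
    below_background_frac: float = 0.6,
    decoy_sample_frac: float = 0.0,
    rnaseq_noise_sd: float = 0.1,
    sphere_radius_mm: float = 3.0,
) -> SyntheticExpressionData:
    """Simulate a multi-donor probe-level expression dataset.

    Gene-level spatial signals are single Gaussian random fields over the
    union of all sample coordinates (exponential covariance, length scale
    ``truth.autocorr_length_mm``) so that regional profiles agree across
    donors.  Genes named in ``truth.true_gene_ids`` instead mix the
    sphere-sampled target-map values with an independent field so their
    population correlation with the target equals ``truth.target_r``.

    Probe-level decoys exercise the preprocessing filters: the last probe
    of each true gene is flagged below background in
    ``below_background_frac`` of samples, and when ``probes_per_gene >= 3``
    the middle probe is pure noise (near-zero correlation with the RNA-seq
    reference).  Optional decoy samples carry right-hemisphere or
    subcortical labels.
    """
    if n_donors < 2:
        raise ValueError("differential stability needs at least 2 donors")
    if n_samples_per_donor < 10:
        raise ValueError("need at least 10 samples per donor")
    if target_map.shape != grid.shape or not np.allclose(target_map.affine, grid.affine):
        raise ValueError("target map must share the analysis grid")
    if truth is None:
        truth = SyntheticTruth(true_gene_ids=())

    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    unknown = set(truth.true_gene_ids) - set(gene_ids)
    if unknown:
        raise ValueError(f"true genes outside the generated universe: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n_samples = n_donors * n_samples_per_donor

    # sample locations: in-mask voxel centres, sampled with replacement per donor
    vox_mm = grid.mask_coordinates_mm()
    pick = rng.integers(0, len(vox_mm), size=n_samples)
    coords = vox_mm[pick]
    donors = np.repeat([f"donor{d + 1}" for d in range(n_donors)], n_samples_per_donor)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]

    # region labels from a spatial partition of the mask
    km = KMeans(n_clusters=min(n_regions, len(vox_mm)), n_init=1,
                random_state=int(rng.integers(0, 2**31 - 1)))
    km.fit(vox_mm)
    regions = np.array([f"region{r:02d}" for r in km.predict(coords)])

    hemisphere = np.full(n_samples, "left", dtype=object)
    structure = np.full(n_samples, "cortex", dtype=object)
    if decoy_sample_frac > 0:
        n_decoy = int(round(decoy_sample_frac * n_samples))
        decoys = rng.choice(n_samples, size=n_decoy, replace=False)
        half = len(decoys) // 2
        hemisphere[decoys[:half]] = "right"
        structure[decoys[half:]] = "subcortex"

    samples = pd.DataFrame(
        {
            "donor": donors,
            "region": regions,
            "hemisphere": hemisphere,
            "structure": structure,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # sphere-sampled target values at the sample coordinates
    from .association import extract_sphere_values

    tvals, valid = extract_sphere_values(target_map, coords, radius_mm=sphere_radius_mm,
                                         empty_policy="nearest")
    target_values = pd.Series(tvals, index=samples.index, name="target_value")
    t_std = _standardize(tvals)

    # gene-level spatial signals
    L = _grf_cholesky(coords, truth.autocorr_length_mm)
    fields = L @ rng.standard_normal((n_samples, n_genes))
    r = truth.target_r
    signal = np.empty((n_samples, n_genes))
    true_set = set(truth.true_gene_ids)
    for j, gid in enumerate(gene_ids):
        f = _standardize(fields[:, j])
        if gid in true_set:
            # orthogonalise the field against the target in-sample so the
            # realised correlation of the clean gene signal equals target_r
            f = f - np.dot(f, t_std) / np.dot(t_std, t_std) * t_std
            f = _standardize(f)
            signal[:, j] = r * t_std + math.sqrt(1 - r**2) * f
        else:
            signal[:, j] = f
    gene_signal = pd.DataFrame(signal, index=samples.index, columns=gene_ids)

    # donor offset/scale effects, removed later by per-donor normalisation
    offsets = rng.normal(0.0, donor_offset_sd, size=n_donors)
    scales = np.exp(rng.normal(0.0, donor_scale_sd, size=n_donors))
    donor_idx = np.repeat(np.arange(n_donors), n_samples_per_donor)
    expressed = signal * scales[donor_idx][:, None] + offsets[donor_idx][:, None]

    # probe-level expression
    probe_rows = []
    expr_rows = []
    above_rows = []
    for j, gid in enumerate(gene_ids):
        for p in range(probes_per_gene):
            pid = f"{gid}_p{p + 1}"
            if probes_per_gene >= 3 and p == 1:
                # decoy probe: pure noise, fails the RNA-seq correlation filter
                vals = rng.standard_normal(n_samples)
            else:
                vals = expressed[:, j] + rng.normal(0.0, probe_noise_sd, size=n_samples)
            above = np.ones(n_samples, dtype=bool)
            if gid in true_set and p == probes_per_gene - 1 and probes_per_gene > 1:
                n_below = int(round(below_background_frac * n_samples))
                below = rng.choice(n_samples, size=n_below, replace=False)
                above[below] = False
            probe_rows.append({"probe_id": pid, "gene_id": gid})
            expr_rows.append(vals)
            above_rows.append(above)

    probes = pd.DataFrame(probe_rows).set_index("probe_id")
    expression = pd.DataFrame(np.array(expr_rows), index=probes.index, columns=samples.index)
    above_background = pd.DataFrame(np.array(above_rows), index=probes.index,
                                    columns=samples.index)

    rnaseq = pd.DataFrame(
        gene_signal.to_numpy().T + rng.normal(0.0, rnaseq_noise_sd, size=(n_genes, n_samples)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=samples.index,
    )

    pt = ProbeTable(probes=probes, expression=expression,
                    above_background=above_background, samples=samples)
    return SyntheticExpressionData(probe_table=pt, rnaseq=rnaseq,
                                   target_values=target_values, truth=truth,
                                   gene_signal=gene_signal)


def gen_annotation_assets(
    gene_universe: list[str],
    n_sets: int = 20,
    edge_density: float = 0.02,
    n_terms: int = 5,
    grid: VolumeMap | None = None,
    seed: int = 0,
    target_list: list[str] | None = None,
    planted_odds_ratio: float = 4.0,
    set_size_range: tuple[int, int] = (10, 50),
    term_smooth_voxels: float = 2.0,
):
    """Generate gene-set, edge-list and term-map stand-ins.

    Returns ``(gene_sets, edges, term_maps)`` where ``gene_sets`` maps set
    names to gene lists (the first set, ``set_enriched``, is sampled with
    the planted odds ratio relative to ``target_list``), ``edges`` is a
    simple undirected scored edge list, and ``term_maps`` are smooth random
    fields on the grid.
    """
    if not gene_universe:
        raise ValueError("gene universe must be non-empty")
    if not 0 < edge_density < 1:
        raise ValueError("edge_density must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    universe = list(gene_universe)
    n = len(universe)
    if target_list is None:
        target_list = universe[: max(1, n // 5)]
    in_target = np.isin(universe, list(target_list))

    gene_sets: dict[str, list[str]] = {}
    # planted set: membership odds differ by planted_odds_ratio inside the target
    p0 = 0.15
    odds1 = planted_odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    member = np.where(in_target, rng.random(n) < p1, rng.random(n) < p0)
    gene_sets["set_enriched"] = [g for g, m in zip(universe, member) if m]
    for s in range(1, n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        size = min(size, n)
        picked = rng.choice(n, size=size, replace=False)
        gene_sets[f"set_{s:03d}"] = sorted(universe[i] for i in picked)

    # Erdos-Renyi style undirected edges with confidence scores
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < edge_density
    scores = rng.uniform(0.5, 1.0, size=int(keep.sum()))
    edges = pd.DataFrame(
        {
            "gene_a": [universe[i] for i in iu[keep]],
            "gene_b": [universe[j] for j in ju[keep]],
            "score": scores,
        }
    )

    term_maps = []
    if grid is not None:
        for t in range(n_terms):
            noise = rng.standard_normal(grid.shape)
            smooth = ndimage.gaussian_filter(noise, sigma=term_smooth_voxels)
            term_maps.append(grid.with_data(smooth))
    return gene_sets, edges, term_maps
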