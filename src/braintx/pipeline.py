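"""End-to-end orchestration on synthetic inputs.

Stages run in the fixed analysis order — meta-analysis, expression
preprocessing, spatial association, spatially constrained permutation
test, gene annotation — with every artifact written under the configured
output directory and listed, with a content hash and the seeds used, in a
JSON manifest.  All randomness flows from the single config seed through
named per-stage substream seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, association, expression, io, meta, surrogates, synthetic
from .config import PipelineConfig
from .volume import write_volume

__all__ = ["run_pipeline", "stage_seeds", "make_inputs"]

logger = logging.getLogger(__name__)


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive one named substream seed per stage from the master seed."""
    ss = np.random.SeedSequence(seed)
    names = ["grid", "peaks", "expression", "annotation_assets", "surrogate"]
    children = ss.spawn(len(names))
    return {name: int(c.generate_state(1)[0] % (2**31 - 1))
            for name, c in zip(names, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_inputs(config: PipelineConfig, seeds: dict[str, int] | None = None):
    """Build the deterministic synthetic inputs for a configuration.

    Returns ``(grid, truth, studies)`` so stage-wise drivers can reconstruct
    the exact inputs of a pipeline run from the config alone.
    """
    seeds = seeds if seeds is not None else stage_seeds(config.seed)
    spec = synthetic.ToyBrainSpec(grid_shape=config.grid_shape,
                                  voxel_size_mm=config.voxel_size_mm,
                                  mask_kind=config.mask_kind, seed=seeds["grid"])
    grid = synthetic.gen_brain_grid(spec)
    gene_ids = tuple(f"G{i + 1:04d}" for i in range(config.n_true_genes))
    extent_mm = np.array(config.grid_shape) * config.voxel_size_mm
    center = (-extent_mm[0] / 4, 0.0, 0.0)  # off-centre, inside the ellipsoid
    truth = synthetic.SyntheticTruth(
        true_gene_ids=gene_ids,
        target_r=config.target_r,
        pooled_effect=(config.pooled_effect,),
        cluster_centers_mm=(center,),
        autocorr_length_mm=config.autocorr_length_mm,
    )
    studies = synthetic.gen_study_peaks(config.n_studies, truth, grid,
                                        noise_sd=config.peak_noise_sd,
                                        seed=seeds["peaks"])
    return grid, truth, studies


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic inputs and return the output manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    logger.info("resolved config: %s", json.dumps(config.to_dict(), sort_keys=True))

    grid, truth, studies = make_inputs(config, seeds)

    # --- meta-analysis ----------------------------------------------------
    maps, result, clusters = meta.run_meta_analysis(
        studies, grid, fwhm_mm=config.fwhm_mm,
        p_voxel=config.p_voxel, extent=config.extent)
    het = meta.heterogeneity_report(result, clusters)
    bias = meta.small_study_tests(maps, result, clusters) if len(studies) >= 3 else None

    # --- synthetic expression against the real z map ----------------------
    data = synthetic.gen_expression_dataset(
        grid, result.z_map,
        n_donors=config.n_donors,
        n_samples_per_donor=config.n_samples_per_donor,
        n_genes=config.n_genes,
        probes_per_gene=config.probes_per_gene,
        truth=truth,
        seed=seeds["expression"],
        sphere_radius_mm=config.radius_mm,
    )

    # --- expression preprocessing -----------------------------------------
    bundle = expression.preprocess(
        data.probe_table, data.rnaseq, grid,
        min_frac=config.min_frac, min_r=config.min_r,
        top_frac_ds=config.top_frac_ds, per_donor=config.per_donor,
        ds_method=config.ds_method)

    # --- spatial association ----------------------------------------------
    assoc, zvec, kept = association.associate(
        bundle.expression, bundle.samples, result.z_map,
        radius_mm=config.radius_mm, alpha=config.alpha)
    sig_genes = assoc.index[assoc["significant"]].tolist()

    # --- surrogate permutation test ---------------------------------------
    coords = bundle.samples.loc[kept.index, ["x", "y", "z"]].to_numpy(dtype=float)
    D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    observed, null_counts, perm_p = surrogates.permutation_test_gene_count(
        kept, zvec.to_numpy(), D, n_perm=config.n_perm,
        mode=config.surrogate_mode, seed=seeds["surrogate"],
        alpha=config.alpha, k_grid=config.k_grid, rank_match=config.rank_match)

    # --- annotation ---------------------------------------------------------
    universe = list(assoc.index)
    gene_sets, edges, term_maps = synthetic.gen_annotation_assets(
        universe, n_sets=config.n_gene_sets, edge_density=config.edge_density,
        n_terms=config.n_terms, grid=grid, seed=seeds["annotation_assets"],
        target_list=sig_genes or None)
    enrichment = annotation.enrich_collection(sig_genes, gene_sets, universe,
                                              alpha=config.alpha)
    kept_edges = annotation.filter_edges(edges, min_score=config.min_edge_score,
                                         restrict_to=sig_genes)
    hubs = annotation.hub_genes(kept_edges, top_frac=config.hub_top_frac)
    term_dict = {f"term_{i:02d}": tm for i, tm in enumerate(term_maps)}
    if sig_genes:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            behavior = annotation.behavioral_relevance(
                kept[sig_genes], term_dict, coords,
                radius_mm=config.radius_mm, threshold=config.behavior_threshold)
    else:
        behavior = pd.DataFrame(columns=["term", "abs_r_mean", "n_genes", "selected"])

    # --- artifacts ----------------------------------------------------------
    artifacts: dict[str, Path] = {}

    def _save(name: str, fn) -> None:
        path = outdir / name
        fn(path)
        artifacts[name] = path

    _save("mask.nii", lambda p: write_volume(grid, p, what="mask"))
    _save("z_map.nii", lambda p: write_volume(result.z_map, p))
    _save("p_map.nii", lambda p: write_volume(result.p_map, p))
    _save("I2_map.nii", lambda p: write_volume(result.I2_map, p))
    _save("peaks.csv", lambda p: io.write_peak_table(studies, p))
    _save("clusters.csv",
          lambda p: clusters.drop(columns="_voxels").to_csv(p, index=False))
    _save("heterogeneity.csv", lambda p: het.to_csv(p, index=False))
    if bias is not None:
        _save("publication_bias.csv", lambda p: bias.to_csv(p, index=False))
    _save("expression.csv", lambda p: bundle.expression.to_csv(p))
    _save("samples.csv",
          lambda p: bundle.samples.loc[bundle.expression.index].to_csv(p))
    _save("ds_scores.csv", lambda p: bundle.ds.to_csv(p))
    _save("association.csv", lambda p: assoc.to_csv(p))
    _save("z_vector.csv", lambda p: zvec.to_csv(p))
    _save("null_counts.csv",
          lambda p: pd.Series(null_counts, name="n_significant").to_csv(p, index=False))
    _save("gene_sets.gmt", lambda p: io.write_gmt(gene_sets, p))
    _save("edges.tsv", lambda p: io.write_edges(edges, p))
    _save("enrichment.csv", lambda p: enrichment.to_csv(p))
    _save("hub_genes.csv", lambda p: hubs.to_csv(p))
    _save("behavior.csv", lambda p: behavior.to_csv(p, index=False))
    _save("truth.json", lambda p: p.write_text(json.dumps(
        {"true_gene_ids": list(truth.true_gene_ids),
         "target_r": truth.target_r,
         "pooled_effect": list(truth.pooled_effect),
         "cluster_centers_mm": [list(c) for c in truth.cluster_centers_mm],
         "autocorr_length_mm": truth.autocorr_length_mm}, indent=2)))

    manifest = {
        "config": config.to_dict(),
        "seeds": seeds,
        "n_significant_genes": int(len(sig_genes)),
        "observed_count": int(observed),
        "permutation_p": float(perm_p),
        "n_clusters": int(len(clusters)),
        "artifacts": {name: {"path": str(p), "sha256": _sha256(p)}
                      for name, p in artifacts.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
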