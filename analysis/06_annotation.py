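"""Stage 6 — enrichment, hub genes, and behavioural relevance."""

import warnings

import pandas as pd

from common import RESULTS, load_config, seeds_for

from braintx import annotation, io, synthetic
from braintx.pipeline import make_inputs


def main() -> None:
    cfg = load_config()
    seeds = seeds_for(cfg)
    grid, _, _ = make_inputs(cfg, seeds)
    assoc = pd.read_csv(RESULTS / "association.csv", index_col=0)
    expr = pd.read_csv(RESULTS / "expression.csv", index_col=0)
    samples = pd.read_csv(RESULTS / "samples.csv", index_col=0)
    zvec = pd.read_csv(RESULTS / "z_vector.csv", index_col=0)["z_value"]
    sig_genes = assoc.index[assoc["significant"]].tolist()
    universe = list(assoc.index)

    gene_sets, edges, term_maps = synthetic.gen_annotation_assets(
        universe, n_sets=cfg.n_gene_sets, edge_density=cfg.edge_density,
        n_terms=cfg.n_terms, grid=grid, seed=seeds["annotation_assets"],
        target_list=sig_genes or None)
    io.write_gmt(gene_sets, RESULTS / "gene_sets.gmt")
    io.write_edges(edges, RESULTS / "edges.tsv")

    annotation.enrich_collection(sig_genes, gene_sets, universe,
                                 alpha=cfg.alpha).to_csv(RESULTS / "enrichment.csv")
    kept_edges = annotation.filter_edges(edges, min_score=cfg.min_edge_score,
                                         restrict_to=sig_genes)
    hubs = annotation.hub_genes(kept_edges, top_frac=cfg.hub_top_frac)
    hubs.to_csv(RESULTS / "hub_genes.csv")

    coords = samples.loc[zvec.index, ["x", "y", "z"]].to_numpy(dtype=float)
    term_dict = {f"term_{i:02d}": tm for i, tm in enumerate(term_maps)}
    if sig_genes:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            behavior = annotation.behavioral_relevance(
                expr.loc[zvec.index, sig_genes], term_dict, coords,
                radius_mm=cfg.radius_mm, threshold=cfg.behavior_threshold)
    else:
        behavior = pd.DataFrame(columns=["term", "abs_r_mean", "n_genes",
                                         "selected"])
    behavior.to_csv(RESULTS / "behavior.csv", index=False)
    print(f"{len(sig_genes)} significant genes, {len(hubs)} hubs, "
          f"{int(behavior['selected'].sum()) if len(behavior) else 0} "
          f"behavioural terms selected -> {RESULTS}")


if __name__ == "__main__":
    main()
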