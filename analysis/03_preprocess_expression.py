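"""Stage 3 — simulate the donor expression dataset and preprocess it."""

from common import RESULTS, load_config, seeds_for

from braintx import expression, synthetic
from braintx.pipeline import make_inputs
from braintx.volume import read_volume


def main() -> None:
    cfg = load_config()
    seeds = seeds_for(cfg)
    grid, truth, _ = make_inputs(cfg, seeds)
    z_map = read_volume(RESULTS / "z_map.nii", mask_path=RESULTS / "mask.nii")
    data = synthetic.gen_expression_dataset(
        grid, z_map, n_donors=cfg.n_donors,
        n_samples_per_donor=cfg.n_samples_per_donor, n_genes=cfg.n_genes,
        probes_per_gene=cfg.probes_per_gene, truth=truth,
        seed=seeds["expression"], sphere_radius_mm=cfg.radius_mm)
    bundle = expression.preprocess(
        data.probe_table, data.rnaseq, grid, min_frac=cfg.min_frac,
        min_r=cfg.min_r, top_frac_ds=cfg.top_frac_ds, per_donor=cfg.per_donor,
        ds_method=cfg.ds_method)
    bundle.expression.to_csv(RESULTS / "expression.csv")
    bundle.samples.loc[bundle.expression.index].to_csv(RESULTS / "samples.csv")
    bundle.ds.to_csv(RESULTS / "ds_scores.csv")
    print(f"{bundle.expression.shape[0]} samples x "
          f"{bundle.expression.shape[1]} genes after preprocessing -> {RESULTS}")


if __name__ == "__main__":
    main()
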