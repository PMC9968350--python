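"""Stage 1 — generate the synthetic brain grid and study peak tables."""

import json

from common import RESULTS, load_config, seeds_for

from braintx import io
from braintx.pipeline import make_inputs
from braintx.volume import write_volume


def main() -> None:
    cfg = load_config()
    grid, truth, studies = make_inputs(cfg, seeds_for(cfg))
    write_volume(grid, RESULTS / "mask.nii", what="mask")
    io.write_peak_table(studies, RESULTS / "peaks.csv")
    (RESULTS / "truth.json").write_text(json.dumps(
        {"true_gene_ids": list(truth.true_gene_ids),
         "target_r": truth.target_r,
         "pooled_effect": list(truth.pooled_effect),
         "cluster_centers_mm": [list(c) for c in truth.cluster_centers_mm],
         "autocorr_length_mm": truth.autocorr_length_mm}, indent=2))
    print(f"wrote {len(studies)} studies, "
          f"{int(grid.mask.sum())} mask voxels -> {RESULTS}")


if __name__ == "__main__":
    main()
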