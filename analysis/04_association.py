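"""Stage 4 — gene-wise spatial correlation with the meta-analytic z map."""

import pandas as pd

from common import RESULTS, load_config

from braintx import association
from braintx.volume import read_volume


def main() -> None:
    cfg = load_config()
    z_map = read_volume(RESULTS / "z_map.nii", mask_path=RESULTS / "mask.nii")
    expr = pd.read_csv(RESULTS / "expression.csv", index_col=0)
    samples = pd.read_csv(RESULTS / "samples.csv", index_col=0)
    table, zvec, _ = association.associate(expr, samples, z_map,
                                           radius_mm=cfg.radius_mm,
                                           alpha=cfg.alpha)
    table.to_csv(RESULTS / "association.csv")
    zvec.to_csv(RESULTS / "z_vector.csv")
    n_sig = int(table["significant"].sum())
    print(f"{n_sig} genes significant at q <= {cfg.alpha} -> {RESULTS}")


if __name__ == "__main__":
    main()
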