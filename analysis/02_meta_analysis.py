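"""Stage 2 — effect-size meta-analysis of the simulated peak tables."""

from common import RESULTS, load_config

from braintx import io, meta
from braintx.volume import read_volume, write_volume


def main() -> None:
    cfg = load_config()
    grid = read_volume(RESULTS / "mask.nii", mask_path=RESULTS / "mask.nii")
    studies = io.read_peak_table(RESULTS / "peaks.csv")
    maps, result, clusters = meta.run_meta_analysis(
        studies, grid, fwhm_mm=cfg.fwhm_mm, p_voxel=cfg.p_voxel,
        extent=cfg.extent)
    write_volume(result.z_map, RESULTS / "z_map.nii")
    write_volume(result.p_map, RESULTS / "p_map.nii")
    write_volume(result.I2_map, RESULTS / "I2_map.nii")
    clusters.drop(columns="_voxels").to_csv(RESULTS / "clusters.csv", index=False)
    meta.heterogeneity_report(result, clusters).to_csv(
        RESULTS / "heterogeneity.csv", index=False)
    if len(studies) >= 3:
        meta.small_study_tests(maps, result, clusters).to_csv(
            RESULTS / "publication_bias.csv", index=False)
    print(f"{len(clusters)} clusters above threshold -> {RESULTS}")


if __name__ == "__main__":
    main()
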