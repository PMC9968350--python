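"""Shared plumbing for the numbered stage drivers.

Every stage loads the same configuration (analysis/config.yaml when present,
package defaults otherwise) and writes into results/, so the scripts can be
run in order to reproduce a full analysis stage by stage.
"""

from pathlib import Path

from braintx.config import PipelineConfig
from braintx.pipeline import stage_seeds

HERE = Path(__file__).resolve().parent
RESULTS = HERE.parent / "results"


def load_config() -> PipelineConfig:
    cfg_path = HERE / "config.yaml"
    if cfg_path.exists():
        cfg = PipelineConfig.from_yaml(cfg_path)
    else:
        cfg = PipelineConfig()
    cfg.outdir = str(RESULTS)
    RESULTS.mkdir(parents=True, exist_ok=True)
    return cfg


def seeds_for(cfg: PipelineConfig) -> dict[str, int]:
    return stage_seeds(cfg.seed)
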