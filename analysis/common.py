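"""Shared demo-cohort configuration for the numbered analysis scripts.

All scripts drive the same deterministic pipeline (root seed 11) and
write under results/pipeline; running a later script re-runs the
earlier stages, so each script is self-contained.
"""

from pathlib import Path

from exalarm.io import PipelineConfig

RESULTS = Path(__file__).resolve().parents[1] / "results" / "pipeline"


def demo_config(stages) -> PipelineConfig:
    return PipelineConfig(out_dir=str(RESULTS), seed=11,
                          stages=tuple(stages))


ALL_STAGES = ("simulate", "discover", "fit_dlm", "features",
              "train", "predict", "alarm", "evaluate")
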