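"""End-to-end benchmark pipeline: simulate -> extract -> train -> evaluate."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .config import PipelineConfig
from .evaluate import run_experiment
from .features import build_feature_table
from .synth import simulate_dataset


def run_pipeline(config: Optional[PipelineConfig] = None, output_dir=None) -> Dict:
    """Run the full pipeline from one master seed; optionally write outputs.

    Returns the experiment report (with the feature table attached under
    ``"_feature_table"`` and fitted models under ``"_fitted_models"``).
    """
    config = (config or PipelineConfig()).with_derived_seeds()
    recordings = simulate_dataset(config.generator)
    table = build_feature_table(recordings, config.extraction)
    report = run_experiment(table, config.experiment)
    report["config"]["master_seed"] = config.master_seed
    report["_feature_table"] = table

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_feature_table, write_recordings

        write_recordings(recordings, out / "recordings.jsonl")
        write_feature_table(table, out / "features.csv")
        for tag, m in report["_fitted_models"].items():
            (out / f"model_{tag}.json").write_text(m.to_json())
        serializable = {
            k: v for k, v in report.items() if not k.startswith("_")
        }
        (out / "report.json").write_text(json.dumps(serializable, indent=1))
    return report


def benchmark(
    master_seed: int,
    run_learning_curves: bool = False,
    wilcoxon_repeats: int = 0,
    bootstrap_reps: int = 200,
) -> Dict:
    """Default synthetic benchmark at a given master seed (no file output).

    Trimmed for speed: learning curves and the Wilcoxon comparison are off
    unless requested.
    """
    cfg = PipelineConfig(master_seed=master_seed)
    cfg.experiment.run_learning_curves = run_learning_curves
    cfg.experiment.wilcoxon_repeats = wilcoxon_repeats
    cfg.experiment.bootstrap_reps = bootstrap_reps
    return run_pipeline(cfg)


def basic_f1_replicates(seeds) -> np.ndarray:
    """Held-out test F1 of the basic-feature model across master seeds."""
    vals = []
    for s in seeds:
        rep = benchmark(int(s))
        vals.append(rep["models"]["basic"]["test"]["f1"])
    return np.array(vals)
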