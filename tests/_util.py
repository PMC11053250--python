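"""Shared helpers for the test suite."""
from __future__ import annotations

import numpy as np

from eibalance.pipeline import PipelineConfig, SimulateSection, analyze_dataset
from eibalance.preprocess import NormMatrix
from eibalance.simulate import generate_dataset


def run_sim_analysis(seed: int = 7, **sim_overrides) -> dict:
    """Generate a dataset and run the in-memory analysis stages."""
    cfg = PipelineConfig(seed=seed, simulate=SimulateSection(**sim_overrides))
    cm, st, sets, gt = generate_dataset(cfg.sim_config())
    bundle = analyze_dataset(cm, st, sets, cfg)
    bundle["ground_truth"] = gt
    bundle["config"] = cfg
    return bundle


def norm_from_values(values, barcodes=None, genes=None) -> NormMatrix:
    """Wrap a raw array as a NormMatrix with autogenerated names."""
    values = np.asarray(values, dtype=float)
    s, g = values.shape
    return NormMatrix(
        values,
        barcodes or [f"bc{i}" for i in range(s)],
        genes or [f"g{j}" for j in range(g)],
    )
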