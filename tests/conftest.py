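import logging

import numpy as np
import pytest

from hervtriage.pipeline import PipelineConfig, run_pipeline
from hervtriage.simulate import SimulationConfig

logging.getLogger("hervtriage").setLevel(logging.ERROR)

#: planted structure of the shared end-to-end run; sizes and effects are
#: chosen so every planted feature is comfortably powered at this scale
PLANTED = {
    "effects": [(3, 1.5), (17, 1.5)],
    "confounded": [25],
    "rare": [30, 31],
    "somatic": [35],
    "linked": [(30, 31)],
}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One powered end-to-end pipeline execution on synthetic data."""
    sim = SimulationConfig(
        seed=7,
        n_cases=200,
        n_controls=400,
        n_variants=40,
        case_effect_variants=PLANTED["effects"],
        confounded_variants=PLANTED["confounded"],
        rare_variants=PLANTED["rare"],
        rare_case_freq=0.15,
        somatic_variants=PLANTED["somatic"],
        somatic_shift=0.10,
        linked_pairs=PLANTED["linked"],
    )
    cfg = PipelineConfig(
        output_dir=str(tmp_path_factory.mktemp("pipeline")),
        seed=7,
        simulation=sim,
    )
    return cfg, run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
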