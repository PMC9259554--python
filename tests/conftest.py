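import numpy as np
import pandas as pd
import pytest

import pepstrat as pp

STUDY_SEED = 1  # fixed seed of the reference synthetic study conditions


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 4+4+4-sample synthetic dataset (24 spectra)."""
    cfg = pp.default_study_config(
        seed=11, n_samples={"CTL": 4, "IS": 4, "LPS": 4})
    spectra, manifest, truth = pp.generate_dataset(cfg)
    return cfg, spectra, manifest, truth


@pytest.fixture(scope="session")
def study_run():
    """The full study-sized run: 76 samples (25 CTL / 22 IS / 29 LPS) in
    duplicate, default pipeline configuration.  Shared session-wide
    because preprocessing 152 spectra plus the repeated-CV grid is the
    expensive part of the suite."""
    cfg = pp.default_study_config(seed=STUDY_SEED)
    spectra, manifest, truth = pp.generate_dataset(cfg)
    pipeline_cfg = pp.PipelineConfig(seed=STUDY_SEED)
    result = pp.run_pipeline(spectra, manifest, pipeline_cfg)
    return {"sim_config": cfg, "manifest": manifest, "truth": truth,
            "result": result}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
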