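import pytest

import fbinet as fb


@pytest.fixture(scope="session")
def null_records_noiseless():
    """Default design, no planted effects, no replicate noise."""
    return fb.generate_dataset(fb.null_config(seed=0, noise_cv=0.0))


@pytest.fixture(scope="session")
def stress_result():
    """One full pipeline run on the planted stress-gradient scenario
    (MM all inductions, PDA all repressions, CV 10%, n=3)."""
    cfg = fb.PipelineConfig(generator=fb.stress_gradient_config(seed=7), seed=7)
    return fb.run_pipeline(cfg)


@pytest.fixture(scope="session")
def null_result():
    cfg = fb.PipelineConfig(generator=fb.null_config(seed=11), seed=11)
    return fb.run_pipeline(cfg)
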