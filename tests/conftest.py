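"""Shared fixtures: one small synthetic study reused across classifier tests."""

import numpy as np
import pytest

from affectlab import pipeline, synthetic


SMALL_FS = 128.0
SMALL_DURATION = 24.0


def small_study_config(n: int, stages=("museum",)) -> synthetic.StudyConfig:
    return synthetic.StudyConfig(
        n_subjects_per_phase=n, fs=SMALL_FS, stages=stages,
        n_iaps_blocks=6, iaps_block_duration=10.0,
        museum_duration=SMALL_DURATION)


def small_pipeline_config(n: int, **kw) -> pipeline.PipelineConfig:
    defaults = dict(n_subjects_per_phase=n, fs=SMALL_FS, stages=("museum",),
                    n_iaps_blocks=6, museum_duration=SMALL_DURATION,
                    ica_mode="none")
    defaults.update(kw)
    return pipeline.PipelineConfig(**defaults)


@pytest.fixture(scope="session")
def study_small():
    """Museum-only study, 6 subjects per phase, strong label effects."""
    return synthetic.generate_study(
        6, synthetic.EffectModel(), seed=7, config=small_study_config(6))


@pytest.fixture(scope="session")
def records_small(study_small):
    """206-feature stimulus records extracted from the small study."""
    return pipeline.extract_features(study_small, small_pipeline_config(6))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
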