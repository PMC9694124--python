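import pytest

from iidrperm import GeneratorConfig, figure3_preset, generate_cohort


@pytest.fixture(scope="session")
def preset_cohort():
    """One full 11-subject synthetic cohort from the bundled calibration."""
    return generate_cohort(figure3_preset(seed=7))


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 2-subject cohort (one per preference group), all 16 cells."""
    preset = figure3_preset()
    cfg = GeneratorConfig(
        n_per_group={"preCSPL65": 1, "preCSPL80": 1},
        accuracy=preset.accuracy,
        subject_sd=0.1,
        seed=42,
    )
    return generate_cohort(cfg)
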