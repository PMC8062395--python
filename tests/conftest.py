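import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A compact but complete synthetic study shared across tests."""
    from segrel.synthetic_data import GeneratorConfig, generate_study

    config = GeneratorConfig(n_speakers=3, trials_per_speaker=9, seed=11)
    return generate_study(config)


@pytest.fixture()
def tiny_annotations():
    """Three annotators on two tokens, both modalities on token A."""
    rows = [
        # token, trial, pos, label, speaker, rate, modality, annotator, boundary, ms
        ("A", "t1", 1, "snavel", "S1", "fast", "baseline", "a1", "onset", 100.0),
        ("A", "t1", 1, "snavel", "S1", "fast", "baseline", "a2", "onset", 102.0),
        ("A", "t1", 1, "snavel", "S1", "fast", "ponss", "a3", "onset", 104.0),
        ("B", "t1", 2, "vogel", "S1", "fast", "baseline", "a1", "onset", 500.0),
        ("B", "t1", 2, "vogel", "S1", "fast", "baseline", "a2", "onset", 504.0),
    ]
    from segrel.annotation_io import ANNOTATION_COLUMNS

    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


@pytest.fixture()
def mixture_sample():
    """3600 draws from the reference recovery mixture sigma=(1,4,20), theta=(.6,.3,.1)."""
    rng = np.random.default_rng(1000)
    comp = rng.choice(3, 3600, p=[0.6, 0.3, 0.1])
    return rng.normal(0.0, np.array([1.0, 4.0, 20.0])[comp])
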