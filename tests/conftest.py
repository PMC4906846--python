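import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A small synthetic study covering the interesting kit archetypes:

    a very low ligation yield, a PCR-free workflow, a kit whose adaptor
    channel cannot be assayed, and a fully efficient ligation.
    """
    from ddprep import StudyConfig, generate_study

    out = tmp_path_factory.mktemp("study")
    cfg = StudyConfig(
        kits=["NEBNext Ultra", "Truseq DNA PCR-free", "Accel-NGS 1S", "KAPA HyperPlus"],
        seed=7,
        n_read_pairs=300,
    )
    truth = generate_study(cfg, out)
    return out, truth
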