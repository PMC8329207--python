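import pytest

from ergspectra import StimulusProtocol, simulate_study
from ergspectra.simulate import default_truth


@pytest.fixture(scope="session")
def protocol():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def isolated_truth():
    """Two receptors with complete isolation at the reference adaptations.

    Zero noise; the dark state sees only the LW receptor and bright green
    only the UV receptor, so every downstream stage is exactly invertible.
    """
    return default_truth(
        noise_sd=0.0, n_per_sex=1, seed=7,
        ki={"UV": {"dark": 0.0, "dim_green": 0.7, "bright_green": 1.0},
            "LW": {"dark": 1.0, "dim_green": 0.35, "bright_green": 0.0}})


@pytest.fixture(scope="session")
def noisy_sessions(protocol):
    """One default-conditions study (10+10 individuals, three adaptations)."""
    return simulate_study(protocol, default_truth(seed=11))
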