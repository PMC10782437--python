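import numpy as np
import pytest

from boselect.scoring import EnergyProfile, FLT3_PANEL, PocketPanel, ScoreConfig


@pytest.fixture
def flt3_panel() -> PocketPanel:
    return FLT3_PANEL


@pytest.fixture
def score_config() -> ScoreConfig:
    return ScoreConfig()


@pytest.fixture
def synthetic_panel() -> PocketPanel:
    """A small abstract panel for landscape tests (one target, five off-targets)."""
    return PocketPanel("T", ("O1", "O2", "O3", "O4", "O5"))


def random_profile(rng: np.random.Generator, panel: PocketPanel) -> EnergyProfile:
    return EnergyProfile(
        {p: float(rng.uniform(-12.0, -3.0)) for p in panel.all_ids}
    )
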