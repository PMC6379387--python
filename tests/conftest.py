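import pytest

from misfit import MIR17, MiRNA
from misfit.simulate import GroundTruthModel, ScreenSimConfig, simulate_screen


@pytest.fixture(scope="session")
def mir17() -> MiRNA:
    return MIR17


@pytest.fixture(scope="session")
def toy_mirna() -> MiRNA:
    """A 5-nt miRNA small enough for brute-force enumeration oracles."""
    return MiRNA(name="toy", sequence="ACGUG", seed_range=(2, 4), supplementary_range=(5, 5))


@pytest.fixture(scope="session")
def model(mir17) -> GroundTruthModel:
    return GroundTruthModel.default(mir17)


@pytest.fixture(scope="session")
def small_screen(mir17, model):
    """A modest-depth simulated screen shared across read-only tests."""
    cfg = ScreenSimConfig(
        mirna=mir17,
        model=model,
        seed=20240917,
        depths={"pDNA": 300_000, "cDNA": 300_000, "monosome": 150_000, "heavy": 150_000},
    )
    return simulate_screen(cfg)
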