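import numpy as np
import pytest

from rbpmt.annotate import MicroRNA
from rbpmt.simulate import (
    EffectSizes,
    SimulationConfig,
    generate_transcriptome,
    implant_rbs,
)

LET7 = MicroRNA(id="let7", sequence="UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture(scope="session")
def let7() -> MicroRNA:
    return LET7


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-transcript simulated cohort with implanted sites and RBSs."""
    cfg = SimulationConfig(seed=11, n_transcripts=60)
    transcripts, truth = generate_transcriptome(cfg)
    rbs = implant_rbs(transcripts, truth, cfg)
    return cfg, transcripts, truth, rbs


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
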