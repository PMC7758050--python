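import numpy as np
import pytest

from degronscreen.motifs import MotifSpec, ProteinRecord


@pytest.fixture
def ken() -> MotifSpec:
    return MotifSpec("KEN", "KEN")


@pytest.fixture
def dbox() -> MotifSpec:
    return MotifSpec("Dbox", "RxxL")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def small_proteome() -> list[ProteinRecord]:
    return [
        ProteinRecord("P1", "GENEA", "AKENA"),
        ProteinRecord("P2", "GENEB", "RAALG"),
        ProteinRecord("P3", "GENEC", "MMMMM"),
    ]
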