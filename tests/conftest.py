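import numpy as np
import pytest

from bindmode import (
    DisorderProfile,
    ModelParams,
    ProteinSequence,
    default_params,
)


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """Packaged default model (fitted on synthetic regions)."""
    return default_params()


@pytest.fixture(scope="session")
def simple_params() -> ModelParams:
    """Hand-set coefficients for arithmetic-level checks."""
    return ModelParams(lambda1=2.0, lambda2=-1.0, lambda3=0.5, gamma=-0.3)


@pytest.fixture
def mixed_sequence() -> ProteinSequence:
    """A 100-mer mixing charged, polar and hydrophobic stretches."""
    rng = np.random.default_rng(7)
    residues = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
    return ProteinSequence(id="mixed", residues=residues)


@pytest.fixture
def flat_profile(mixed_sequence) -> DisorderProfile:
    return DisorderProfile(
        sequence_id=mixed_sequence.id,
        scores=np.full(mixed_sequence.n, 0.5),
    )
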