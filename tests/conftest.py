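import numpy as np
import pytest
from scipy.stats import special_ortho_group

from molvib import FieldSetup, NormalMode
from molvib.synthgen import SynthSpec, generate, make_witness_fixtures


def random_mode(rng: np.random.Generator, wavenumber: float = 1000.0) -> NormalMode:
    t = rng.normal(size=(3, 3))
    return NormalMode(
        index=0,
        wavenumber=wavenumber,
        dipole_derivative=rng.normal(size=3),
        polarizability_derivative=(t + t.T) / 2.0,
    )


def random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def random_rotations(n: int, seed: int) -> np.ndarray:
    r = special_ortho_group.rvs(3, size=n, random_state=np.random.default_rng(seed))
    return r.reshape(n, 3, 3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


@pytest.fixture
def fields() -> FieldSetup:
    return FieldSetup.from_axes("z", "z", "z")


@pytest.fixture
def witness_db():
    return make_witness_fixtures()


@pytest.fixture
def synth_db():
    return generate(SynthSpec(n_molecules=8, seed=11))
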