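import numpy as np
import pytest

from petkin import (
    BloodCurve,
    KineticParams,
    generate_blood,
    make_study_schedule,
)


@pytest.fixture(scope="session")
def schedule():
    """Full three-session study schedule (46 dynamic + 6-h + 48-h frames)."""
    return make_study_schedule()


@pytest.fixture(scope="session")
def blood():
    """Reference triexponential input (printed half-lives, (0.6, 0.3, 0.1) fractions)."""
    return generate_blood()


@pytest.fixture(scope="session")
def bone_marrow_params():
    return KineticParams(vb=0.15, K1=0.25, k2=0.2, k3=0.05, k4=0.001)


@pytest.fixture(scope="session")
def irreversible_params():
    """2T4P (k4 = 0) parameter set."""
    return KineticParams(vb=0.15, K1=0.25, k2=0.2, k3=0.05, k4=0.0)


def random_params(rng: np.random.Generator) -> KineticParams:
    """A random physiologic 2T5P parameter draw (log-uniform rates)."""
    return KineticParams(
        vb=float(rng.uniform(0.0, 0.6)),
        K1=float(np.exp(rng.uniform(np.log(0.01), np.log(2.0)))),
        k2=float(np.exp(rng.uniform(np.log(1e-3), np.log(1.0)))),
        k3=float(np.exp(rng.uniform(np.log(1e-3), np.log(1.0)))),
        k4=float(np.exp(rng.uniform(np.log(1e-4), np.log(0.1)))),
    )


def random_blood(rng: np.random.Generator) -> BloodCurve:
    """A random triexponential input with half-lives spanning the study ranges."""
    hl = np.array(
        [
            rng.uniform(2.6, 8.1),
            rng.uniform(29.3, 120.0),
            rng.uniform(13.4 * 60, 50.4 * 60),
        ]
    )
    f = rng.dirichlet([3.0, 2.0, 1.0])
    return generate_blood(hl, f, scale=float(rng.uniform(1.0, 10.0)))
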