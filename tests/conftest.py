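import hypothesis
import pytest

import glucopt as g
from glucopt.synth import random_admissible_subject  # noqa: F401  (shared by tests)

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def subjects() -> dict:
    return g.fixture_subjects()


@pytest.fixture(scope="session")
def subjA(subjects):
    return subjects["subjA"]


@pytest.fixture(scope="session")
def subjB(subjects):
    return subjects["subjB"]


@pytest.fixture(scope="session")
def subjC(subjects):
    return subjects["subjC"]


@pytest.fixture(scope="session")
def fine_solver():
    return g.SolverSettings(method="rk4", step=0.05, horizon=480.0)


@pytest.fixture(scope="session")
def clean_datasets(subjects):
    """Zero-noise six-condition datasets per fixture subject."""
    return {
        name: g.generate_dataset(
            g.SyntheticSubjectSpec(subject=s, noise_fraction=0.0, seed=0)
        )
        for name, s in subjects.items()
    }


@pytest.fixture(scope="session")
def noisy_dataset_factory(subjects):
    def make(name: str, noise: float, seed: int):
        return g.generate_dataset(
            g.SyntheticSubjectSpec(subject=subjects[name], noise_fraction=noise, seed=seed)
        )

    return make

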