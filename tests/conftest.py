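import numpy as np
import pytest

from icval.data import SubjectRecord, VisitRecord
from icval.event import WeibullPHParams
from icval.simulate import SimulationConfig, generate_dataset, resolve_design


def make_subject(id, times_statuses, C, x=(0.0,), delta_dropout=0):
    return SubjectRecord(
        id=str(id),
        x=np.asarray(x, dtype=float),
        visits=[VisitRecord(float(t), int(z)) for t, z in times_statuses],
        C=float(C),
        delta_dropout=delta_dropout,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def exp_model():
    """Unit-rate exponential event model (kappa = 1, lambda = 1, beta = 0)."""
    return WeibullPHParams(lam=1.0, kappa=1.0, beta=np.zeros(1))


@pytest.fixture(scope="session")
def default_design():
    """The main study design (normal covariates, corr 0, Poisson visits)."""
    return resolve_design(SimulationConfig())


@pytest.fixture(scope="session")
def small_dataset(default_design):
    """A modest generated training/validation pair shared across tests."""
    from dataclasses import replace

    cfg = replace(default_design.config, n_train=300, n_valid=300)
    return generate_dataset(resolve_design(cfg), seed=424242)
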