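"""Shared fixtures: seeded assembly ensembles reused across the suite.

The heavy ensembles are session-scoped so that the acceptance checks and the
invariant tests share one set of runs. Seeds are fixed literals spawned from
a base generator, so the whole suite is reproducible.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ktwsim as kw

settings.register_profile(
    "suite", settings(max_examples=25, deadline=None, derandomize=True,
                      suppress_health_check=[HealthCheck.too_slow]))
settings.load_profile("suite")

SEED_BASE = 20220808


def make_seeds(n, salt):
    rng = np.random.default_rng(SEED_BASE + salt)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


@pytest.fixture(scope="session")
def ens_R_p0():
    """Model R, p=0 (diagonal kill-the-winner limit), 20 seeds x 2500 steps."""
    return kw.run_ensemble("R", 0.0, 2500, make_seeds(20, 1))


@pytest.fixture(scope="session")
def ens_R_p005():
    """Model R, p=0.05 (eliminate-the-winner regime), 20 seeds x 2500 steps."""
    return kw.run_ensemble("R", 0.05, 2500, make_seeds(20, 2))


@pytest.fixture(scope="session")
def ens_R_p01():
    """Model R, p=0.1, 10 seeds x 2000 steps (pairing statistics)."""
    return kw.run_ensemble("R", 0.1, 2000, make_seeds(10, 3))


@pytest.fixture(scope="session")
def ens_R_p1():
    """Model R, p=1 (fully connected wiring), 10 seeds x 2000 steps."""
    return kw.run_ensemble("R", 1.0, 2000, make_seeds(10, 4))


@pytest.fixture(scope="session")
def ens_N_p02():
    """Model N, p=0.2, 10 seeds x 2000 steps (trigger-rule statistics)."""
    return kw.run_ensemble("N", 0.2, 2000, make_seeds(10, 5))


@pytest.fixture(scope="session")
def sweep_R():
    """Model R over p in {0, 0.05, 0.2, 0.5}, 8 seeds x 600 steps each."""
    return {p: kw.run_ensemble("R", p, 600, make_seeds(8, 10 + i))
            for i, p in enumerate((0.0, 0.05, 0.2, 0.5))}


@pytest.fixture(scope="session")
def ens_N_p0():
    """Model N at p=0, 8 seeds x 600 steps (coincidence with Model R)."""
    return kw.run_ensemble("N", 0.0, 600, make_seeds(8, 20))
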