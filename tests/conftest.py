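import dataclasses

import numpy as np
import pytest

from coda24 import close, clr_from_pivot_beta1
from coda24.simulate import paper_like_config, simulate_cohort


@pytest.fixture(scope="session")
def table1_means():
    """Published all-schools compositional mean (sleep, st, lpa, mvpa)."""
    return close([543.2, 635.8, 210.1, 50.9])


@pytest.fixture(scope="session")
def overall_clr():
    """Published all-schools overall-score first-pivot coefficients, clr scale."""
    return clr_from_pivot_beta1([-2.45, -0.60, -1.76, 4.81])


@pytest.fixture(scope="session")
def paper_cohort():
    """One paper-like synthetic cohort: n=360, 12 schools."""
    return simulate_cohort(paper_like_config(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for fast model fits: n=80, 4 schools."""
    cfg = dataclasses.replace(
        paper_like_config(seed=3), n_participants=80, n_schools=4, n_primary_schools=3
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Tiny 2-school cohort for brute-force likelihood comparisons."""
    cfg = dataclasses.replace(
        paper_like_config(seed=9), n_participants=36, n_schools=2, n_primary_schools=1
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
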