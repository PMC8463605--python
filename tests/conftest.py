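"""Shared fixtures: small analytic graphs and session-scoped cohort results.

The expensive cohort-level computations (surrogate validation, the
19-subject strategy comparison) are computed once per session and shared
by the acceptance-level tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import virtres
from virtres.connectome import ConnectomeMatrix


def star_graph(n_leaves: int = 4) -> ConnectomeMatrix:
    """K_{1,n}: node 0 is the center."""
    a = np.zeros((n_leaves + 1, n_leaves + 1))
    a[0, 1:] = 1.0
    a[1:, 0] = 1.0
    return ConnectomeMatrix(a, is_binary=True)


def path_graph(n: int = 3) -> ConnectomeMatrix:
    a = np.zeros((n, n))
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1.0
    return ConnectomeMatrix(a, is_binary=True)


def complete_graph(n: int) -> ConnectomeMatrix:
    a = np.ones((n, n)) - np.eye(n)
    return ConnectomeMatrix(a, is_binary=True)


def triangle() -> ConnectomeMatrix:
    return complete_graph(3)


@pytest.fixture(scope="session")
def star():
    return star_graph(4)


@pytest.fixture(scope="session")
def path3():
    return path_graph(3)


@pytest.fixture(scope="session")
def default_subject():
    """One default-condition synthetic subject (92 nodes, 11% density)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return virtres.generate_cohort(virtres.CohortSpec(n_subjects=1, master_seed=1))[0]


@pytest.fixture(scope="session")
def calibrated_subject3():
    """Default synthetic connectome with a size-3 EZ plus its calibrated beta."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        subj = virtres.generate_cohort(
            virtres.CohortSpec(n_subjects=1, master_seed=1, ez_size_range=(3, 3))
        )[0]
    cal = virtres.calibrate_beta(
        subj.connectome, subj.ez, n_runs=1000, rng=np.random.default_rng(11)
    )
    return subj, cal


@pytest.fixture(scope="session")
def surrogate_validation():
    """EC vs single-seed I(t=10) over a 5-subject default cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = virtres.generate_cohort(
            virtres.CohortSpec(n_subjects=5, master_seed=0)
        )
    return virtres.validate_surrogate(
        cohort, np.random.default_rng(0), n_runs=1000
    )


@pytest.fixture(scope="session")
def cohort19_comparison():
    """Surrogate-only strategy comparison on a 19-subject default cohort.

    Propagation (SIR) evaluation is skipped here to keep the suite fast;
    the ranking claims under test are about the EC surrogate.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = virtres.generate_cohort(
            virtres.CohortSpec(n_subjects=19, master_seed=0)
        )
    comparison = virtres.compare_strategies(
        cohort,
        np.random.default_rng(0),
        sa_params=virtres.SAParams(restarts=3),
        propagation_runs=None,
    )
    return cohort, comparison
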