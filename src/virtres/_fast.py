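"""Numba kernels for the simulated-annealing objective.

The annealer evaluates the seed's mean eigenvector centrality on thousands
of slightly different edge-deleted graphs.  Each evaluation is a sparse
power iteration warm-started from the vector of the annealer's current
state, which converges in a few dozen matvecs on these small, well-gapped
networks.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def csr_power_iteration(indptr, indices, data, x0, tol, max_iter):
    """Leading-eigenvector power iteration on a CSR matrix.

    Iterates on the shifted operator A + I, which has the same
    eigenvectors but strictly dominant top eigenvalue even on bipartite
    components (where plain power iteration oscillates between the +/-
    lambda_max eigenspaces).  ``x0`` must be non-negative with positive
    norm; since A + I is non-negative, iterates stay non-negative and
    converge to the Perron vector of the dominant component(s).  Returns
    the unit vector (all zeros if the matrix has no edges).
    """
    n = x0.shape[0]
    x = x0 / np.sqrt(np.sum(x0 * x0))
    y = np.empty(n)
    for _ in range(max_iter):
        for i in range(n):
            s = x[i]  # the +I shift
            for p in range(indptr[i], indptr[i + 1]):
                s += data[p] * x[indices[p]]
            y[i] = s
        ny = np.sqrt(np.sum(y * y))
        if ny < 1e-300:
            return np.zeros(n)
        diff = 0.0
        for i in range(n):
            y[i] /= ny
            d = abs(y[i] - x[i])
            if d > diff:
                diff = d
        x, y = y, x
        if diff < tol:
            break
    return x.copy()
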