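"""Independent textbook MCL used as an oracle in tests.

Deliberately written as a separate, minimal dense-matrix implementation:
no pruning, and cluster read-out via connected components of the converged
matrix's non-zero pattern (scipy.sparse.csgraph), rather than the
package's attractor-system interpretation. Kept independent of
drgpop.mcl so the two can disagree.
"""

import numpy as np
from scipy.sparse.csgraph import connected_components


def reference_mcl(
    adjacency: np.ndarray,
    inflation: float = 1.8,
    preinflation: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> list[frozenset]:
    """Cluster a 0/1 adjacency matrix; returns node-index partitions."""
    a = adjacency.astype(float).copy()
    np.fill_diagonal(a, 1.0)
    m = a / a.sum(axis=0)
    if preinflation is not None:
        m = np.power(m, preinflation)
        m = m / m.sum(axis=0)
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = np.power(m, inflation)
        m = m / m.sum(axis=0)
        if np.abs(m - prev).max() < tol:
            break
    support = m > 1e-8
    n_comp, labels = connected_components(
        (support | support.T).astype(np.int8), directed=False
    )
    return [frozenset(np.flatnonzero(labels == k).tolist()) for k in range(n_comp)]
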