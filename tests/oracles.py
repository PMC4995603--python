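"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where feasible, the
libraries) used by the package itself: flood fill by explicit BFS,
eigendecomposition via a different routine, the GP mean via the primal
ridge identity, and rank-sum p-values via scipy's exact Mann-Whitney U.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np

OFFSETS = {
    6: [o for o in product((-1, 0, 1), repeat=3) if sum(map(abs, o)) == 1],
    18: [o for o in product((-1, 0, 1), repeat=3)
         if 1 <= sum(map(abs, o)) <= 2],
    26: [o for o in product((-1, 0, 1), repeat=3) if any(o)],
}


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[set]:
    """Connected components of a boolean grid by breadth-first search."""
    offsets = OFFSETS[connectivity]
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    shape = binary.shape
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.add(v)
            for o in offsets:
                w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= w[i] < shape[i] for i in range(3)):
                    if binary[w] and not seen[w]:
                        seen[w] = True
                        q.append(w)
        comps.append(comp)
    return comps


def brute_segment(prob: np.ndarray, threshold: float, min_cluster: int,
                  connectivity: int) -> np.ndarray:
    binary = prob > threshold
    out = np.zeros_like(binary)
    for comp in flood_fill_components(binary, connectivity):
        if len(comp) >= min_cluster:
            for v in comp:
                out[v] = True
    return out


def fpc_oracle(Y: np.ndarray):
    """Leading principal component via SVD of the centred table."""
    means = Y.mean(axis=0)
    centred = Y - means
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    lead = vt[0]
    if lead.sum() < 0:
        lead = -lead
    return centred @ lead, lead


def primal_ridge_mean(X_train, y, X_test, noise_var, scale=1.0):
    """GP mean with linear kernel == regularized primal linear regression:
    f* = X* (X^T X + (sigma^2/s) I)^{-1} X^T y  (with kernel s * X X^T)."""
    d = X_train.shape[1]
    A = X_train.T @ X_train + (noise_var / scale) * np.eye(d)
    return X_test @ np.linalg.solve(A, X_train.T @ y)
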