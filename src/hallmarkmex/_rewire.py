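"""Degree-preserving rewiring of binary matrices (checkerboard-swap chain).

The permutation null for the exclusivity score keeps every row and
column sum of the binary alteration matrix fixed while randomising
which samples carry which events. Each step proposes two 1-entries
(r1, c1), (r2, c2) chosen uniformly at random and, when (r1, c2) and
(r2, c1) are both 0 and rows/columns differ, replaces the pair with
its checkerboard swap. The proposal is symmetric, the state space of
matrices with fixed margins is connected under such swaps, and the
number of 1s is invariant, so the chain's stationary distribution is
uniform over that space.

The inner loop is optionally JIT-compiled with numba when available;
both paths execute the same algorithm on the same pre-generated
proposal stream and produce identical matrices.
"""

from __future__ import annotations

import numpy as np


def _swap_kernel_py(rows, cols, occupied, proposals):
    n_swapped = 0
    for t in range(proposals.shape[0]):
        i = proposals[t, 0]
        j = proposals[t, 1]
        r1 = rows[i]
        c1 = cols[i]
        r2 = rows[j]
        c2 = cols[j]
        if r1 == r2 or c1 == c2:
            continue
        if occupied[r1, c2] or occupied[r2, c1]:
            continue
        occupied[r1, c1] = 0
        occupied[r2, c2] = 0
        occupied[r1, c2] = 1
        occupied[r2, c1] = 1
        cols[i] = c2
        cols[j] = c1
        n_swapped += 1
    return n_swapped


try:  # optional acceleration; the pure-python kernel is the reference
    from numba import njit

    _swap_kernel = njit(cache=False)(_swap_kernel_py)
except Exception:  # pragma: no cover - exercised only without numba
    _swap_kernel = _swap_kernel_py


def rewire_binary_matrix(
    matrix: np.ndarray,
    rng: np.random.Generator,
    *,
    swap_factor: int = 10,
    use_python_kernel: bool = False,
) -> np.ndarray:
    """Return a margin-preserving randomisation of a 0/1 matrix.

    ``swap_factor`` scales the number of attempted swaps as a multiple
    of the number of 1-entries (burn-in contract: >= 10x). If no valid
    swap exists (degenerate margins) the input is returned unchanged.
    """
    mat = np.ascontiguousarray(matrix, dtype=np.int8)
    rows_idx, cols_idx = np.nonzero(mat)
    n_ones = rows_idx.size
    if n_ones < 2:
        return mat.copy()
    attempts = max(1, swap_factor * n_ones)
    proposals = rng.integers(0, n_ones, size=(attempts, 2), dtype=np.int64)
    occupied = mat.copy()
    rows = rows_idx.astype(np.int64)
    cols = cols_idx.astype(np.int64)
    kernel = _swap_kernel_py if use_python_kernel else _swap_kernel
    kernel(rows, cols, occupied, proposals)
    return occupied
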