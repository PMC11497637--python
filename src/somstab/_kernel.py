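"""JIT-compiled online SOM update loop.

Kept separate so the heavy numba import/compile cost is paid only when
training actually happens.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True, fastmath=False)
def online_update(codebook, data, griddist, niter, alpha_start, alpha_end, radius0):
    """Run ``niter`` online updates in place on ``codebook``.

    Step ``t`` presents cell ``t mod n`` (cyclic order), finds the
    best-matching node by squared Euclidean distance (ties -> lowest
    index), and moves every node within the current bubble radius on the
    grid toward the cell by the current learning rate.  Both the
    learning rate and the radius decay linearly over ``niter`` steps.
    """
    n, m = data.shape
    k = codebook.shape[0]
    inv = 1.0 / niter if niter > 0 else 0.0
    for t in range(niter):
        i = t % n
        best = 0
        best_d = np.inf
        for j in range(k):
            d = 0.0
            for c in range(m):
                diff = data[i, c] - codebook[j, c]
                d += diff * diff
            if d < best_d:
                best_d = d
                best = j
        frac = t * inv
        alpha = alpha_start - (alpha_start - alpha_end) * frac
        radius = radius0 * (1.0 - frac)
        for j in range(k):
            if griddist[best, j] <= radius:
                for c in range(m):
                    codebook[j, c] += alpha * (data[i, c] - codebook[j, c])
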