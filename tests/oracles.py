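"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def grid_decompose(F, f, step=0.001):
    """Grid-search oracle for min ‖f − Fα‖ over α ∈ [0,1]^n, n ≤ 3.

    Exhaustive at the requested step for n ≤ 2.  For n = 3 the objective
    (convex, so the global minimum is the only local one) is located by
    successive grid refinement down to the requested step.
    """
    n = F.shape[1]
    if n == 1:
        a = np.arange(0, 1 + step / 2, step)[:, None]
    elif n == 2:
        g = np.arange(0, 1 + step / 2, step)
        a = np.stack(np.meshgrid(g, g, indexing="ij"), axis=-1).reshape(-1, 2)
    else:
        lo, hi, s = np.zeros(3), np.ones(3), 0.05
        while True:
            axes = [np.arange(lo[k], hi[k] + s / 2, s) for k in range(3)]
            a = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
            err = ((a @ F.T - f) ** 2).sum(axis=1)
            best = a[int(np.argmin(err))]
            if s <= step:
                return best
            lo = np.clip(best - 2 * s, 0, 1)
            hi = np.clip(best + 2 * s, 0, 1)
            s = max(s / 5, step)
    err = ((a @ F.T - f) ** 2).sum(axis=1)
    return a[int(np.argmin(err))]
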