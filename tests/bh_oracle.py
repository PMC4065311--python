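"""Hand-rolled Benjamini-Hochberg step-up oracle, independent of statsmodels."""

import numpy as np


def bh_step_up(pvalues: np.ndarray) -> np.ndarray:
    """Adjusted q-values by the literal step-up recipe.

    Sort the m p-values ascending, scale the i-th (1-based) by m/i, then
    enforce monotonicity from the largest rank down; q_i = min over j >= i
    of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    running = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(running, 1.0)
    return q
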