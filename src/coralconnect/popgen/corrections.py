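"""Sequential Bonferroni (Holm) multiple-testing correction."""
from __future__ import annotations

import numpy as np


def sequential_bonferroni(pvals, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down significance flags, in the input order.

    Sort p ascending; p_(i) is significant when every p_(j<=i) satisfies
    p_(j) < alpha / (m - j + 1); the procedure stops at the first failure.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D list of p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] < alpha / (m - rank):
            flags[idx] = True
        else:
            break
    return flags
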