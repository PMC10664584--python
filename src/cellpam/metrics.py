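"""Partition agreement via the Adjusted Rand Index.

ARI = (Index − Expected) / (Max − Expected), with Index = Σᵢⱼ C(nᵢⱼ, 2)
over the contingency table of the two partitions, Expected =
Σᵢ C(aᵢ,2) Σⱼ C(bⱼ,2) / C(n,2) and Max = ½[Σᵢ C(aᵢ,2) + Σⱼ C(bⱼ,2)].
It is 1 for identical partitions (up to relabelling), has expectation 0 for
independent random partitions, and is symmetric in its arguments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["adjusted_rand_index"]


def adjusted_rand_index(p, q) -> float:
    """Chance-corrected pair-counting agreement between two labellings.

    Labels may be arbitrary hashables; the partitions need not have the same
    number of clusters.  The degenerate case where both partitions are a
    single cluster (0/0) returns 1.0, as the partitions are identical.
    """
    p = np.asarray(p)
    q = np.asarray(q)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError(f"label vectors must be 1-D of equal length, got "
                         f"{p.shape} and {q.shape}")
    n = len(p)
    if n < 2:
        raise ValueError("need at least 2 items")
    ci = pd.factorize(p)[0]
    cj = pd.factorize(q)[0]
    table = np.zeros((ci.max() + 1, cj.max() + 1), dtype=np.int64)
    np.add.at(table, (ci, cj), 1)

    def comb2(x):
        return x * (x - 1) // 2

    index = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:
        return 1.0
    return float((index - expected) / (maximum - expected))
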