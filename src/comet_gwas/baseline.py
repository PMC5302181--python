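"""Hypergeometric (DAVID-style) enrichment test on overlap variants.

The single-trait enrichment test popularised by gene-set tools: condition
on the n variants found associated (here: associated with both traits)
and ask whether the k of them falling inside a category of K variants,
out of N total, is surprising under random sampling without replacement —
the upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

This conditions on the number of associated variants and treats category
membership as the random quantity — the reverse of the overlap model's
conditioning — and it ignores the marginal association structure of the
two traits.  It is provided as the comparator whose behaviour on shared
variants the corrected overlap test is designed to improve upon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .assoc import InvalidInputError


@dataclass(frozen=True)
class EnrichmentTable:
    """Counts for one category's hypergeometric test.

    N: total variants; K: variants in the category; n: overlap-associated
    variants; k: overlap-associated variants in the category.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        ok = (0 <= self.K <= self.N and 0 <= self.n <= self.N
              and 0 <= self.k <= min(self.K, self.n)
              and self.k >= max(0, self.n + self.K - self.N))
        if not ok:
            raise InvalidInputError(
                f"inconsistent enrichment counts N={self.N} K={self.K} "
                f"n={self.n} k={self.k}"
            )


def hypergeom_enrichment_p(t: EnrichmentTable) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(t.k - 1, t.N, t.K, t.n))


def overlap_hypergeom_tests(y_overlap, X: pd.DataFrame) -> pd.DataFrame:
    """Apply the hypergeometric test to every category of a design matrix.

    ``y_overlap``: 0/1 overlap verdicts aligned with the rows of the
    binary annotation matrix ``X``.  Returns one row per category with the
    counts and the upper-tail p-value, flagged ``method="hypergeometric"``.
    """
    y = np.asarray(y_overlap, dtype=int)
    if y.shape[0] != len(X):
        raise InvalidInputError("response and design matrix differ in length")
    N = int(len(X))
    n = int(y.sum())
    rows = []
    for c in X.columns:
        x = X[c].to_numpy(dtype=int)
        K = int(x.sum())
        k = int(((x == 1) & (y == 1)).sum())
        p = hypergeom_enrichment_p(EnrichmentTable(N=N, K=K, n=n, k=k))
        rows.append({"method": "hypergeometric", "covariate": c,
                     "N": N, "K": K, "n": n, "k": k, "p": p})
    return pd.DataFrame(rows)
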