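"""LD clumping with a joint (multi-trait) association metric.

The regression models downstream assume approximately independent
variants, so the variant panel is reduced by greedy clumping: variants are
ranked by a joint association score and, walking down the ranking, each
retained variant knocks out every remaining variant in LD with it
(r^2 above a threshold, default 0.1).  Variants with MAF at or below a
floor (default 5%) are removed before clumping.

The joint score favours variants with evidence in *every* trait over
variants with strong evidence in one trait only: the primary score is the
minimum log10(ABF) across traits and ties are broken by the sum across
traits (both pluggable).  Absent pairs in the LD table are treated as
r^2 = 0, the practical convention for sparse pairwise tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .assoc import InvalidInputError

logger = logging.getLogger(__name__)

#: built-in joint association metrics: primary score, tie-break score
METRICS: dict[str, Callable[[np.ndarray], float]] = {
    "min": lambda v: float(np.min(v)),
    "max": lambda v: float(np.max(v)),
    "sum": lambda v: float(np.sum(v)),
}


@dataclass(frozen=True)
class LDPair:
    snp_a: str
    snp_b: str
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise InvalidInputError(f"r2 must lie in [0, 1], got {self.r2}")


@dataclass(frozen=True)
class JointScore:
    snp_id: str
    per_trait_log10_abf: tuple
    score: float
    tiebreak: float = 0.0


@dataclass
class ClumpResult:
    """Retained variant ids plus per-filter accounting."""

    retained: list[str]
    n_input: int
    n_maf_removed: int
    n_ld_removed: int
    maf_removed: list[str] = field(default_factory=list)


def joint_metric(per_trait_log10_abf, method: str | Callable = "min") -> float:
    """Joint association score of one variant across traits.

    Default is the minimum log10(ABF) across traits, so a variant with
    moderate evidence in both traits outranks one with strong evidence in
    a single trait; ties are broken downstream by the sum across traits.
    """
    v = np.asarray(per_trait_log10_abf, dtype=float)
    if v.size == 0:
        raise InvalidInputError("per-trait score vector is empty")
    if np.any(~np.isfinite(v)):
        raise InvalidInputError("per-trait scores must be finite")
    fn = METRICS[method] if isinstance(method, str) else method
    return fn(v)


def joint_scores(abf_wide: pd.DataFrame, method: str | Callable = "min") -> pd.DataFrame:
    """Score every variant of a variants x traits log10(ABF) matrix.

    Returns a DataFrame indexed by variant id with columns ``score``
    (primary) and ``tiebreak`` (sum across traits).
    """
    vals = abf_wide.to_numpy(dtype=float)
    if vals.shape[1] < 1:
        raise InvalidInputError("need at least one trait column")
    if np.any(~np.isfinite(vals)):
        raise InvalidInputError("log10(ABF) values must be finite")
    fn = METRICS[method] if isinstance(method, str) else method
    score = np.apply_along_axis(fn, 1, vals)
    return pd.DataFrame(
        {"score": score, "tiebreak": vals.sum(axis=1)}, index=abf_wide.index
    )


def _ld_adjacency(ld: pd.DataFrame, r2_max: float, keep: set[str]) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    if len(ld) == 0:
        return adj
    r2 = ld["r2"].to_numpy(dtype=float)
    if np.any((r2 < 0) | (r2 > 1)) or np.any(~np.isfinite(r2)):
        raise InvalidInputError("r2 values must lie in [0, 1]")
    for a, b, r in zip(ld["snp_a"], ld["snp_b"], r2):
        if r > r2_max and a in keep and b in keep and a != b:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    return adj


def greedy_clump(
    scores: pd.DataFrame,
    ld: pd.DataFrame | None,
    maf: Mapping[str, float] | pd.Series,
    r2_max: float = 0.1,
    maf_min: float = 0.05,
) -> ClumpResult:
    """Greedy selection of an approximately independent variant set.

    ``scores``: DataFrame indexed by variant id with a ``score`` column and
    optional ``tiebreak`` column (as from :func:`joint_scores`).
    ``ld``: 3-column table (snp_a, snp_b, r2); pairs absent from the table
    are treated as independent.  ``maf``: per-variant minor allele
    frequency; variants with MAF <= ``maf_min`` are removed first.

    The greedy pass repeatedly retains the highest-ranked remaining
    variant (score desc, tiebreak desc, id asc — a total order, so the
    output is independent of input ordering) and discards all variants
    with r^2 > ``r2_max`` against it.
    """
    if not (0.0 <= r2_max <= 1.0):
        raise InvalidInputError("r2_max must lie in [0, 1]")
    maf = pd.Series(maf)
    missing = scores.index.difference(maf.index)
    if len(missing):
        raise InvalidInputError(f"{len(missing)} scored variants lack a MAF value")

    ids = scores.index.to_numpy()
    pass_maf = maf.loc[scores.index].to_numpy(dtype=float) > maf_min
    maf_removed = [str(s) for s in ids[~pass_maf]]
    keep = set(map(str, ids[pass_maf]))
    logger.info("MAF filter (> %g): removed %d of %d variants",
                maf_min, len(maf_removed), len(ids))

    tiebreak = (scores["tiebreak"] if "tiebreak" in scores
                else pd.Series(0.0, index=scores.index))
    order = sorted(
        keep,
        key=lambda s: (-float(scores.at[s, "score"]), -float(tiebreak.at[s]), str(s)),
    )
    adj = _ld_adjacency(
        ld if ld is not None else pd.DataFrame(columns=["snp_a", "snp_b", "r2"]),
        r2_max, keep,
    )

    retained: list[str] = []
    discarded: set[str] = set()
    for s in order:
        if s in discarded:
            continue
        retained.append(s)
        discarded |= adj.get(s, set())
    n_ld = len(keep) - len(retained)
    logger.info("clumping (r2 > %g): removed %d variants, retained %d",
                r2_max, n_ld, len(retained))
    return ClumpResult(
        retained=retained,
        n_input=len(ids),
        n_maf_removed=len(maf_removed),
        n_ld_removed=n_ld,
        maf_removed=maf_removed,
    )
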