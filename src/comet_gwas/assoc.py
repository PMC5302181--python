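"""Approximate Bayes factors and binary per-trait association verdicts.

A GWAS summary statistic — effect estimate ``beta`` with standard error
``se`` — is converted into an approximate Bayes factor (ABF) in favour of
association, assuming a zero-centred normal prior on the true effect size:

    ABF = sqrt(V / (V + W)) * exp(z^2 * W / (2 * (V + W)))

with ``V = se**2`` (the sampling variance), ``W = prior_sd**2`` (the prior
variance) and ``z = beta / se``.  Larger ABF means more evidence for
association; the ABF depends on ``beta`` only through ``z**2`` and is
therefore symmetric in the sign of the effect.

A binary association verdict per (variant, trait) pair is obtained by
comparing ``log10(ABF)`` against a Bayesian decision threshold

    log10( pi0 / ((1 - pi0) * R) )

where ``pi0`` is the prior probability that a variant is null and ``R`` the
cost ratio of a false positive to a false negative.  The default settings
``R = 20``, ``pi0 = 0.99`` give a threshold of 0.695 (3 d.p.), roughly
equivalent to a per-variant p-value threshold of 0.004-0.01 depending on
study size.  The comparison is strict: a variant is called associated only
when ``log10(ABF) > threshold``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)


class InvalidInputError(ValueError):
    """Raised when an operation receives out-of-domain inputs."""


@dataclass(frozen=True)
class SummaryStat:
    """One variant's association summary for one trait.

    ``beta`` is a log odds ratio for case-control traits or a standardised
    regression coefficient for quantitative traits; ``se`` its standard
    error; ``n_eff`` an optional effective sample size.
    """

    snp_id: str
    trait_id: str
    beta: float
    se: float
    n_eff: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta):
            raise InvalidInputError(f"beta must be finite (snp={self.snp_id})")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise InvalidInputError(f"se must be positive (snp={self.snp_id})")
        if self.n_eff is not None and not (self.n_eff > 0):
            raise InvalidInputError(f"n_eff must be positive (snp={self.snp_id})")


def decision_threshold(R: float, pi0: float) -> float:
    """log10(ABF) decision bound implied by cost ratio ``R`` and prior ``pi0``.

    A variant is worth declaring associated when the posterior odds of
    association exceed the cost ratio, which happens iff
    ``log10(ABF) > log10(pi0 / ((1 - pi0) * R))``.
    """
    if not (R > 0):
        raise InvalidInputError("cost ratio R must be positive")
    if not (0.0 < pi0 < 1.0):
        raise InvalidInputError("pi0 must lie strictly between 0 and 1")
    return math.log10(pi0 / ((1.0 - pi0) * R))


@dataclass(frozen=True)
class BFDecisionRule:
    """Bayesian classification rule for association verdicts.

    ``log10_threshold`` is derived from ``R`` and ``pi0`` when not given;
    if given explicitly it must agree with the derived value to 1e-12.
    ``prior_sd`` is the SD of the normal effect-size prior used in the ABF,
    on the log-OR / standardised-beta scale.
    """

    R: float = 20.0
    pi0: float = 0.99
    prior_sd: float = 0.2
    log10_threshold: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        derived = decision_threshold(self.R, self.pi0)
        if self.log10_threshold is None:
            object.__setattr__(self, "log10_threshold", derived)
        elif abs(self.log10_threshold - derived) > 1e-12:
            raise InvalidInputError(
                "log10_threshold inconsistent with R and pi0: "
                f"{self.log10_threshold} vs derived {derived}"
            )
        if self.prior_sd < 0:
            raise InvalidInputError("prior_sd must be non-negative")


@dataclass(frozen=True)
class AssociationCall:
    """Binary association verdict for one (variant, trait) pair."""

    snp_id: str
    trait_id: str
    log10_abf: float
    y: int


def log10_abf(beta, se, prior_sd: float):
    """log10 approximate Bayes factor in favour of association.

    Vectorised over ``beta`` and ``se``.  ``prior_sd == 0`` is the
    degenerate limit with no prior mass on the alternative and returns
    exactly 0 (ABF = 1).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(~np.isfinite(beta)):
        raise InvalidInputError("beta must be finite")
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise InvalidInputError("se must be positive and finite")
    if prior_sd < 0:
        raise InvalidInputError("prior_sd must be non-negative")
    if prior_sd == 0:
        out = np.zeros_like(beta)
        return float(out) if out.ndim == 0 else out
    V = se**2
    W = float(prior_sd) ** 2
    z2 = (beta / se) ** 2
    out = 0.5 * np.log10(V / (V + W)) + z2 * W / (2.0 * (V + W)) / LN10
    return float(out) if out.ndim == 0 else out


def association_call(stat: SummaryStat, rule: BFDecisionRule) -> AssociationCall:
    """Classify a single summary statistic under ``rule``."""
    lab = log10_abf(stat.beta, stat.se, rule.prior_sd)
    return AssociationCall(stat.snp_id, stat.trait_id, lab, int(lab > rule.log10_threshold))


def classify(
    trait_stats: Mapping[str, pd.DataFrame] | Iterable[SummaryStat],
    rule: BFDecisionRule,
) -> pd.DataFrame:
    """Per-(variant, trait) association calls on the common variant set.

    ``trait_stats`` maps trait id to a DataFrame with columns
    ``snp, beta, se`` (the layout produced by :mod:`comet_gwas.io` and by
    the simulator).  Only variants present for *every* trait are classified;
    variants missing from any trait are excluded with a logged count.

    Returns a long-format DataFrame with columns
    ``snp, trait, log10_abf, y``, ordered by trait then variant id.
    """
    if not isinstance(trait_stats, Mapping):
        records = list(trait_stats)
        frames: dict[str, pd.DataFrame] = {}
        for trait in sorted({r.trait_id for r in records}):
            sub = [r for r in records if r.trait_id == trait]
            frames[trait] = pd.DataFrame(
                {"snp": [r.snp_id for r in sub],
                 "beta": [r.beta for r in sub],
                 "se": [r.se for r in sub]}
            )
        trait_stats = frames
    if len(trait_stats) < 1:
        raise InvalidInputError("no traits supplied")

    indexes = {}
    for trait, df in trait_stats.items():
        ids = pd.Index(df["snp"])
        if ids.has_duplicates:
            raise InvalidInputError(f"duplicate snp ids in trait {trait!r}")
        indexes[trait] = ids
    traits = sorted(trait_stats)
    first = indexes[traits[0]]
    identical = all(indexes[t].equals(first) for t in traits[1:])
    if identical:
        common = first  # shared ordering: no intersection or realignment needed
    else:
        common = first
        for t in traits[1:]:
            common = common.intersection(indexes[t])
        common = common.sort_values()

    out = []
    for trait in traits:
        df = trait_stats[trait]
        n_missing = len(indexes[trait]) - len(common)
        if n_missing:
            logger.info(
                "trait %s: %d variants absent from the common set were excluded",
                trait, n_missing,
            )
        if identical:
            beta = df["beta"].to_numpy()
            se = df["se"].to_numpy()
        else:
            sub = df.set_index("snp").loc[common]
            beta = sub["beta"].to_numpy()
            se = sub["se"].to_numpy()
        lab = log10_abf(beta, se, rule.prior_sd)
        out.append(pd.DataFrame({
            "snp": common, "trait": trait,
            "log10_abf": lab, "y": (lab > rule.log10_threshold).astype(int),
        }))
    return pd.concat(out, ignore_index=True)


def _pivot_calls(calls: pd.DataFrame, value: str) -> pd.DataFrame:
    traits = sorted(calls["trait"].unique())
    blocks = {t: calls[calls["trait"] == t] for t in traits}
    first = blocks[traits[0]]["snp"].to_numpy()
    aligned = (np.all(first[:-1] <= first[1:])
               and all(np.array_equal(b["snp"].to_numpy(), first)
                       for b in blocks.values()))
    if aligned:  # blocks share one sorted ordering: plain column assembly
        return pd.DataFrame({t: blocks[t][value].to_numpy() for t in traits},
                            index=pd.Index(first, name="snp"))
    return calls.pivot(index="snp", columns="trait", values=value).sort_index()


def call_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format calls to a variants x traits 0/1 verdict matrix."""
    return _pivot_calls(calls, "y")


def abf_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format calls to a variants x traits log10(ABF) matrix."""
    return _pivot_calls(calls, "log10_abf")


def pvalue_call_rule(alpha: float = 0.005):
    """Alternative p-value-based verdict rule (off by default).

    Returns a callable mapping (beta, se) arrays to 0/1 verdicts using a
    two-sided Wald p-value threshold, for users who prefer classical
    significance to the Bayes-factor rule.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError("alpha must lie strictly between 0 and 1")

    def rule(beta, se):
        z = np.asarray(beta, float) / np.asarray(se, float)
        return (2.0 * norm.sf(np.abs(z)) < alpha).astype(int)

    return rule
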