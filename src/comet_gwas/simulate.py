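"""Synthetic paired GWAS summary statistics with annotated variant panels.

The generator emulates the sampling structure of two GWAS on a shared
panel of m approximately independent common variants:

* each of K binary annotation categories is assigned independently per
  variant at a stated marginal frequency (defaults: Q1 51.5%, Q2 0.39%,
  Q3 0.54%, Q5 1.40%, Q6 64.1% — the frequency profile of functional
  consequence classes among LD-pruned common European variants);
* causal status is planted so that proportions p1 and p2 of variants are
  associated with traits 1 and 2 and a proportion p12 with both; under an
  enrichment scenario a proportion p12' of variants are shared-causal AND
  inside the enriched category (the null allocation is p12' = p12 times
  the category frequency, i.e. uniform);
* summary statistics are drawn from the asymptotic sampling distribution
  of the per-variant association estimate: the standard error follows
  from the MAF and study size, the estimate is the true effect plus
  N(0, se^2) noise.  Shared-causal variants receive a common effect in
  both traits; studies sharing individuals get correlated noise.

Generation happens at the summary-statistic level rather than via
genotypes: the enrichment models consume only summary statistics, and
their calibration under the null depends only on the sampling
distribution of the association evidence.  Variants are simulated as
independent (the panel represents post-clumping variants), so LD clumping
is exercised separately on explicit pairwise-r^2 tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .assoc import LN10, BFDecisionRule, InvalidInputError

logger = logging.getLogger(__name__)

#: annotation category frequencies used by default in simulations
SIM_CATEGORY_PROPS: dict[str, float] = {
    "Q1": 0.515, "Q2": 0.0039, "Q3": 0.0054, "Q5": 0.0140, "Q6": 0.641,
}

#: catalogue of the standard variant-consequence covariate taxonomy:
#: description plus frequency among common CEU variants (unpruned and
#: LD-pruned at r^2 > 0.1).  Q4 is excluded from default models because
#: fewer than 0.025% of pruned variants fall in it.
COVARIATE_CATALOG: tuple[dict, ...] = (
    {"label": "Q1", "description": "transcribed but not translated region",
     "prop_unpruned": 0.513, "prop_pruned": 0.517},
    {"label": "Q2", "description": "translated, no amino-acid change",
     "prop_unpruned": 0.00334, "prop_pruned": 0.00380},
    {"label": "Q3", "description": "potentially deleterious",
     "prop_unpruned": 0.00341, "prop_pruned": 0.00422},
    {"label": "Q4", "description": "potentially loss of function",
     "prop_unpruned": 0.000104, "prop_pruned": 0.000139},
    {"label": "Q5", "description": "potentially regulatory or regulatory",
     "prop_unpruned": 0.135, "prop_pruned": 0.144},
    {"label": "Q6", "description": "intergenic",
     "prop_unpruned": 0.635, "prop_pruned": 0.638},
)


def covariate_catalog() -> pd.DataFrame:
    """The covariate taxonomy as a DataFrame indexed by label."""
    return pd.DataFrame(COVARIATE_CATALOG).set_index("label")


@dataclass
class SimulationConfig:
    """All generative parameters of a paired-study simulation.

    Defaults reproduce the null calibration setting: a 208,780-variant
    panel, marginal associated proportions p1 = 0.04 and p2 = 0.02, shared
    proportion p12 = 5e-4, two equal-sized case-control studies with 3000
    and 5000 cases (and as many controls), and no enriched category.

    ``p12_prime`` is the proportion of all variants that are shared-causal
    AND inside ``enriched_category``; the null allocation for a category
    of frequency q is ``p12_prime = p12 * q``.  ``effect_floor`` (the
    minimum |effect|) defaults so that a variant at the floor is detected
    at the Bayes-factor threshold with probability ~0.8 in the smaller
    study at a typical MAF.
    """

    m: int = 208_780
    category_props: Mapping[str, float] = field(
        default_factory=lambda: dict(SIM_CATEGORY_PROPS))
    p1: float = 0.04
    p2: float = 0.02
    p12: float = 5e-4
    enriched_category: str | None = None
    p12_prime: float | None = None
    study_type: str = "case-control"
    N1: int = 3000
    N2: int = 5000
    shared_individuals: float = 0.0
    effect_sd: float = 0.2
    effect_floor: float | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    prior_sd: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise InvalidInputError("m must be positive")
        for lab, q in self.category_props.items():
            if not (0.0 < q < 1.0):
                raise InvalidInputError(
                    f"category proportion for {lab!r} must lie strictly in (0, 1)")
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise InvalidInputError(f"{name} must lie in [0, 1)")
        if self.p12 > min(self.p1, self.p2):
            raise InvalidInputError("p12 cannot exceed min(p1, p2)")
        if self.study_type not in ("case-control", "quantitative"):
            raise InvalidInputError("study_type must be case-control or quantitative")
        if self.enriched_category is not None:
            if self.enriched_category not in self.category_props:
                raise InvalidInputError(
                    f"unknown enriched category {self.enriched_category!r}")
            if self.p12_prime is None:
                self.p12_prime = self.null_p12_prime(self.enriched_category)
            if not (0.0 <= self.p12_prime <= self.p12):
                raise InvalidInputError("p12_prime must lie in [0, p12]")
        if not (0.0 <= self.shared_individuals <= 1.0):
            raise InvalidInputError("shared_individuals must lie in [0, 1]")
        if not (0.05 <= self.maf_range[0] < self.maf_range[1] <= 0.5):
            raise InvalidInputError("maf_range must be within [0.05, 0.5]")
        if self.effect_floor is None:
            se = typical_se(min(self.N1, self.N2), study_type=self.study_type)
            self.effect_floor = effect_floor_for_power(
                se, power=0.8, prior_sd=self.prior_sd)

    def null_p12_prime(self, category: str) -> float:
        """p12' under no enrichment: uniform allocation over the category."""
        return self.p12 * float(self.category_props[category])


@dataclass
class TruthTable:
    """Ground truth of one simulated panel.

    ``table`` is indexed by variant id with boolean columns
    ``causal_trait1``, ``causal_trait2``, ``causal_shared`` and the
    per-variant ``maf``.
    """

    table: pd.DataFrame

    @property
    def snp_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class SimulatedStudy:
    """A simulated study pair: summary statistics, annotations, truth."""

    stats: dict
    annotations: pd.DataFrame
    truth: TruthTable
    config: SimulationConfig


# --------------------------------------------------------------------------
# detection-power helpers


def typical_se(N: int, maf: float = 0.275, study_type: str = "case-control") -> float:
    """Asymptotic SE of the association estimate at a given MAF.

    Case-control: studies of N cases and N controls with a log-OR effect,
    se = sqrt(1 / (N * maf * (1 - maf))).  Quantitative: N individuals and
    a standardised effect, se = 1 / sqrt(2 * N * maf * (1 - maf)).
    """
    if study_type == "case-control":
        return math.sqrt(1.0 / (N * maf * (1.0 - maf)))
    return 1.0 / math.sqrt(2.0 * N * maf * (1.0 - maf))


def z_cutoff(se: float, rule: BFDecisionRule | None = None,
             prior_sd: float | None = None) -> float:
    """|z| above which log10(ABF) exceeds the rule's decision threshold."""
    rule = rule or BFDecisionRule()
    W = (prior_sd if prior_sd is not None else rule.prior_sd) ** 2
    V = se**2
    if W <= 0:
        raise InvalidInputError("prior_sd must be positive for a finite cutoff")
    z2 = (rule.log10_threshold * LN10 + 0.5 * math.log((V + W) / V)) \
        * 2.0 * (V + W) / W
    return math.sqrt(max(z2, 0.0))


def detection_power(b: float, se: float, rule: BFDecisionRule | None = None,
                    prior_sd: float | None = None) -> float:
    """Probability a variant with true effect b is called associated."""
    zc = z_cutoff(se, rule, prior_sd)
    mu = b / se
    return float(norm.sf(zc - mu) + norm.cdf(-zc - mu))


def effect_floor_for_power(se: float, power: float = 0.8,
                           rule: BFDecisionRule | None = None,
                           prior_sd: float | None = None) -> float:
    """Smallest |effect| detected with the given probability.

    Inverts :func:`detection_power` in b (monotone for b >= 0) by
    bracketed root-finding.
    """
    if not (0.0 < power < 1.0):
        raise InvalidInputError("power must lie strictly in (0, 1)")
    zc = z_cutoff(se, rule, prior_sd)
    approx = se * (zc + norm.ppf(power))
    lo, hi = 0.0, max(4.0 * approx, se)
    return float(brentq(
        lambda b: detection_power(b, se, rule, prior_sd) - power, lo, hi,
        xtol=1e-12,
    ))


# --------------------------------------------------------------------------
# generation


def _rand_round(x: float, rng: np.random.Generator) -> int:
    """Randomised rounding: unbiased integer with mean x."""
    base = math.floor(x)
    return base + int(rng.random() < (x - base))


def _snp_ids(m: int) -> pd.Index:
    return pd.Index([f"snp{i:07d}" for i in range(m)], name="snp")


def simulate_annotations(cfg: SimulationConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Binary m x K annotation matrix with independent category columns.

    Each column is Bernoulli at the configured frequency; a variant may
    belong to several categories, as with real consequence annotations.
    A joint-membership fixture may be passed straight to the model
    instead if correlated memberships are wanted.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    labels = list(cfg.category_props)
    u = rng.random((cfg.m, len(labels)))
    props = np.array([cfg.category_props[c] for c in labels])
    return pd.DataFrame((u < props).astype(int), index=_snp_ids(cfg.m),
                        columns=labels)


def assign_causal(cfg: SimulationConfig, annotations: pd.DataFrame,
                  rng: np.random.Generator | None = None) -> TruthTable:
    """Plant causal status and MAFs on an annotated panel.

    Shared-causal variants: without an enriched category, m * p12 of them
    (randomised rounding keeps the expectation exact at any m) are drawn
    uniformly.  With an enriched category, each shared-causal variant is
    assigned to the category independently with probability p12' / p12 —
    the "proportion among the causal variants" — and drawn uniformly
    within (or outside) the category.  The in-category count therefore
    keeps its binomial dispersion, and at the null point
    p12' = p12 * prop(category) the allocation is distributionally
    identical to the uniform draw.  Trait-1-only and trait-2-only causal
    variants are then drawn uniformly from the remaining variants to hit
    the p1, p2 marginal totals.  Causal variants may belong to any
    category.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    m = cfg.m
    ids = annotations.index
    if len(ids) != m:
        raise InvalidInputError("annotation matrix size differs from config m")

    n12 = _rand_round(m * cfg.p12, rng)
    if cfg.enriched_category is None:
        shared = rng.choice(m, size=n12, replace=False)
    else:
        members = np.flatnonzero(
            annotations[cfg.enriched_category].to_numpy() == 1)
        q = cfg.p12_prime / cfg.p12 if cfg.p12 > 0 else 0.0
        n_in = int(rng.binomial(n12, q))
        n_out = n12 - n_in
        if n_in > len(members) or n_out > m - len(members):
            raise InvalidInputError(
                "infeasible enrichment counts for category "
                f"{cfg.enriched_category!r}")
        nonmembers = np.setdiff1d(np.arange(m), members, assume_unique=True)
        shared = np.concatenate([
            rng.choice(members, size=n_in, replace=False),
            rng.choice(nonmembers, size=n_out, replace=False),
        ])
    shared_mask = np.zeros(m, dtype=bool)
    shared_mask[shared] = True

    n1_only = _rand_round(m * (cfg.p1 - cfg.p12), rng)
    n2_only = _rand_round(m * (cfg.p2 - cfg.p12), rng)
    pool = np.flatnonzero(~shared_mask)
    if n1_only + n2_only > len(pool):
        raise InvalidInputError("causal proportions exceed the panel size")
    picks = rng.choice(pool, size=n1_only + n2_only, replace=False)
    c1 = shared_mask.copy()
    c1[picks[:n1_only]] = True
    c2 = shared_mask.copy()
    c2[picks[n1_only:]] = True

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    table = pd.DataFrame({
        "causal_trait1": c1, "causal_trait2": c2, "causal_shared": shared_mask,
        "maf": maf,
    }, index=ids)
    logger.info("planted causal variants: trait1=%d trait2=%d shared=%d",
                c1.sum(), c2.sum(), shared_mask.sum())
    return TruthTable(table=table)


def _truncated_effects(n: int, cfg: SimulationConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Effects ~ N(0, effect_sd^2) with |b| >= effect_floor, random sign."""
    a = cfg.effect_floor / cfg.effect_sd
    u = rng.uniform(norm.cdf(a), 1.0, size=n)
    mag = cfg.effect_sd * norm.ppf(u)
    sign = rng.choice((-1.0, 1.0), size=n)
    return sign * mag


def simulate_summary_stats(truth: TruthTable, cfg: SimulationConfig,
                           rng: np.random.Generator | None = None) -> dict:
    """Draw per-trait summary statistics from the asymptotic distribution.

    Returns ``{"trait1": df, "trait2": df}`` with columns
    ``snp, beta, se``.  Non-causal variants get beta ~ N(0, se^2); causal
    variants add a true effect drawn once per variant from the truncated
    normal effect distribution, with shared-causal variants receiving the
    identical effect in both traits.  If ``shared_individuals`` > 0 the
    per-variant noise of the two traits is correlated with that
    coefficient.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    t = truth.table
    m = len(t)
    maf = t["maf"].to_numpy()
    Ns = {"trait1": cfg.N1, "trait2": cfg.N2}
    if cfg.study_type == "case-control":
        se = {k: np.sqrt(1.0 / (N * maf * (1.0 - maf))) for k, N in Ns.items()}
    else:
        se = {k: 1.0 / np.sqrt(2.0 * N * maf * (1.0 - maf)) for k, N in Ns.items()}

    b = {k: np.zeros(m) for k in Ns}
    shared = t["causal_shared"].to_numpy()
    b_shared = _truncated_effects(int(shared.sum()), cfg, rng)
    for k, col in (("trait1", "causal_trait1"), ("trait2", "causal_trait2")):
        b[k][shared] = b_shared
        only = t[col].to_numpy() & ~shared
        b[k][only] = _truncated_effects(int(only.sum()), cfg, rng)

    rho = cfg.shared_individuals
    e1 = rng.standard_normal(m)
    if rho > 0:
        e2 = rho * e1 + math.sqrt(1.0 - rho**2) * rng.standard_normal(m)
    else:
        e2 = rng.standard_normal(m)
    noise = {"trait1": e1, "trait2": e2}

    out = {}
    for k in Ns:
        out[k] = pd.DataFrame({
            "snp": truth.snp_ids,
            "beta": b[k] + se[k] * noise[k],
            "se": se[k],
        })
    return out


def simulate_study_pair(cfg: SimulationConfig,
                        rng: np.random.Generator | None = None) -> SimulatedStudy:
    """Full generative chain: annotations -> causal truth -> summary stats."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    annotations = simulate_annotations(cfg, rng)
    truth = assign_causal(cfg, annotations, rng)
    stats = simulate_summary_stats(truth, cfg, rng)
    return SimulatedStudy(stats=stats, annotations=annotations, truth=truth,
                          config=cfg)


def with_enrichment(cfg: SimulationConfig, category: str,
                    p12_prime: float) -> SimulationConfig:
    """Copy of ``cfg`` with an enriched category at a given p12'."""
    return replace(cfg, enriched_category=category, p12_prime=p12_prime)
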