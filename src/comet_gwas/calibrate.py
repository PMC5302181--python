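"""Replicate-level calibration harness: type-I error, power, inflation, QQ.

Runs the full generative chain (simulate a study pair, fit the two-stage
enrichment models, apply the hypergeometric comparator) across seeded
replicates and aggregates per-covariate rejection rates with Wilson 95%
binomial intervals, genomic-control-style inflation factors of the
standardised coefficient estimates, and QQ quantiles against N(0, 1).

Replicates are seeded from one master seed through independent spawned
streams, so any run can be replayed exactly from its recorded seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .assoc import BFDecisionRule, InvalidInputError, call_matrix
from .baseline import overlap_hypergeom_tests
from .model import SeparationError, comet, overlap_response
from .simulate import SimulationConfig, simulate_study_pair, with_enrichment

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with one degree of freedom
CHI2_1_MEDIAN = 0.45493642311957283


@dataclass
class CalibrationResult:
    """Aggregated calibration summary for one (method, covariate) cell."""

    method: str
    covariate: str
    n_reps: int
    alpha: float
    rejection_rate: float
    ci_lo: float
    ci_hi: float
    inflation: float
    qq: tuple | None = None


@dataclass
class CalibrationRun:
    """Raw per-replicate records plus aggregated results."""

    records: pd.DataFrame
    results: list
    alpha: float
    seed: int | None
    n_degenerate: int = 0


def inflation_factor(standardized_estimates, positive_only: bool = False) -> float:
    """Median-chi-square inflation factor of standardised estimates.

    lambda = median(z^2) / median(chi^2_1); 1 indicates calibrated
    statistics.  ``positive_only=True`` computes the one-sided variant
    from the positive statistics only, appropriate for small categories
    where negative estimates are censored by the exclusion rule.
    """
    z = np.asarray(standardized_estimates, dtype=float)
    z = z[np.isfinite(z)]
    if positive_only:
        z = z[z > 0]
    if z.size == 0:
        raise InvalidInputError("no standardized estimates supplied")
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def qq_points(standardized_estimates) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) normal quantile pairs for a QQ plot.

    Expected quantiles are Phi^-1((i - 0.5) / n); observed are the sorted
    statistics.  Plotting is left to the caller; the data are the product.
    """
    z = np.asarray(standardized_estimates, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise InvalidInputError("no standardized estimates supplied")
    n = z.size
    expected = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return expected, np.sort(z)


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    # guard float jitter at the boundaries so the interval always contains k/n
    lo = 0.0 if successes == 0 else min(float(lo), successes / n)
    hi = 1.0 if successes == n else max(float(hi), successes / n)
    return lo, hi


def _replicate_records(study, res, alpha: float, covariates) -> list[dict]:
    traits = res.traits
    Y = call_matrix(res.calls)
    y_ov = overlap_response([Y[t].to_numpy() for t in traits])
    hyper = overlap_hypergeom_tests(y_ov, study.annotations).set_index("covariate")
    ov = res.overlap
    rows = []
    for c in covariates:
        rec = {"covariate": c}
        for j, t in enumerate(traits, start=1):
            fit = res.marginal[t]
            rec[f"z_marg{j}"] = (float(fit.gamma[c] / fit.se[c])
                                 if c in fit.gamma.index else np.nan)
        if c in ov.beta.index:
            rec["z_overlap"] = float(ov.beta[c] / ov.se[c])
            rec["reject_comet"] = bool(ov.p_one_sided[c] < alpha)
            rec["excluded"] = False
        else:
            rec["z_overlap"] = np.nan
            rec["reject_comet"] = False
            rec["excluded"] = True
        rec["p_hyper"] = float(hyper.at[c, "p"])
        rec["reject_hyper"] = bool(rec["p_hyper"] < alpha)
        rows.append(rec)
    return rows


def run_replicates(
    cfg: SimulationConfig,
    n_reps: int,
    alpha: float = 0.05,
    seed: int | None = None,
    rule: BFDecisionRule | None = None,
) -> CalibrationRun:
    """Simulate -> fit -> record, ``n_reps`` times, and aggregate.

    Per replicate and covariate the records hold the standardised
    marginal and overlap estimates, the one-sided overlap rejection at
    ``alpha``, the exclusion flag, and the hypergeometric comparator's
    p-value and rejection.  Degenerate replicates (no called or no
    overlap variants — possible at very small panel sizes) contribute
    non-rejections with missing statistics and are counted.
    """
    if n_reps < 1:
        raise InvalidInputError("n_reps must be at least 1")
    if not (0.0 < alpha <= 1.0):
        raise InvalidInputError("alpha must lie in (0, 1]")
    rule = rule or BFDecisionRule(prior_sd=cfg.prior_sd)
    covariates = list(cfg.category_props)
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    all_rows: list[dict] = []
    n_degenerate = 0
    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        study = simulate_study_pair(cfg, rng)
        try:
            res = comet(study.stats, study.annotations, rule)
            rows = _replicate_records(study, res, alpha, covariates)
        except (InvalidInputError, SeparationError) as exc:
            logger.warning("replicate %d degenerate: %s", rep, exc)
            n_degenerate += 1
            rows = [{"covariate": c, "z_marg1": np.nan, "z_marg2": np.nan,
                     "z_overlap": np.nan, "reject_comet": False,
                     "excluded": True, "p_hyper": np.nan,
                     "reject_hyper": False} for c in covariates]
        for r in rows:
            r["rep"] = rep
        all_rows.extend(rows)
    records = pd.DataFrame(all_rows)
    results = summarize(records, alpha=alpha, n_reps=n_reps)
    return CalibrationRun(records=records, results=results, alpha=alpha,
                          seed=seed, n_degenerate=n_degenerate)


def summarize(records: pd.DataFrame, alpha: float, n_reps: int) -> list:
    """Per-covariate CalibrationResult rows for both methods."""
    out = []
    for c, sub in records.groupby("covariate", sort=False):
        z_ov = sub["z_overlap"].to_numpy(dtype=float)
        z_ov = z_ov[np.isfinite(z_ov)]
        lam = inflation_factor(z_ov) if z_ov.size else np.nan
        k = int(sub["reject_comet"].sum())
        lo, hi = wilson_ci(k, n_reps)
        out.append(CalibrationResult(
            method="comet", covariate=str(c), n_reps=n_reps, alpha=alpha,
            rejection_rate=k / n_reps, ci_lo=lo, ci_hi=hi, inflation=lam,
            qq=qq_points(z_ov) if z_ov.size else None,
        ))
        kh = int(sub["reject_hyper"].sum())
        lo, hi = wilson_ci(kh, n_reps)
        out.append(CalibrationResult(
            method="hypergeometric", covariate=str(c), n_reps=n_reps,
            alpha=alpha, rejection_rate=kh / n_reps, ci_lo=lo, ci_hi=hi,
            inflation=np.nan, qq=None,
        ))
    return out


def results_frame(run: CalibrationRun) -> pd.DataFrame:
    """Calibration results as a flat table (one row per method x covariate)."""
    return pd.DataFrame([
        {"method": r.method, "covariate": r.covariate, "n_reps": r.n_reps,
         "alpha": r.alpha, "rate": r.rejection_rate,
         "ci_lo": r.ci_lo, "ci_hi": r.ci_hi, "lambda": r.inflation}
        for r in run.results
    ])


def marginal_inflation(run: CalibrationRun, covariate: str,
                       positive_only: bool = False) -> float:
    """Inflation factor pooling both traits' marginal standardised estimates."""
    sub = run.records[run.records["covariate"] == covariate]
    z = np.concatenate([sub["z_marg1"].to_numpy(float),
                        sub["z_marg2"].to_numpy(float)])
    return inflation_factor(z, positive_only=positive_only)


def overlap_inflation(run: CalibrationRun, covariate: str,
                      positive_only: bool = False) -> float:
    """Inflation factor of the overlap-model standardised estimates."""
    sub = run.records[run.records["covariate"] == covariate]
    return inflation_factor(sub["z_overlap"].to_numpy(float),
                            positive_only=positive_only)


def power_sweep(
    cfg: SimulationConfig,
    p12_prime_grid,
    n_reps: int,
    alpha: float = 0.05,
    seed: int | None = None,
    category: str = "Q5",
    rule: BFDecisionRule | None = None,
) -> pd.DataFrame:
    """Rejection rate of one category's overlap test across a p12' grid.

    Each grid point reruns the replicate harness with the category set as
    enriched at that p12'; the null point p12' = p12 * prop(category)
    recovers the type-I error.  Returns one row per grid point with the
    rate and its Wilson interval.
    """
    grid = list(p12_prime_grid)
    if not grid:
        raise InvalidInputError("empty p12_prime grid")
    streams = np.random.SeedSequence(seed).spawn(len(grid))
    rows = []
    for p12p, stream in zip(grid, streams):
        sub_seed = int(stream.generate_state(1)[0] % (2**31))
        run = run_replicates(with_enrichment(cfg, category, float(p12p)),
                             n_reps=n_reps, alpha=alpha, seed=sub_seed,
                             rule=rule)
        res = {r.covariate: r for r in run.results if r.method == "comet"}
        r = res[category]
        rows.append({"category": category, "p12_prime": float(p12p),
                     "enrichment_frac": float(p12p) / cfg.p12,
                     "rate": r.rejection_rate, "ci_lo": r.ci_lo,
                     "ci_hi": r.ci_hi, "n_reps": n_reps, "seed": sub_seed})
    return pd.DataFrame(rows)
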