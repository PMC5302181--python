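"""The two-stage corrected overlap and marginal enrichment test (COMET).

Stage one fits, independently for each trait r, a marginal logistic model
for the probability that variant i is called associated with the trait:

    logit(p_ir) = gamma_0r + gamma_r' x_i

where x_i are binary variant-level covariates (functional annotation
categories).  The intercept gamma_0r is the baseline association
probability not attributable to any covariate; a positive significant
gamma suggests the category is enriched for trait-associated variants.

Stage two asks whether variants called associated with *every* trait
(the overlap response Y_i = prod_r Y_ir) concentrate in particular
categories beyond what the marginal models already imply.  The fitted
marginal probabilities give a per-variant log-odds of chance overlap,

    offset_i = log( p1_i p2_i / (1 - p1_i p2_i) ),

which enters the overlap model as a fixed offset:

    logit(p_i) = beta_0 + beta' x_i + offset_i.

If overlap is due to chance alone, all beta are zero and the overlap
probability is just the product of the marginal probabilities; a
significant positive beta_k flags category k as enriched for shared
variants beyond chance, and a significant intercept flags excess sharing
not attributable to any covariate.  Standard errors are taken from the
model treating the offset as known (a leave-one-out jackknife is
available behind a flag); enrichment tests are one-sided Wald tests for
beta > 0, with two-sided p-values reported alongside.

Covariate categories containing no overlap-positive variants are removed
from the overlap model and reported; categories covering fewer than a
configurable minimal fraction of variants (default 0.025%) are excluded
up front, since enrichment tests in near-empty categories are
uninterpretable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .assoc import BFDecisionRule, InvalidInputError, call_matrix, classify

logger = logging.getLogger(__name__)

INTERCEPT = "(Intercept)"

#: fitted marginal probabilities are clipped into this open interval before
#: the offset transform so the offset stays finite
PROB_CLIP = 1e-12

#: categories with a positive fraction below this are excluded up front
MIN_CATEGORY_PROP = 0.00025


class SeparationError(RuntimeError):
    """Perfect (quasi-)separation: the logistic MLE does not exist.

    Reduce the covariate set, or rerun with ``firth=True`` for a
    penalised (Jeffreys-prior) fit.
    """


def validate_design(X: pd.DataFrame) -> pd.DataFrame:
    """Check a design matrix is binary 0/1 with unique labels."""
    if X.columns.has_duplicates:
        raise InvalidInputError("duplicate covariate labels in design matrix")
    vals = X.to_numpy()
    if not ((vals == 0) | (vals == 1)).all():
        raise InvalidInputError("design matrix entries must be 0/1")
    return X.astype(int)


def overlap_response(calls_per_trait: Sequence[np.ndarray | pd.Series]) -> np.ndarray:
    """Elementwise product of per-trait 0/1 verdict vectors.

    The response of the overlap model: 1 iff the variant is called
    associated with every trait.  Concordant *absence* of association is
    deliberately not counted as agreement, since a missing call may simply
    reflect lack of power.
    """
    if len(calls_per_trait) < 2:
        raise InvalidInputError("need verdicts for at least two traits")
    arrs = [np.asarray(v, dtype=int) for v in calls_per_trait]
    m = arrs[0].shape[0]
    for a in arrs:
        if a.shape != (m,):
            raise InvalidInputError("per-trait verdict vectors differ in length")
    out = arrs[0].copy()
    for a in arrs[1:]:
        out *= a
    return out


def chance_offset(*p_hat: np.ndarray) -> np.ndarray:
    """Per-variant log-odds of chance overlap from fitted marginal probabilities.

    With independent per-trait association probabilities p_r at a variant,
    the chance probability that all traits call it is ``prod_r p_r``; the
    offset is ``log(prod / (1 - prod))``.  All entries must lie strictly
    in (0, 1); clip fitted probabilities (see ``PROB_CLIP``) beforehand.
    """
    if len(p_hat) < 2:
        raise InvalidInputError("need fitted probabilities for at least two traits")
    prod = None
    for p in p_hat:
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0.0) | (p >= 1.0)) or np.any(~np.isfinite(p)):
            raise InvalidInputError("fitted probabilities must lie strictly in (0, 1)")
        prod = p if prod is None else prod * p
    return np.log(prod / (1.0 - prod))


# --------------------------------------------------------------------------
# logistic fitting machinery


def _firth_logistic(y, X, offset=None, max_iter=200, tol=1e-10):
    """Jeffreys-prior penalised logistic regression (Firth-type).

    Newton iteration on the penalised score U(b) + H'(0.5 - mu), where H is
    the hat diagonal; gives finite estimates under separation.  Offered as
    an extension for separated data, not the default estimator.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    off = np.zeros(len(y)) if offset is None else np.asarray(offset, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = expit(X @ beta + off)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        U = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ U
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = expit(X @ beta + off)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = X.T @ (X * w[:, None])
    bse = np.sqrt(np.diag(np.linalg.pinv(info)))
    return beta, bse, mu


def _log_likelihood(y, eta):
    # sum(y*eta - log(1 + exp(eta))), numerically safe
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def _newton_logistic(y, X, offset=None, max_iter=60, tol=1e-10):
    """Maximum-likelihood logistic fit by Newton iteration with step-halving.

    Supports a fixed offset; the covariance is the inverse observed
    information at the MLE, so with an offset the SEs are those of the
    known-offset model.  The log-likelihood is concave, making the
    iteration deterministic and reliable away from separation.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    off = np.zeros(len(y)) if offset is None else np.asarray(offset, float)
    p = X.shape[1]
    beta = np.zeros(p)
    if np.all(X[:, 0] == 1.0):  # warm-start the intercept at the crude rate
        ybar = min(max(y.mean(), 1e-10), 1 - 1e-10)
        beta[0] = math.log(ybar / (1.0 - ybar)) - off.mean()
    eta = X @ beta + off
    ll = _log_likelihood(y, eta)
    info = None
    converged = False
    for _ in range(max_iter):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(info) @ grad
        # step-halve until the likelihood does not decrease
        for _h in range(40):
            cand = beta + step
            eta_c = X @ cand + off
            ll_c = _log_likelihood(y, eta_c)
            if ll_c >= ll - 1e-12:
                break
            step = 0.5 * step
        beta, eta = cand, eta_c
        improved, ll = ll_c - ll, ll_c
        if np.max(np.abs(step)) < tol or (0 <= improved < 1e-12):
            converged = True
            break
    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return beta, bse, mu, converged


def _fit_binary_glm(y, X_df: pd.DataFrame, offset=None, firth: bool = False):
    """Fit a binary logistic model, raising SeparationError on a divergent MLE."""
    X = X_df.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if firth:
        params, bse, fitted = _firth_logistic(y, X, offset)
        return (pd.Series(params, index=X_df.columns),
                pd.Series(bse, index=X_df.columns), fitted)
    params, bse, fitted, converged = _newton_logistic(y, X, offset=offset)
    if (not converged or np.any(~np.isfinite(params)) or np.any(~np.isfinite(bse))
            or np.any(np.abs(params) > 15.0) or np.any(bse > 50.0)):
        raise SeparationError(
            "perfect or quasi-perfect separation detected: reduce the covariate "
            "set or refit with firth=True"
        )
    return (pd.Series(params, index=X_df.columns),
            pd.Series(bse, index=X_df.columns), fitted)


def _wald_pvalues(params: pd.Series, bse: pd.Series):
    z = params / bse
    one_sided = pd.Series(norm.sf(z.to_numpy()), index=params.index)
    two_sided = pd.Series(2.0 * norm.sf(np.abs(z.to_numpy())), index=params.index)
    return one_sided, two_sided


# --------------------------------------------------------------------------
# fits


@dataclass
class MarginalFit:
    """Maximum-likelihood fit of one trait's marginal enrichment model."""

    trait_id: str
    gamma0: float
    gamma: pd.Series
    se: pd.Series  # indexed like [INTERCEPT] + covariates
    fitted_p: np.ndarray
    counts: pd.Series  # associated variants per category
    p_one_sided: pd.Series
    p_two_sided: pd.Series
    n_assoc: int
    m: int
    dropped_columns: list[str] = field(default_factory=list)


@dataclass
class OverlapFit:
    """Fit of the offset-corrected overlap enrichment model."""

    traits: tuple
    beta0: float
    beta: pd.Series
    se: pd.Series
    p_one_sided: pd.Series
    p_two_sided: pd.Series
    offset: np.ndarray
    excluded_covariates: list[str]
    counts: pd.Series  # overlap variants per category (incl. excluded, count 0)
    n_overlap: int
    m: int
    se_jackknife: pd.Series | None = None


def fit_marginal(
    y, X: pd.DataFrame, trait_id: str = "trait", firth: bool = False
) -> MarginalFit:
    """Fit the marginal logistic enrichment model for one trait.

    ``y`` is the 0/1 verdict vector; ``X`` the binary annotation matrix
    (no intercept column — one is added).  The full covariate set intended
    for the overlap model should be included here, since the fitted
    probabilities feed the chance-overlap offset.  Columns without
    variation are dropped with a warning.
    """
    X = validate_design(X)
    y = np.asarray(y, dtype=int)
    if y.shape[0] != len(X):
        raise InvalidInputError("response and design matrix differ in length")
    if y.sum() == 0:
        raise InvalidInputError(f"no associated variants for trait {trait_id!r}")
    if y.sum() == y.shape[0]:
        raise InvalidInputError(f"all variants associated for trait {trait_id!r}")

    dropped = [c for c in X.columns if X[c].nunique() < 2]
    if dropped:
        logger.warning("trait %s: dropping constant covariate columns %s",
                       trait_id, dropped)
        X = X.drop(columns=dropped)

    design = X.copy()
    design.insert(0, INTERCEPT, 1)
    params, bse, fitted = _fit_binary_glm(y, design, firth=firth)
    one_sided, two_sided = _wald_pvalues(params, bse)
    counts = pd.Series(
        {c: int(((X[c] == 1) & (y == 1)).sum()) for c in X.columns}, dtype=int
    )
    return MarginalFit(
        trait_id=trait_id,
        gamma0=float(params[INTERCEPT]),
        gamma=params.drop(INTERCEPT),
        se=bse,
        fitted_p=fitted,
        counts=counts,
        p_one_sided=one_sided,
        p_two_sided=two_sided,
        n_assoc=int(y.sum()),
        m=int(y.shape[0]),
        dropped_columns=dropped,
    )


def fit_overlap(
    y_overlap,
    X: pd.DataFrame,
    offset,
    traits: tuple = ("trait1", "trait2"),
    firth: bool = False,
) -> OverlapFit:
    """Fit the overlap enrichment model with a fixed chance-overlap offset.

    Covariates whose category contains zero overlap-positive variants are
    removed before fitting and reported in ``excluded_covariates`` (their
    table rows carry estimate 0, SE NA, p 1, count 0).  Standard errors
    come from the information matrix of the known-offset model.
    """
    X = validate_design(X)
    y = np.asarray(y_overlap, dtype=int)
    offset = np.asarray(offset, dtype=float)
    if y.shape[0] != len(X) or offset.shape[0] != len(X):
        raise InvalidInputError("response, design and offset differ in length")
    if np.any(~np.isfinite(offset)):
        raise InvalidInputError("offset must be finite")
    if y.sum() == 0:
        raise InvalidInputError("no overlap variants")

    counts = pd.Series(
        {c: int(((X[c] == 1) & (y == 1)).sum()) for c in X.columns}, dtype=int
    )
    excluded = [c for c in X.columns if counts[c] == 0]
    if excluded:
        logger.info("overlap model: excluding zero-overlap-count covariates %s",
                    excluded)
    kept = X.drop(columns=excluded)

    design = kept.copy()
    design.insert(0, INTERCEPT, 1)
    params, bse, _ = _fit_binary_glm(y, design, offset=offset, firth=firth)
    one_sided, two_sided = _wald_pvalues(params, bse)
    return OverlapFit(
        traits=tuple(traits),
        beta0=float(params[INTERCEPT]),
        beta=params.drop(INTERCEPT),
        se=bse,
        p_one_sided=one_sided,
        p_two_sided=two_sided,
        offset=offset,
        excluded_covariates=excluded,
        counts=counts,
        n_overlap=int(y.sum()),
        m=int(y.shape[0]),
    )


# --------------------------------------------------------------------------
# orchestration


@dataclass
class CometResult:
    """Everything one COMET run produces."""

    traits: tuple
    calls: pd.DataFrame
    marginal: dict
    overlap: OverlapFit
    guard_excluded: list[str]
    no_offset: bool
    table: pd.DataFrame


def comet(
    trait_stats: Mapping[str, pd.DataFrame],
    annotations: pd.DataFrame,
    rule: BFDecisionRule | None = None,
    *,
    no_offset: bool = False,
    min_category_prop: float = MIN_CATEGORY_PROP,
    firth: bool = False,
    jackknife: bool = False,
) -> CometResult:
    """Run the full two-stage analysis for a set of traits.

    ``trait_stats`` maps trait id to a summary-statistic DataFrame
    (columns ``snp, beta, se``); ``annotations`` is the binary variant x
    category matrix indexed by variant id.  Variants are intersected
    across traits; clumping, if required, is applied beforehand.

    ``no_offset=True`` drops the chance-overlap offset (sensitivity
    analysis: overlap enrichment *not* corrected for the marginals).
    ``jackknife=True`` additionally computes leave-one-variant-out
    jackknife SEs for the overlap coefficients (quadratic cost in m —
    intended for small panels).
    """
    rule = rule or BFDecisionRule()
    if len(trait_stats) < 2:
        raise InvalidInputError("COMET needs at least two traits")
    calls = classify(trait_stats, rule)
    Y = call_matrix(calls)
    traits = tuple(Y.columns)

    X = annotations.reindex(Y.index)
    n_unannotated = int(X.isna().any(axis=1).sum())
    if n_unannotated:
        logger.info("%d variants missing from the annotation matrix were "
                    "assigned all-zero covariates", n_unannotated)
        X = X.fillna(0)
    X = validate_design(X)

    props = X.mean(axis=0)
    guard_excluded = [c for c in X.columns if props[c] < min_category_prop]
    if guard_excluded:
        logger.info("excluding near-empty categories (< %g positive): %s",
                    min_category_prop, guard_excluded)
        X = X.drop(columns=guard_excluded)

    marginal = {
        t: fit_marginal(Y[t].to_numpy(), X, trait_id=t, firth=firth) for t in traits
    }
    if no_offset:
        offset = np.zeros(len(X))
    else:
        clipped = [np.clip(marginal[t].fitted_p, PROB_CLIP, 1 - PROB_CLIP)
                   for t in traits]
        offset = chance_offset(*clipped)
    y_overlap = overlap_response([Y[t].to_numpy() for t in traits])
    overlap = fit_overlap(y_overlap, X, offset, traits=traits, firth=firth)

    if jackknife:
        overlap.se_jackknife = _jackknife_overlap_se(
            Y, X, traits, no_offset=no_offset, firth=firth
        )

    result = CometResult(
        traits=traits, calls=calls, marginal=marginal, overlap=overlap,
        guard_excluded=guard_excluded, no_offset=no_offset,
        table=pd.DataFrame(),
    )
    result.table = results_table(result)
    return result


def _jackknife_overlap_se(Y, X, traits, no_offset=False, firth=False):
    """Leave-one-variant-out jackknife SEs for the overlap coefficients.

    Refits both stages per deletion; O(m) model fits, so only sensible on
    small panels.  The known-offset SEs are the default for exactly this
    reason.
    """
    m = len(X)
    ests: list[pd.Series] = []
    idx = np.arange(m)
    for i in range(m):
        keep = idx != i
        Xi = X.iloc[keep]
        marg = {t: fit_marginal(Y[t].to_numpy()[keep], Xi, trait_id=t, firth=firth)
                for t in traits}
        if no_offset:
            off = np.zeros(m - 1)
        else:
            off = chance_offset(*[
                np.clip(marg[t].fitted_p, PROB_CLIP, 1 - PROB_CLIP) for t in traits
            ])
        yov = overlap_response([Y[t].to_numpy()[keep] for t in traits])
        fit = fit_overlap(yov, Xi, off, traits=traits, firth=firth)
        full = pd.concat([pd.Series({INTERCEPT: fit.beta0}), fit.beta])
        ests.append(full)
    mat = pd.DataFrame(ests)
    mean = mat.mean(axis=0)
    var = (m - 1) / m * ((mat - mean) ** 2).sum(axis=0)
    return np.sqrt(var)


def results_table(result: CometResult) -> pd.DataFrame:
    """Long-format results: one row per (model, covariate).

    Columns: model, covariate, estimate, se, p_one_sided, p_two_sided,
    count.  Intercept rows report the two-sided p only.  Covariates
    excluded from the overlap model for zero overlap counts appear with
    estimate 0, SE NA, p 1 and count 0.
    """
    rows = []
    for t in result.traits:
        fit = result.marginal[t]
        rows.append({
            "model": f"marginal:{t}", "covariate": INTERCEPT,
            "estimate": fit.gamma0, "se": fit.se[INTERCEPT],
            "p_one_sided": np.nan, "p_two_sided": fit.p_two_sided[INTERCEPT],
            "count": fit.n_assoc,
        })
        for c in fit.gamma.index:
            rows.append({
                "model": f"marginal:{t}", "covariate": c,
                "estimate": fit.gamma[c], "se": fit.se[c],
                "p_one_sided": fit.p_one_sided[c],
                "p_two_sided": fit.p_two_sided[c],
                "count": fit.counts[c],
            })
    ov = result.overlap
    model = "overlap:" + "*".join(map(str, ov.traits))
    rows.append({
        "model": model, "covariate": INTERCEPT,
        "estimate": ov.beta0, "se": ov.se[INTERCEPT],
        "p_one_sided": np.nan, "p_two_sided": ov.p_two_sided[INTERCEPT],
        "count": ov.n_overlap,
    })
    for c in ov.counts.index:
        if c in ov.excluded_covariates:
            rows.append({
                "model": model, "covariate": c, "estimate": 0.0, "se": np.nan,
                "p_one_sided": 1.0, "p_two_sided": np.nan, "count": 0,
            })
        else:
            rows.append({
                "model": model, "covariate": c,
                "estimate": ov.beta[c], "se": ov.se[c],
                "p_one_sided": ov.p_one_sided[c],
                "p_two_sided": ov.p_two_sided[c],
                "count": ov.counts[c],
            })
    return pd.DataFrame(rows)
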