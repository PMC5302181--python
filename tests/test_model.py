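"""Two-stage enrichment model: marginal fits, offset, overlap fit, pipeline."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from comet_gwas.assoc import InvalidInputError
from comet_gwas.model import (INTERCEPT, SeparationError, _jackknife_overlap_se,
                              chance_offset, comet, fit_marginal, fit_overlap,
                              overlap_response, results_table)
from comet_gwas.simulate import SimulationConfig, simulate_study_pair


def logit(p):
    return math.log(p / (1 - p))


def table_2x2(a, b, c, d):
    """y/x vectors for a 2x2 of (assoc, not) x (in category, out)."""
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)].astype(int)
    x = np.r_[np.ones(a + b), np.zeros(c + d)].astype(int)
    return y, pd.DataFrame({"Q": x})


class TestOverlapResponse:
    def test_pairwise_product(self):
        out = overlap_response([np.array([1, 1, 0]), np.array([1, 0, 0])])
        assert list(out) == [1, 0, 0]

    def test_all_zero_partner_annihilates(self):
        out = overlap_response([np.array([1, 1, 1]), np.zeros(3, int)])
        assert not out.any()

    def test_three_trait_product(self):
        out = overlap_response([np.array([1, 1]), np.array([1, 1]),
                                np.array([1, 0])])
        assert list(out) == [1, 0]

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            overlap_response([np.array([1, 0]), np.array([1])])


class TestChanceOffset:
    def test_half_half(self):
        assert chance_offset(np.array([0.5]), np.array([0.5]))[0] == \
            pytest.approx(-math.log(3.0), abs=1e-12)

    def test_null_marginal_rates(self):
        val = chance_offset(np.array([0.04]), np.array([0.02]))[0]
        assert val == pytest.approx(math.log(0.0008 / 0.9992), abs=1e-12)
        assert val == pytest.approx(-7.130, abs=5e-4)

    def test_monotone_to_minus_infinity(self):
        p = np.array([1e-2, 1e-4, 1e-6, 1e-8])
        off = chance_offset(p, p)
        assert np.all(np.diff(off) < 0)

    @pytest.mark.parametrize("bad", [0.0, 1.0])
    def test_boundary_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            chance_offset(np.array([bad]), np.array([0.5]))


class TestFitMarginal:
    def test_intercept_only_is_logit_of_mean(self):
        y = np.r_[np.ones(4), np.zeros(96)].astype(int)
        fit = fit_marginal(y, pd.DataFrame(index=range(100)))
        assert fit.gamma0 == pytest.approx(logit(0.04), abs=1e-8)
        assert fit.gamma0 == pytest.approx(-3.178, abs=5e-4)

    def test_single_covariate_matches_2x2_log_odds_ratio(self):
        a, b, c, d = 30, 70, 20, 180
        y, X = table_2x2(a, b, c, d)
        fit = fit_marginal(y, X)
        assert fit.gamma["Q"] == pytest.approx(math.log(a * d / (b * c)), abs=1e-6)
        assert fit.gamma0 == pytest.approx(logit(c / (c + d)), abs=1e-6)
        # Wald SE of a 2x2 log-OR
        assert fit.se["Q"] == pytest.approx(
            math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), abs=1e-6)
        assert fit.counts["Q"] == a

    def test_perfect_separation_raises(self):
        x = np.r_[np.ones(10), np.zeros(30)].astype(int)
        with pytest.raises(SeparationError):
            fit_marginal(x, pd.DataFrame({"Q": x}))

    def test_firth_fallback_is_finite_under_separation(self):
        x = np.r_[np.ones(10), np.zeros(30)].astype(int)
        fit = fit_marginal(x, pd.DataFrame({"Q": x}), firth=True)
        assert np.isfinite(fit.gamma["Q"]) and np.isfinite(fit.se["Q"])

    def test_constant_column_dropped_with_warning(self):
        y = np.r_[np.ones(10), np.zeros(40)].astype(int)
        X = pd.DataFrame({"Q": np.zeros(50, int),
                          "R": np.tile([1, 0], 25).astype(int)})
        fit = fit_marginal(y, X)
        assert fit.dropped_columns == ["Q"]
        assert list(fit.gamma.index) == ["R"]

    def test_degenerate_response_rejected(self):
        with pytest.raises(InvalidInputError, match="no associated"):
            fit_marginal(np.zeros(10, int), pd.DataFrame(index=range(10)))
        with pytest.raises(InvalidInputError, match="all variants"):
            fit_marginal(np.ones(10, int), pd.DataFrame(index=range(10)))


class TestFitOverlap:
    def test_constant_offset_shifts_intercept_only(self):
        a, b, c, d = 12, 88, 30, 370
        y, X = table_2x2(a, b, c, d)
        off = np.full(len(y), -2.5)
        fit = fit_overlap(y, X, off)
        assert fit.beta["Q"] == pytest.approx(math.log(a * d / (b * c)), abs=1e-6)
        assert fit.beta0 == pytest.approx(logit(c / (c + d)) + 2.5, abs=1e-6)

    def test_zero_overlap_count_covariate_excluded(self):
        y = np.r_[np.ones(5), np.zeros(95)].astype(int)
        r = np.zeros(100, int)
        r[[0, 1, 2, 20, 21, 22, 23, 24, 25, 26]] = 1  # 3 overlap hits, 7 misses
        X = pd.DataFrame({
            "Q": np.r_[np.zeros(5), np.ones(20), np.zeros(75)].astype(int),
            "R": r,
        })
        fit = fit_overlap(y, X, np.zeros(100))
        assert fit.excluded_covariates == ["Q"]
        assert fit.counts["Q"] == 0 and fit.counts["R"] == 3
        assert "Q" not in fit.beta.index

    def test_no_overlap_variants_rejected(self):
        with pytest.raises(InvalidInputError, match="no overlap"):
            fit_overlap(np.zeros(10, int), pd.DataFrame(index=range(10)),
                        np.zeros(10))

    def test_one_sided_pvalue_orientation(self):
        # strongly enriched category must give a small one-sided p
        y = np.r_[np.ones(40), np.zeros(60), np.ones(5), np.zeros(295)].astype(int)
        X = pd.DataFrame({"Q": np.r_[np.ones(100), np.zeros(300)].astype(int)})
        fit = fit_overlap(y, X, np.zeros(400))
        assert fit.beta["Q"] > 0
        assert fit.p_one_sided["Q"] < 1e-6
        assert fit.p_two_sided["Q"] == pytest.approx(2 * fit.p_one_sided["Q"], rel=1e-9)


class TestSolverAgainstStatsmodels:
    """The in-package Newton solver vs the GLM reference, with offsets."""

    @pytest.mark.parametrize("use_offset", [False, True])
    def test_random_instances(self, rng, use_offset):
        for _ in range(5):
            n = 500
            X = pd.DataFrame({
                "A": rng.integers(0, 2, n), "B": rng.integers(0, 2, n)})
            eta = -1.0 + 0.8 * X["A"] - 0.5 * X["B"]
            off = rng.normal(0, 0.5, n) if use_offset else np.zeros(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-(eta + off)))).astype(int)
            if y.sum() in (0, n):
                continue
            fit = fit_overlap(y, X, off) if use_offset else fit_marginal(y, X)
            Xd = np.column_stack([np.ones(n), X.to_numpy(float)])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = sm.GLM(y.astype(float), Xd, family=sm.families.Binomial(),
                             offset=off).fit()
            mine = np.r_[fit.beta0 if use_offset else fit.gamma0,
                         (fit.beta if use_offset else fit.gamma).to_numpy()]
            se = fit.se.to_numpy()
            assert np.max(np.abs(mine - ref.params)) < 1e-6
            assert np.max(np.abs(se - ref.bse)) < 1e-6


class TestCometPipeline:
    @staticmethod
    def small_study(seed=3, **kw):
        cfg = SimulationConfig(m=20_000, p1=0.05, p2=0.05, p12=0.01,
                               N1=5000, N2=5000, seed=seed, **kw)
        return simulate_study_pair(cfg)

    def test_offset_only_intercept_near_zero_under_chance_overlap(self, rng):
        # verdicts independent across traits: beta0 of the offset model ~ 0
        m = 200_000
        y1 = (rng.random(m) < 0.04).astype(int)
        y2 = (rng.random(m) < 0.02).astype(int)
        X = pd.DataFrame(index=range(m))
        f1 = fit_marginal(y1, X)
        f2 = fit_marginal(y2, X)
        off = chance_offset(f1.fitted_p, f2.fitted_p)
        fit = fit_overlap(overlap_response([y1, y2]), X, off)
        assert abs(fit.beta0) < 3 * fit.se[INTERCEPT]

    def test_marginal_fit_invariant_to_other_trait(self):
        study = self.small_study()
        res1 = comet(study.stats, study.annotations)
        other = study.stats["trait2"].copy()
        other["beta"] = other["beta"].to_numpy()[::-1].copy()
        res2 = comet({"trait1": study.stats["trait1"], "trait2": other},
                     study.annotations)
        pd.testing.assert_series_equal(res1.marginal["trait1"].gamma,
                                       res2.marginal["trait1"].gamma)

    def test_deterministic_rerun(self):
        study = self.small_study()
        t1 = comet(study.stats, study.annotations).table
        t2 = comet(study.stats, study.annotations).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_small_category_guard(self):
        study = self.small_study()
        ann = study.annotations.copy()
        tiny = np.zeros(len(ann), int)
        tiny[0] = 1  # 1/20000 is well below the 0.025% guard
        ann["Qtiny"] = tiny
        res = comet(study.stats, ann)
        assert res.guard_excluded == ["Qtiny"]
        assert "Qtiny" not in res.overlap.counts.index

    def test_no_offset_mode_changes_intercept(self):
        study = self.small_study()
        with_off = comet(study.stats, study.annotations)
        no_off = comet(study.stats, study.annotations, no_offset=True)
        assert no_off.no_offset
        # dropping a large negative offset must be absorbed by the intercept
        assert no_off.overlap.beta0 < with_off.overlap.beta0 - 3

    def test_results_table_contract(self):
        study = self.small_study()
        res = comet(study.stats, study.annotations)
        tbl = results_table(res)
        assert set(tbl.columns) == {"model", "covariate", "estimate", "se",
                                    "p_one_sided", "p_two_sided", "count"}
        models = tbl["model"].unique().tolist()
        assert models == ["marginal:trait1", "marginal:trait2",
                          "overlap:trait1*trait2"]
        for c in res.overlap.excluded_covariates:
            row = tbl[(tbl["model"] == models[-1]) & (tbl["covariate"] == c)]
            assert float(row["estimate"]) == 0.0
            assert np.isnan(float(row["se"]))
            assert float(row["p_one_sided"]) == 1.0
            assert int(row["count"]) == 0

    def test_jackknife_se_comparable_to_known_offset_se(self, rng):
        m = 150
        y1 = (rng.random(m) < 0.4).astype(int)
        y2 = (rng.random(m) < 0.35).astype(int)
        X = pd.DataFrame({"Q": rng.integers(0, 2, m)})
        Y = pd.DataFrame({"t1": y1, "t2": y2})
        jack = _jackknife_overlap_se(Y, X, ("t1", "t2"))
        f1 = fit_marginal(y1, X)
        f2 = fit_marginal(y2, X)
        fit = fit_overlap(overlap_response([y1, y2]), X,
                          chance_offset(f1.fitted_p, f2.fitted_p))
        ratio = jack["Q"] / fit.se["Q"]
        assert 0.3 < ratio < 3.0
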