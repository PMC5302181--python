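"""Synthetic study-pair generator: proportions, truth, sampling distribution."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from comet_gwas.assoc import BFDecisionRule, InvalidInputError, log10_abf
from comet_gwas.simulate import (SimulationConfig, assign_causal,
                                 covariate_catalog, detection_power,
                                 effect_floor_for_power, simulate_annotations,
                                 simulate_study_pair, z_cutoff)


def numeric_z_cutoff(se, rule):
    """Independent oracle: root of log10(ABF(z)) - threshold in |z|."""
    f = lambda z: log10_abf(z * se, se, rule.prior_sd) - rule.log10_threshold
    return brentq(f, 0.0, 50.0, xtol=1e-12)


class TestConfig:
    def test_null_enrichment_identity(self):
        cfg = SimulationConfig(m=1000)
        assert cfg.null_p12_prime("Q5") == pytest.approx(7e-6, abs=1e-18)

    def test_enriched_category_defaults_to_null_point(self):
        cfg = SimulationConfig(m=1000, enriched_category="Q5")
        assert cfg.p12_prime == pytest.approx(7e-6)

    @pytest.mark.parametrize("kw", [
        {"p12": 0.05},                       # exceeds min(p1, p2)
        {"enriched_category": "Q9"},
        {"category_props": {"Q1": 1.0}},
        {"maf_range": (0.0, 0.5)},
        {"study_type": "exome"},
        {"shared_individuals": 1.5},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(InvalidInputError):
            SimulationConfig(m=100, **kw)

    def test_default_effect_floor_hits_target_power(self):
        cfg = SimulationConfig(m=100)
        from comet_gwas.simulate import typical_se
        se = typical_se(min(cfg.N1, cfg.N2))
        assert detection_power(cfg.effect_floor, se) == pytest.approx(0.8, abs=1e-9)

    def test_catalog_covers_six_categories(self):
        cat = covariate_catalog()
        assert list(cat.index) == ["Q1", "Q2", "Q3", "Q4", "Q5", "Q6"]
        assert cat.at["Q4", "prop_pruned"] < 0.00025  # why Q4 sits out of models


class TestAnnotations:
    def test_column_means_concentrate(self):
        cfg = SimulationConfig(m=100_000, seed=5)
        ann = simulate_annotations(cfg)
        for lab, prop in cfg.category_props.items():
            tol = 3 * math.sqrt(prop * (1 - prop) / cfg.m)
            assert abs(ann[lab].mean() - prop) <= tol

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(m=5000, seed=9)
        a = simulate_annotations(cfg)
        b = simulate_annotations(cfg)
        assert a.equals(b)


class TestAssignCausal:
    def test_realised_shared_count(self):
        cfg = SimulationConfig(m=100_000, seed=2)
        truth = assign_causal(cfg, simulate_annotations(cfg))
        t = truth.table
        assert abs(t["causal_shared"].sum() - cfg.m * cfg.p12) <= 1
        assert abs(t["causal_trait1"].sum() - cfg.m * cfg.p1) <= 2
        assert abs(t["causal_trait2"].sum() - cfg.m * cfg.p2) <= 2
        # shared is the intersection
        assert ((t["causal_trait1"] & t["causal_trait2"]) ==
                t["causal_shared"]).all()

    def test_full_enrichment_boundary(self):
        cfg = SimulationConfig(m=50_000, seed=4, enriched_category="Q5",
                               p12_prime=5e-4)
        ann = simulate_annotations(cfg)
        truth = assign_causal(cfg, ann)
        shared = truth.table["causal_shared"]
        assert (ann.loc[shared, "Q5"] == 1).all()

    def test_null_allocation_matches_category_frequencies(self):
        # pooled over replicate panels, shared-causal category membership
        # should match the unconditional frequency
        cfg = SimulationConfig(m=50_000, p12=5e-3, p1=0.04, p2=0.02)
        rng = np.random.default_rng(77)
        in_q1 = tot = 0
        for _ in range(5):
            ann = simulate_annotations(cfg, rng)
            truth = assign_causal(cfg, ann, rng)
            shared = truth.table["causal_shared"].to_numpy()
            in_q1 += int(ann["Q1"].to_numpy()[shared].sum())
            tot += int(shared.sum())
        frac = in_q1 / tot
        assert abs(frac - 0.515) <= 3 * math.sqrt(0.515 * 0.485 / tot)


class TestSummaryStats:
    def test_null_call_rate_matches_analytic_tail(self):
        cfg = SimulationConfig(m=200_000, p1=0.0, p2=0.0, p12=0.0, seed=6)
        study = simulate_study_pair(cfg)
        rule = BFDecisionRule()
        df = study.stats["trait1"]
        lab = log10_abf(df["beta"].to_numpy(), df["se"].to_numpy(),
                        rule.prior_sd)
        rate = float((lab > rule.log10_threshold).mean())
        from scipy.stats import norm
        se = df["se"].to_numpy()
        zc = np.array([z_cutoff(s, rule) for s in se[:2000]])
        expected = float(2 * norm.sf(zc).mean())
        assert abs(rate - expected) <= 3 * math.sqrt(expected / cfg.m) + 5e-4

    def test_z_cutoff_matches_numeric_root(self):
        rule = BFDecisionRule()
        for se in (0.01, 0.03, 0.1):
            assert z_cutoff(se, rule) == pytest.approx(
                numeric_z_cutoff(se, rule), abs=1e-9)

    def test_strong_effect_detected(self):
        # |b|/se = 6 gives essentially certain detection
        assert detection_power(0.6, 0.1) > 0.99

    def test_effect_floor_inverts_power(self):
        for se in (0.02, 0.05):
            b = effect_floor_for_power(se, power=0.9)
            assert detection_power(b, se) == pytest.approx(0.9, abs=1e-9)

    def test_independent_studies_have_uncorrelated_null_z(self):
        cfg = SimulationConfig(m=100_000, p1=0.0, p2=0.0, p12=0.0, seed=8)
        study = simulate_study_pair(cfg)
        z1 = study.stats["trait1"]["beta"] / study.stats["trait1"]["se"]
        z2 = study.stats["trait2"]["beta"] / study.stats["trait2"]["se"]
        assert abs(np.corrcoef(z1, z2)[0, 1]) < 3 / math.sqrt(cfg.m)

    def test_shared_individuals_induce_correlation(self):
        cfg = SimulationConfig(m=100_000, p1=0.0, p2=0.0, p12=0.0, seed=8,
                               shared_individuals=0.5)
        study = simulate_study_pair(cfg)
        z1 = study.stats["trait1"]["beta"] / study.stats["trait1"]["se"]
        z2 = study.stats["trait2"]["beta"] / study.stats["trait2"]["se"]
        assert np.corrcoef(z1, z2)[0, 1] == pytest.approx(0.5, abs=0.02)

    def test_shared_causal_effects_same_sign(self):
        cfg = SimulationConfig(m=50_000, p12=5e-3, p1=0.02, p2=0.01, seed=10,
                               N1=100_000, N2=100_000)
        study = simulate_study_pair(cfg)
        shared = study.truth.table["causal_shared"].to_numpy()
        b1 = study.stats["trait1"]["beta"].to_numpy()[shared]
        b2 = study.stats["trait2"]["beta"].to_numpy()[shared]
        # with huge studies the noise is tiny relative to the planted effect
        assert (np.sign(b1) == np.sign(b2)).mean() > 0.95

    def test_end_to_end_determinism(self):
        cfg = SimulationConfig(m=3000, seed=12)
        a = simulate_study_pair(cfg)
        b = simulate_study_pair(cfg)
        assert a.annotations.equals(b.annotations)
        assert a.truth.table.equals(b.truth.table)
        for t in a.stats:
            assert a.stats[t].equals(b.stats[t])
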