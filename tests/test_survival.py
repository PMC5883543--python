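"""Kaplan-Meier, log-rank, hazard ratios, strata and independence testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

import gbmsig as G
from conftest import logrank_oracle, random_survival_cohort


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        km = G.kaplan_meier([1, 2, 3], [1, 1, 1])
        surv = dict(zip(km.event_times, km.survival))
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[2.0] == pytest.approx(1 / 3)
        assert surv[3.0] == pytest.approx(0.0)
        assert km.median == 2.0  # smallest time with S <= 0.5

    def test_censoring_renormalizes_tail(self):
        km = G.kaplan_meier([1, 2, 3], [1, 0, 1])
        surv = dict(zip(km.event_times, km.survival))
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[3.0] == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        km = G.kaplan_meier([5, 8, 13], [0, 0, 0])
        assert (km.survival == 1.0).all()
        assert np.isinf(km.median)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            G.kaplan_meier([-1, 2], [1, 1])

    def test_survival_monotone_and_ci_ordered(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        km = G.kaplan_meier(t, e)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert (km.ci_lower <= km.survival + 1e-12).all()
        assert (km.survival <= km.ci_upper + 1e-12).all()

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.integers(1, 30), min_size=1, max_size=25))
    def test_equals_empirical_survival_without_censoring(self, times):
        t = np.asarray(times, dtype=float)
        km = G.kaplan_meier(t, np.ones_like(t, dtype=int))
        for ti, s in zip(km.event_times, km.survival):
            assert s == pytest.approx((t > ti).mean(), abs=1e-12)


class TestLogRank:
    def test_hand_computed_four_sample_case(self):
        res = G.log_rank([1, 2, 3, 4], [1, 1, 1, 1], list("AABB"))
        assert res.chi_square == pytest.approx(2.882, abs=0.001)
        assert res.observed["A"] == 2.0
        assert res.expected["A"] == pytest.approx(2 - 7 / 6, abs=1e-9) or \
            res.expected["A"] == pytest.approx(1 / 2 + 1 / 3, abs=1e-9)

    def test_identical_groups_chi_zero(self):
        t = [3, 5, 7, 9]
        res = G.log_rank(t + t, [1, 1, 0, 1] * 2, ["A"] * 4 + ["B"] * 4)
        assert res.chi_square == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            G.log_rank([1, 2], [0, 0], ["A", "B"])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            G.log_rank([1, 2, 3], [1, 1, 1], ["A", "A", "A"])

    def test_matches_brute_force_on_small_cohorts(self):
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 200:
            t, e, g = random_survival_cohort(rng)
            if e.sum() < 1 or len(np.unique(g)) < 2:
                continue
            expected = logrank_oracle(t, e, g)
            if not np.isfinite(expected):
                continue
            res = G.log_rank(t, e, g)
            assert res.chi_square == pytest.approx(expected, abs=1e-8)
            checked += 1

    def test_label_swap_invariance(self):
        t = [1, 4, 2, 8, 3, 9, 5]
        e = [1, 1, 0, 1, 1, 0, 1]
        g = list("ABABABA")
        swapped = ["B" if x == "A" else "A" for x in g]
        assert G.log_rank(t, e, g).chi_square == pytest.approx(
            G.log_rank(t, e, swapped).chi_square)

    def test_censoring_time_beyond_last_event_irrelevant(self):
        # moving an already-censored observation further past the last event
        # leaves every risk set, and hence the statistic, unchanged
        t = [1, 4, 2, 8, 3, 9, 5]
        e = [1, 1, 0, 1, 1, 0, 1]
        g = list("ABABABA")
        base = G.log_rank(t, e, g).chi_square
        moved = G.log_rank([1, 4, 2, 8, 3, 900, 5], e, g).chi_square
        assert moved == pytest.approx(base)

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(200):
            t = rng.exponential(size=40)
            g = rng.permutation(["A"] * 20 + ["B"] * 20)
            ps.append(G.log_rank(t, np.ones(40, int), g).p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestGroupHazardRatio:
    def test_null_ci_covers_one(self):
        covered = 0
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            t = rng.exponential(size=200)
            g = rng.permutation(["low"] * 100 + ["high"] * 100)
            lo, hi = G.group_hazard_ratio(t, np.ones(200, int), g).ci()
            covered += lo <= 1.0 <= hi
        assert covered >= 18

    def test_reference_swap_inverts_hr(self):
        rng = np.random.default_rng(6)
        t = np.r_[rng.exponential(0.5, 50), rng.exponential(1.0, 50)]
        g = np.array(["high"] * 50 + ["low"] * 50)
        fwd = G.group_hazard_ratio(t, np.ones(100, int), g, reference="low")
        rev = G.group_hazard_ratio(t, np.ones(100, int), g, reference="high")
        assert fwd.hr == pytest.approx(1 / rev.hr, rel=1e-6)

    def test_recovers_true_rate_ratio(self):
        rng = np.random.default_rng(13)
        g = np.array(["low"] * 200 + ["high"] * 200)
        t = np.where(g == "high", rng.exponential(0.5, 400),
                     rng.exponential(1.0, 400))
        fit = G.group_hazard_ratio(t, np.ones(400, int), g)
        assert fit.hr == pytest.approx(2.0, abs=0.4)


def _planted_risk(n_samples, effect, seed, n_genes=100, k=10):
    cfg = G.SimulationConfig(n_samples=n_samples, n_genes=n_genes,
                             n_signature_genes=k, effect_size=effect,
                             censoring_rate=0.2, seed=seed)
    expr, clinical, _, truth = G.simulate_cohort(cfg)
    model = G.SignatureModel(tuple(truth.signature_gene_ids),
                             tuple(truth.beta_true))
    risk = G.assign_risk(G.transfer_signature(model, expr, scaling="z"))
    return clinical, risk


class TestStratifiedSurvival:
    def test_single_stratum_matches_unstratified(self):
        clinical, risk = _planted_risk(150, 3.0, seed=31)
        clinical = clinical.assign(subtype="only")
        strata, skipped = G.stratified_survival(clinical, risk.group)
        assert skipped == []
        assert len(strata) == 1
        direct = G.log_rank(clinical["pfs_days"], clinical["pfs_event"],
                            risk.group)
        assert strata[0].log_rank.chi_square == pytest.approx(
            direct.chi_square)

    def test_all_subtypes_significant_with_shared_betas(self):
        clinical, risk = _planted_risk(600, 3.0, seed=17)
        strata, _ = G.stratified_survival(clinical, risk.group)
        assert len(strata) == 4
        assert all(s.log_rank.p < 0.05 for s in strata)

    def test_one_group_stratum_skipped(self):
        clinical, risk = _planted_risk(150, 3.0, seed=31)
        clinical = clinical.assign(subtype="A")
        lowest = risk.pi.sort_values().index[:20]
        clinical.loc[lowest, "subtype"] = "B"  # stratum with only low-risk
        strata, skipped = G.stratified_survival(clinical, risk.group)
        assert "B" in skipped
        assert [s.stratum for s in strata] == ["A"]


class TestMultivariateIndependence:
    def test_planted_risk_only_significant_covariate(self):
        wins = 0
        for seed in range(10):
            clinical, risk = _planted_risk(250, 3.0, seed=700 + seed)
            rep = G.multivariate_independence(clinical, risk.group)
            if (rep.joint["high_risk"].p_wald < 0.05
                    and rep.joint["age"].p_wald >= 0.05
                    and rep.joint["mgmt_unmethylated"].p_wald >= 0.05):
                wins += 1
        assert wins >= 6

    def test_joint_model_reports_all_three_variables(self):
        clinical, risk = _planted_risk(200, 2.0, seed=41)
        rep = G.multivariate_independence(clinical, risk.group)
        assert set(rep.joint) == {"high_risk", "age", "mgmt_unmethylated"}
        assert set(rep.univariate) == set(rep.joint)
        assert rep.n_events <= rep.n

    def test_duplicated_covariate_collinearity_error(self):
        clinical, risk = _planted_risk(150, 2.0, seed=51)
        clinical = clinical.copy()
        clinical["mgmt_methylated"] = (clinical["age"] > clinical["age"]
                                       .median()).astype(int)
        clinical["age"] = clinical["mgmt_methylated"] * 10.0  # collinear pair
        with pytest.raises(ArithmeticError):
            G.multivariate_independence(clinical, risk.group)

    def test_degenerate_complete_cases_rejected(self):
        clinical, risk = _planted_risk(150, 2.0, seed=61)
        clinical = clinical.copy()
        clinical["age"] = np.nan
        with pytest.raises(G.CoxFitError):
            G.multivariate_independence(clinical, risk.group)


def test_compare_risk_groups_summary_fields():
    clinical, risk = _planted_risk(200, 3.0, seed=71)
    cmp = G.compare_risk_groups(clinical, risk.group, "os_days", "os_event")
    assert cmp["median_high"] <= cmp["median_low"]
    assert cmp["log_rank"].p < 0.05
    assert cmp["hazard_ratio"].hr > 1.0
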