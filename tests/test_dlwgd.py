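"""Tests for the duplication-loss + WGD count model and its MCMC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wgdsig as w
from wgdsig.dlwgd import (
    DlWgdLikelihood,
    RateModel,
    TruncationError,
    bd_transition_matrix,
    bd_transition_probability,
    filter_families,
    poisson_outlier_rule,
    prior_logdensity,
    run_mcmc,
    summarize_wgd_support,
    wgd_retention_matrix,
)
from wgdsig.speciestree import DatedSpeciesTree

from oracles import bd_expm_matrix, enumeration_family_loglik


class TestBdKernel:
    def test_pure_death_closed_form(self):
        mu, t = 0.002, 100.0
        assert bd_transition_probability(1, 0, 0.0, mu, t) == pytest.approx(
            1 - np.exp(-mu * t), abs=1e-14
        )

    def test_critical_case_closed_form(self):
        rho, t = 0.002, 100.0
        assert bd_transition_probability(1, 0, rho, rho, t) == pytest.approx(
            rho * t / (1 + rho * t), abs=1e-12
        )

    def test_pure_birth_geometric(self):
        lam, t = 0.003, 200.0
        p = np.exp(-lam * t)
        for m in (1, 2, 5):
            assert bd_transition_probability(1, m, lam, 0.0, t) == pytest.approx(
                p * (1 - p) ** (m - 1), rel=1e-12
            )

    def test_against_matrix_exponential_oracle(self):
        for lam, mu in [(0.001, 0.002), (0.002, 0.002), (0.005, 0.0)]:
            P = bd_expm_matrix(lam, mu, 100.0, K=200)
            for n, m in itertools.product((0, 1, 2, 5, 10), repeat=2):
                assert bd_transition_probability(n, m, lam, mu, 100.0) == pytest.approx(
                    P[n, m], abs=1e-10
                )

    def test_matrix_rows_consistent_with_scalar(self):
        P = bd_transition_matrix(15, 0.002, 0.001, 80.0)
        for n in (0, 3, 7):
            for m in (0, 5, 15):
                assert P[n, m] == pytest.approx(
                    bd_transition_probability(n, m, 0.002, 0.001, 80.0), abs=1e-12
                )
        assert (P[:8].sum(axis=1) > 1 - 1e-4).all()
        assert (P[:4].sum(axis=1) > 1 - 1e-9).all()

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            bd_transition_probability(-1, 0, 0.001, 0.001, 10)
        with pytest.raises(ValueError):
            bd_transition_probability(1, 0, 0.001, 0.001, -10)


def test_wgd_retention_matrix_binomial_rows():
    W = wgd_retention_matrix(10, 0.3)
    assert W[2, 2] == pytest.approx(0.49)
    assert W[2, 3] == pytest.approx(2 * 0.3 * 0.7)
    assert W[2, 4] == pytest.approx(0.09)
    assert W[0, 0] == 1.0
    W0 = wgd_retention_matrix(10, 0.0)
    assert np.allclose(W0, np.eye(11))


class TestFamilyLikelihood:
    def test_matches_enumeration_on_two_and_three_leaf_trees(
        self, two_leaf_tree, three_leaf_tree
    ):
        eta = 0.7
        for tree in (two_leaf_tree, three_leaf_tree):
            labels = tree.leaf_labels
            model = RateModel("constant", 0.002, 0.001, eta)
            for combo in itertools.product(range(3), repeat=len(labels)):
                if sum(combo) == 0:
                    continue
                counts = pd.Series(dict(zip(labels, combo)))
                ll = w.family_loglikelihood(counts, tree, model, bound=40)
                ref = enumeration_family_loglik(tree, dict(zip(labels, combo)),
                                                0.002, 0.001, eta)
                if np.isfinite(ll) and np.isfinite(ref):
                    assert ll == pytest.approx(ref, abs=1e-8)
                else:
                    assert np.isfinite(ll) == np.isfinite(ref)

    def test_q_zero_identical_to_no_wgd(self, three_leaf_tree):
        counts = pd.DataFrame(
            [[1, 2, 1], [0, 1, 3], [2, 2, 2]], columns=three_leaf_tree.leaf_labels
        )
        wgd = w.WgdHypothesis(branch="i", age=10.0, q=0.0, name="h")
        plain = DlWgdLikelihood(counts, three_leaf_tree).loglik(
            RateModel("constant", 0.002, 0.001, 0.8)
        )
        with_wgd = DlWgdLikelihood(counts, three_leaf_tree, wgds=[wgd]).loglik(
            RateModel("constant", 0.002, 0.001, 0.8, q={"h": 0.0})
        )
        assert with_wgd == pytest.approx(plain, abs=1e-10)

    def test_zero_branch_lengths_reduce_to_root_prior(self):
        tree = DatedSpeciesTree.from_newick("(A:0,B:0);")
        eta = 0.6
        model = RateModel("constant", 0.002, 0.002, eta)
        for c in (1, 2, 4):
            counts = pd.Series({"A": c, "B": c})
            ll = w.family_loglikelihood(counts, tree, model, bound=30)
            # geometric mass renormalized by the conditioning event (n >= 1)
            assert ll == pytest.approx(np.log(eta * (1 - eta) ** (c - 1)), abs=1e-10)
        # unequal counts are impossible without evolution
        ll = w.family_loglikelihood(pd.Series({"A": 1, "B": 2}), tree, model, bound=30)
        assert ll == -np.inf

    def test_additive_over_families_and_label_invariant(self, three_leaf_tree):
        counts = pd.DataFrame(
            [[1, 0, 2], [3, 1, 1], [0, 2, 1]],
            columns=three_leaf_tree.leaf_labels,
            index=["f1", "f2", "f3"],
        )
        model = RateModel("constant", 0.003, 0.002, 0.8)
        like = DlWgdLikelihood(counts, three_leaf_tree)
        per_fam = like.loglik_per_family(model)
        assert like.loglik(model) == pytest.approx(per_fam.sum())
        shuffled = counts.iloc[[2, 0, 1]]
        assert DlWgdLikelihood(shuffled, three_leaf_tree).loglik(model) == pytest.approx(
            like.loglik(model)
        )

    def test_truncation_self_consistency(self, three_leaf_tree):
        counts = pd.DataFrame([[2, 3, 1]], columns=three_leaf_tree.leaf_labels)
        model = RateModel("constant", 0.002, 0.001, 0.8)
        ll1 = DlWgdLikelihood(counts, three_leaf_tree, bound=30).loglik(model)
        ll2 = DlWgdLikelihood(counts, three_leaf_tree, bound=60).loglik(model)
        assert abs(ll1 - ll2) < 1e-6

    def test_leak_detection_raises_loudly(self, three_leaf_tree):
        counts = pd.DataFrame([[2, 3, 1]], columns=three_leaf_tree.leaf_labels)
        like = DlWgdLikelihood(counts, three_leaf_tree, bound=7)
        with pytest.raises(TruncationError, match="leak"):
            like.loglik(RateModel("constant", 0.05, 0.04, 0.8))

    def test_bound_below_twice_max_rejected(self, two_leaf_tree):
        counts = pd.DataFrame([[4, 4]], columns=two_leaf_tree.leaf_labels)
        with pytest.raises(ValueError, match="bound"):
            DlWgdLikelihood(counts, two_leaf_tree, bound=6)


class TestFilters:
    def test_poisson_outlier_worked_example(self):
        # X = {1, 4, 9, 25} -> Y = {2, 4, 6, 10}, median 5, threshold 8,
        # so exactly the X = 25 family is an outlier
        mask, median_y, threshold = poisson_outlier_rule([1, 4, 9, 25])
        assert median_y == pytest.approx(5.0)
        assert threshold == pytest.approx(8.0)
        assert list(mask) == [False, False, False, True]

    def test_filters_applied_in_order(self, two_leaf_tree):
        counts = pd.DataFrame(
            {"A": [1, 2, 4, 13], "B": [0, 2, 5, 12]},
            index=["f1", "f2", "f3", "f4"],
        )
        filtered, report = filter_families(counts, two_leaf_tree)
        assert report.table.loc["f1", "reason"] == "root_clade"  # absent from B
        # median(Y) over survivors {4, 9, 25}: threshold 9, so f4 (Y=10) goes
        assert report.threshold == pytest.approx(9.0)
        assert report.table.loc["f4", "reason"] == "poisson_outlier"
        assert list(filtered.index) == ["f2", "f3"]

    def test_single_clade_family_removed(self, three_leaf_tree):
        counts = pd.DataFrame(
            {"A": [2, 1], "B": [3, 1], "C": [0, 1]}, index=["f1", "f2"]
        )
        filtered, report = filter_families(counts, three_leaf_tree)
        assert report.table.loc["f1", "reason"] == "root_clade"
        assert list(filtered.index) == ["f2"]

    def test_identical_sizes_none_removed_by_outlier_rule(self, two_leaf_tree):
        counts = pd.DataFrame({"A": [2, 2, 2], "B": [1, 1, 1]})
        filtered, report = filter_families(counts, two_leaf_tree)
        assert len(filtered) == 3
        assert not (report.table.reason == "poisson_outlier").any()


class TestPriors:
    def test_constant_prior_at_exponential_mean(self):
        model = RateModel("constant", 0.005, 0.005, 10 / 12)
        lp = prior_logdensity(model)
        expected = (
            2 * (np.log(1 / 0.005) - 1.0)
            + stats.beta.logpdf(10 / 12, 10, 2)
        )
        assert lp == pytest.approx(expected)

    def test_out_of_support_is_minus_inf(self):
        assert prior_logdensity(RateModel("constant", 0.005, 0.005, 0.8,
                                          q={"x": 1.2})) == -np.inf
        assert prior_logdensity(RateModel("constant", -0.1, 0.005, 0.8)) == -np.inf
        assert prior_logdensity(RateModel("constant", 0.005, 0.005, 1.5)) == -np.inf

    def test_independent_rates_density_matches_lognormal(self, two_leaf_tree):
        m, s2 = 0.002, 0.3
        lam = {"A": 0.001, "B": 0.004}
        mu = {"A": 0.002, "B": 0.002}
        model = RateModel("independent_rates", lam, mu, 0.8,
                          hyper={"mean_lambda": m, "mean_mu": m, "sigma2": s2})
        lp = prior_logdensity(model, two_leaf_tree)
        expected = (
            2 * (np.log(1 / 0.5) - m / 0.5)
            + stats.invgamma.logpdf(s2, 5, scale=1.0)
            + stats.beta.logpdf(0.8, 10, 2)
            + sum(
                stats.norm.logpdf(np.log(v), np.log(m), np.sqrt(s2))
                for v in [*lam.values(), *mu.values()]
            )
        )
        assert lp == pytest.approx(expected)

    def test_gbm_prior_drift_corrected(self, three_leaf_tree):
        # rates equal to the hyper mean: each increment evaluated at its drift
        m, nu = 0.002, 0.1
        branches = [three_leaf_tree.label[i] for i in range(three_leaf_tree.n_nodes)
                    if i != three_leaf_tree.root]
        lam = {b: m for b in branches}
        model = RateModel("gbm", lam, dict(lam), 0.8,
                          hyper={"mean_lambda": m, "mean_mu": m, "nu": nu})
        lp = prior_logdensity(model, three_leaf_tree)
        expected = 2 * (np.log(1 / 0.5) - m / 0.5) + stats.beta.logpdf(0.8, 10, 2)
        for b in branches:
            node = three_leaf_tree.node_by_label(b)
            t = three_leaf_tree.length[node]
            var = nu**2 * t
            expected += 2 * stats.norm.logpdf(0.0, -var / 2, np.sqrt(var))
        assert lp == pytest.approx(expected)


class TestMcmcAndSupport:
    def test_prior_only_recovers_beta_eta_and_uniform_q(self, three_leaf_tree):
        counts = pd.DataFrame(columns=three_leaf_tree.leaf_labels)
        wgd = w.WgdHypothesis(branch="i", age=10.0, q=0.0, name="h")
        summary, trace = run_mcmc(
            counts, three_leaf_tree, wgds=[wgd], structure="constant",
            chain_length=4000, burn_in=500, seed=5,
        )
        assert summary.means["eta"] == pytest.approx(10 / 12, abs=0.03)
        assert summary.means["q_h"] == pytest.approx(0.5, abs=0.05)
        assert summary.means["lambda"] == pytest.approx(0.005, rel=0.25)

    @pytest.mark.parametrize("structure", ["independent_rates", "gbm"])
    def test_branchwise_structures_run_and_stay_near_truth(
        self, structure, three_leaf_tree
    ):
        fs = w.simulate_family_counts(
            three_leaf_tree, (0.002, 0.002), root_prior_eta=0.8,
            n_families=150, seed=9,
        )
        filtered, _ = filter_families(fs.counts, three_leaf_tree)
        summary, trace = run_mcmc(
            filtered, three_leaf_tree, structure=structure,
            chain_length=250, burn_in=100, seed=10, tie_root_branches=True,
        )
        # tied root branches share one parameter
        assert "lambda_i" in summary.means
        branch_cols = [c for c in trace.columns if c.startswith("lambda_")]
        # all branch-rate posteriors stay within an order of magnitude of truth
        for c in branch_cols:
            assert 1e-4 < summary.means[c] < 0.05
        assert np.isfinite(trace["logpost"]).all()

    def test_pilot_chains_feed_rhat(self, three_leaf_tree):
        fs = w.simulate_family_counts(
            three_leaf_tree, (0.002, 0.002), root_prior_eta=0.8,
            n_families=80, seed=11,
        )
        filtered, _ = filter_families(fs.counts, three_leaf_tree)
        summary, _ = run_mcmc(
            filtered, three_leaf_tree, structure="constant",
            chain_length=150, burn_in=50, n_pilot_chains=2, pilot_subset=40,
            seed=12,
        )
        assert np.isfinite(summary.rhat["lambda"])

    def test_support_verdicts(self):
        rng = np.random.default_rng(0)
        trace = pd.DataFrame({"q_a": rng.uniform(0.25, 0.35, 2000),
                              "q_b": rng.uniform(0.0, 0.004, 2000)})
        out = summarize_wgd_support(trace)
        assert out["a"]["supported"] and not out["b"]["supported"]

    def test_bimodal_trace_warns_and_pools(self, caplog):
        rng = np.random.default_rng(1)
        q = np.concatenate([rng.uniform(0, 0.003, 700), rng.normal(0.3, 0.02, 1300)])
        import logging

        with caplog.at_level(logging.WARNING, logger="wgdsig.dlwgd"):
            out = summarize_wgd_support(pd.DataFrame({"q_x": q}))
        assert out["x"]["multimodal_warning"]
        assert out["x"]["lower"] < 0.01  # pooled interval reaches the zero mode
        assert any("multimodal" in r.message for r in caplog.records)

    def test_missing_q_rejected(self):
        with pytest.raises(ValueError, match="q"):
            summarize_wgd_support(pd.DataFrame({"lambda": [0.1, 0.2]}))
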