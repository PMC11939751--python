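"""Posterior model and MAP search: closed forms, oracles, determinism."""
import numpy as np
import pandas as pd
import pytest

from brskit.brs_inference import (
    ChainConfig,
    LikelihoodParams,
    PriorParams,
    RuleSet,
    enumerate_map,
    fit,
    log_likelihood,
    log_posterior,
    log_prior,
    pool_scaled_prior,
    predict,
)
from brskit.data_prep import prepare
from brskit.rule_mining import MiningConfig, Rule, mine_candidates, rule_cover
from brskit.synthetic_data import generate_survey

from conftest import random_binary_features


def _rule(*lits):
    return Rule(literals=frozenset(lits))


class TestPredict:
    def test_empty_ruleset_predicts_all_zero(self, binary_fixture):
        assert predict(RuleSet(), binary_fixture).sum() == 0

    def test_or_of_two_rules_fires_when_either_holds(self):
        # one conjunction rule plus one single-condition rule: meeting only
        # the single condition still predicts positive
        f = pd.DataFrame({"age_high": [0], "hours_low": [0], "salary_high": [1]})
        rs = RuleSet(frozenset({_rule("age_high", "hours_low"), _rule("salary_high")}))
        assert predict(rs, f).tolist() == [1]

    def test_prediction_equals_elementwise_or_oracle(self, rng, binary_fixture):
        rules = [_rule("f0_high", "f1_high"), _rule("NOT_f2_high"), _rule("f3_high")]
        rs = RuleSet(frozenset(rules))
        oracle = np.zeros(len(binary_fixture), dtype=np.uint8)
        for r in rules:
            oracle |= rule_cover(r, binary_fixture)
        np.testing.assert_array_equal(predict(rs, binary_fixture), oracle)


class TestLogPrior:
    def test_empty_set_equals_minus_lambda(self):
        assert log_prior(RuleSet(), PriorParams(lambda_rules=3.0)) == pytest.approx(-3.0)

    def test_decreasing_beyond_the_poisson_mean(self):
        prior = PriorParams(lambda_rules=1.0)
        sets = [
            RuleSet(frozenset({_rule("a_high")})),
            RuleSet(frozenset({_rule("a_high"), _rule("b_high")})),
            RuleSet(frozenset({_rule("a_high"), _rule("b_high"), _rule("c_high")})),
        ]
        scores = [log_prior(s, prior) for s in sets]
        assert scores[0] > scores[1] > scores[2]

    def test_same_size_same_length_profile_scores_equal(self):
        prior = PriorParams()
        a = RuleSet(frozenset({_rule("a_high", "b_high"), _rule("c_high")}))
        b = RuleSet(frozenset({_rule("x_high", "y_high"), _rule("z_high")}))
        assert log_prior(a, prior) == pytest.approx(log_prior(b, prior))

    def test_pool_scaled_prior_charges_log_pool_per_rule(self):
        prior = pool_scaled_prior(5000, expected_rules=3.0)
        one = log_prior(RuleSet(frozenset({_rule("a_high")})), prior)
        two = log_prior(RuleSet(frozenset({_rule("a_high"), _rule("b_high")})), prior)
        # extra-rule cost: log(pool/expected) + Poisson count term + the
        # uniform length weight of the added one-literal rule
        assert one - two == pytest.approx(
            np.log(5000 / 3.0) + np.log(2) - np.log(1 / 3)
        )


class TestLogLikelihood:
    def test_perfect_separation_beats_single_bit_corruptions(self):
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 1], dtype=np.uint8)
        cols = {"truth_high": labels.copy(), "NOT_truth_high": 1 - labels}
        for i in range(10):  # corrupted copies of the perfect predictor
            c = labels.copy()
            c[i] ^= 1
            cols[f"c{i}_high"] = c
        f = pd.DataFrame(cols)
        perfect = log_likelihood(RuleSet(frozenset({_rule("truth_high")})), f, labels)
        for i in range(10):
            corrupted = log_likelihood(
                RuleSet(frozenset({_rule(f"c{i}_high")})), f, labels
            )
            assert perfect > corrupted

    def test_empty_set_depends_only_on_label_counts(self, binary_fixture, rng):
        labels = rng.integers(0, 2, len(binary_fixture)).astype(np.uint8)
        a = log_likelihood(RuleSet(), binary_fixture, labels)
        perm = rng.permutation(len(labels))
        b = log_likelihood(
            RuleSet(), binary_fixture.iloc[perm].reset_index(drop=True), labels[perm]
        )
        assert a == pytest.approx(b)

    def test_row_swap_leaves_likelihood_unchanged(self, binary_fixture, rng):
        labels = rng.integers(0, 2, len(binary_fixture)).astype(np.uint8)
        rs = RuleSet(frozenset({_rule("f0_high", "f1_high")}))
        a = log_likelihood(rs, binary_fixture, labels)
        perm = rng.permutation(len(labels))
        b = log_likelihood(
            rs, binary_fixture.iloc[perm].reset_index(drop=True), labels[perm]
        )
        assert a == pytest.approx(b)

    def test_non_binary_labels_rejected(self, binary_fixture):
        with pytest.raises(ValueError, match="binary"):
            log_likelihood(RuleSet(), binary_fixture, np.full(len(binary_fixture), 2))


class TestPosterior:
    def test_exhaustive_enumeration_on_small_pools(self, rng):
        """fit's MAP matches the 2^4-subset argmax on 50-row fixtures."""
        matches = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            features = random_binary_features(r, n=50, k=4)
            labels = (
                features["f0_high"].to_numpy()
                & (r.random(50) < 0.9)
            ).astype(np.uint8)
            pool = [_rule("f0_high"), _rule("f1_high"),
                    _rule("f0_high", "f2_high"), _rule("NOT_f3_high")]
            best, best_score = enumerate_map(pool, features, labels)
            res = fit(features, labels, pool,
                      chains=ChainConfig(n_chains=2, n_iters=200, seed=seed))
            if (res.map_ruleset.literal_sets() == best.literal_sets()
                    or res.map_score == pytest.approx(best_score, abs=1e-9)):
                matches += 1
        assert matches >= 4

    def test_planted_posterior_dominates_empty_on_noiseless_data(self, small_sim):
        table, truth = generate_survey(small_sim)
        _, m = prepare(table)
        planted = RuleSet(frozenset(
            Rule(literals=frozenset(r)) for r in truth["planted_rules"]
        ))
        assert (log_posterior(planted, m.features, m.outcome)
                >= log_posterior(RuleSet(), m.features, m.outcome))


class TestFit:
    def test_noiseless_planted_rules_are_the_map(self, small_sim):
        table, truth = generate_survey(small_sim)
        _, m = prepare(table)
        pool = mine_candidates(m.features, m.outcome, MiningConfig())
        res = fit(m.features, m.outcome, pool, prior=pool_scaled_prior(len(pool)),
                  chains=ChainConfig(n_chains=2, n_iters=800, seed=3))
        assert res.map_ruleset.literal_sets() == {
            frozenset(r) for r in truth["planted_rules"]
        }

    def test_same_seed_reproduces_the_result_exactly(self, small_sim):
        table, _ = generate_survey(small_sim)
        _, m = prepare(table)
        pool = mine_candidates(m.features, m.outcome, MiningConfig())
        cc = ChainConfig(n_chains=2, n_iters=300, seed=9)
        a = fit(m.features, m.outcome, pool, chains=cc)
        b = fit(m.features, m.outcome, pool, chains=cc)
        assert a.map_ruleset == b.map_ruleset
        assert a.map_score == b.map_score
        assert a.chain_best_scores == b.chain_best_scores
        assert a.chain_acceptance_rates == b.chain_acceptance_rates

    def test_map_score_bounds(self, small_sim):
        table, _ = generate_survey(small_sim)
        _, m = prepare(table)
        pool = mine_candidates(m.features, m.outcome, MiningConfig())
        prior = pool_scaled_prior(len(pool))
        res = fit(m.features, m.outcome, pool, prior=prior,
                  chains=ChainConfig(n_chains=2, n_iters=300, seed=4))
        assert res.map_score >= max(res.chain_best_scores) - 1e-9
        assert res.map_score >= log_posterior(RuleSet(), m.features, m.outcome, prior)

    def test_empty_pool_is_fatal_with_guidance(self, binary_fixture):
        labels = np.zeros(len(binary_fixture), dtype=np.uint8)
        with pytest.raises(ValueError, match="min_support"):
            fit(binary_fixture, labels, [])
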