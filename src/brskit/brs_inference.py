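"""Bayesian rule set model: prior, likelihood, posterior, MAP search.

The model scores a candidate rule set A (an OR of AND-rules) by the
unnormalized posterior

    p(A | S)  ∝  π(A) · p(S | A)

where the prior π(A) is Poisson on the number of rules (penalizing large
sets) times a categorical weight on each rule's length (penalizing long
rules), and the likelihood p(S | A) is a Beta-Binomial marginal over the two
strata the rule set induces: rows it covers (predicted positive) and rows it
leaves uncovered (predicted negative).  With covered-stratum pseudo-counts
(α+, β+) and uncovered-stratum pseudo-counts (α−, β−),

    log p(S|A) = log B(TP+α+, FP+β+) − log B(α+, β+)
               + log B(TN+α−, FN+β−) − log B(α−, β−)

so the data enter only through the confusion counts.  Large α+ and β−
express a strong prior belief that covered rows are positive and uncovered
rows negative, i.e. that a good rule set is both precise and complete.

The MAP rule set is found by multi-chain simulated annealing over subsets of
the mined pool, with add / remove / replace moves.  Proposals are guided:
add moves prefer rules covering a currently false-negative row and remove
moves prefer rules covering a false positive, which is what makes the search
practical on pools of thousands of rules.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

from .rule_mining import Rule, rule_cover


@dataclass(frozen=True)
class RuleSet:
    rules: frozenset[Rule] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", frozenset(self.rules))

    def __len__(self) -> int:
        return len(self.rules)

    def literal_sets(self) -> set[frozenset[str]]:
        return {r.literals for r in self.rules}

    def describe(self) -> str:
        return " | ".join(sorted(f"({r.describe()})" for r in self.rules)) or "(empty)"


@dataclass(frozen=True)
class PriorParams:
    """Poisson mean on rule count + probability over rule lengths 1..L."""

    lambda_rules: float = 3.0
    length_weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if self.lambda_rules <= 0:
            raise ValueError("lambda_rules must be > 0")
        if abs(sum(self.length_weights) - 1.0) > 1e-8 or min(self.length_weights) < 0:
            raise ValueError("length_weights must be a probability vector")


@dataclass(frozen=True)
class LikelihoodParams:
    """Beta pseudo-counts for the covered (+) and uncovered (−) strata."""

    alpha_pos: float = 100.0
    beta_pos: float = 1.0
    alpha_neg: float = 1.0
    beta_neg: float = 100.0

    def __post_init__(self) -> None:
        if min(self.alpha_pos, self.beta_pos, self.alpha_neg, self.beta_neg) <= 0:
            raise ValueError("all pseudo-counts must be > 0")


@dataclass(frozen=True)
class ChainConfig:
    n_chains: int = 10
    n_iters: int = 10_000
    seed: int = 0
    temp_start: float = 1.0
    temp_end: float = 0.01
    move_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)  # add, remove, replace
    guided_prob: float = 0.8
    # exponent biasing guided adds toward precise rules; 0 = uniform
    precision_power: float = 2.0
    # deterministic local improvement (best single add/remove/swap) from the
    # annealed optimum until no move improves the posterior
    polish: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iters < 1:
            raise ValueError("n_chains and n_iters must be >= 1")
        if abs(sum(self.move_probs) - 1.0) > 1e-8:
            raise ValueError("move probabilities must sum to 1")


@dataclass
class FitResult:
    map_ruleset: RuleSet
    map_score: float
    chain_best_scores: list[float]
    chain_acceptance_rates: list[float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "map_rules": [sorted(r.literals) for r in self.map_ruleset.rules],
            "map_score": self.map_score,
            "chain_best_scores": self.chain_best_scores,
            "chain_acceptance_rates": self.chain_acceptance_rates,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        d = json.loads(Path(path).read_text())
        rs = RuleSet(frozenset(Rule(literals=frozenset(ls)) for ls in d["map_rules"]))
        return cls(rs, d["map_score"], d["chain_best_scores"],
                   d["chain_acceptance_rates"], d["seed"])


def pool_scaled_prior(
    pool_size: int,
    expected_rules: float = 3.0,
    length_weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3),
) -> PriorParams:
    """Poisson prior whose mean prices rule *selection* from the pool.

    A count-only Poisson with mean ~3 makes an extra rule nearly free
    (log 3 − log k!), yet choosing one specific conjunction out of a pool of
    thousands should cost ≈ log(pool size).  Setting the Poisson mean to
    ``expected_rules / pool_size`` folds that selection cost into the
    count prior: each additional rule then pays ≈ log(pool_size /
    expected_rules), which is what keeps noise-chasing rules out of the MAP
    set while leaving genuinely predictive rules (whose likelihood gain is
    far larger) untouched.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    return PriorParams(
        lambda_rules=expected_rules / pool_size, length_weights=length_weights
    )


# ---------------------------------------------------------------------------
# Scoring


def predict(ruleset: RuleSet, features: pd.DataFrame) -> np.ndarray:
    """OR-of-ANDs prediction: 1 iff any rule covers the row."""
    out = np.zeros(len(features), dtype=np.uint8)
    for rule in ruleset.rules:
        out |= rule_cover(rule, features)
    return out


def log_prior(ruleset: RuleSet, prior: PriorParams = PriorParams()) -> float:
    k = len(ruleset)
    lp = k * np.log(prior.lambda_rules) - prior.lambda_rules - gammaln(k + 1)
    for rule in ruleset.rules:
        if rule.length > len(prior.length_weights):
            return -np.inf
        w = prior.length_weights[rule.length - 1]
        lp += np.log(w) if w > 0 else -np.inf
    return float(lp)


def _loglik_counts(tp, fp, tn, fn, lik: LikelihoodParams) -> float:
    return float(
        betaln(tp + lik.alpha_pos, fp + lik.beta_pos)
        - betaln(lik.alpha_pos, lik.beta_pos)
        + betaln(tn + lik.alpha_neg, fn + lik.beta_neg)
        - betaln(lik.alpha_neg, lik.beta_neg)
    )


def log_likelihood(
    ruleset: RuleSet,
    features: pd.DataFrame,
    labels: np.ndarray,
    lik: LikelihoodParams = LikelihoodParams(),
) -> float:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    pred = predict(ruleset, features)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    return _loglik_counts(tp, fp, tn, fn, lik)


def log_posterior(
    ruleset: RuleSet,
    features: pd.DataFrame,
    labels: np.ndarray,
    prior: PriorParams = PriorParams(),
    lik: LikelihoodParams = LikelihoodParams(),
) -> float:
    return log_prior(ruleset, prior) + log_likelihood(ruleset, features, labels, lik)


def enumerate_map(
    pool: list[Rule],
    features: pd.DataFrame,
    labels: np.ndarray,
    prior: PriorParams = PriorParams(),
    lik: LikelihoodParams = LikelihoodParams(),
) -> tuple[RuleSet, float]:
    """Exhaustive argmax over all 2^|pool| subsets (oracle for small pools)."""
    if len(pool) > 16:
        raise ValueError("exhaustive enumeration is limited to pools of <= 16 rules")
    best, best_score = RuleSet(), -np.inf
    for mask in range(1 << len(pool)):
        rs = RuleSet(frozenset(r for i, r in enumerate(pool) if mask >> i & 1))
        s = log_posterior(rs, features, labels, prior, lik)
        if s > best_score:
            best, best_score = rs, s
    return best, best_score


# ---------------------------------------------------------------------------
# Annealed search


class _ChainState:
    """Incremental confusion-count bookkeeping for one chain."""

    def __init__(self, covers: np.ndarray, labels: np.ndarray,
                 lengths: np.ndarray, prior: PriorParams, lik: LikelihoodParams):
        self.covers = covers  # (M, n) uint8
        self.labels = labels.astype(bool)
        self.lengths = lengths
        self.prior = prior
        self.lik = lik
        self.n_pos = int(self.labels.sum())
        self.n_neg = len(labels) - self.n_pos
        self.members: list[int] = []
        self.member_mask = np.zeros(covers.shape[0], dtype=bool)
        self.count = np.zeros(covers.shape[1], dtype=np.int32)
        self.tp = 0
        self.fp = 0

    def _stratum_delta(self, m: int, adding: bool) -> tuple[int, int]:
        cov = self.covers[m].astype(bool)
        if adding:
            newly = cov & (self.count == 0)
        else:
            newly = cov & (self.count == 1)
        dp = int((newly & self.labels).sum())
        dn = int((newly & ~self.labels).sum())
        return dp, dn

    def add(self, m: int) -> None:
        dp, dn = self._stratum_delta(m, adding=True)
        self.tp += dp
        self.fp += dn
        self.count += self.covers[m]
        self.members.append(m)
        self.member_mask[m] = True

    def remove(self, m: int) -> None:
        self.count -= self.covers[m]
        # rows this rule covered that are now covered by nothing leave the
        # positive-prediction stratum
        cov = self.covers[m].astype(bool)
        left = cov & (self.count == 0)
        self.tp -= int((left & self.labels).sum())
        self.fp -= int((left & ~self.labels).sum())
        self.members.remove(m)
        self.member_mask[m] = False

    def score(self) -> float:
        k = len(self.members)
        lp = (k * np.log(self.prior.lambda_rules) - self.prior.lambda_rules
              - gammaln(k + 1))
        for m in self.members:
            w = self.prior.length_weights[self.lengths[m] - 1]
            lp += np.log(w) if w > 0 else -np.inf
        fn = self.n_pos - self.tp
        tn = self.n_neg - self.fp
        return float(lp) + _loglik_counts(self.tp, self.fp, tn, fn, self.lik)


def _propose_add(
    state: _ChainState, rng, guided: bool, weights: np.ndarray
) -> int | None:
    M = state.covers.shape[0]
    if len(state.members) == M:
        return None
    if guided:
        fn_rows = np.flatnonzero(state.labels & (state.count == 0))
        if len(fn_rows):
            row = rng.choice(fn_rows)
            cands = np.flatnonzero(
                (state.covers[:, row] == 1) & ~state.member_mask
            )
            if len(cands):
                w = weights[cands]
                total = w.sum()
                if total > 0:
                    return int(rng.choice(cands, p=w / total))
                return int(rng.choice(cands))
    return int(rng.choice(np.flatnonzero(~state.member_mask)))


def _propose_remove(state: _ChainState, rng, guided: bool) -> int | None:
    if not state.members:
        return None
    members = np.asarray(state.members, dtype=int)
    if guided:
        fp_rows = np.flatnonzero(~state.labels & (state.count > 0))
        if len(fp_rows):
            row = rng.choice(fp_rows)
            cands = members[state.covers[members, row] == 1]
            if len(cands):
                return int(rng.choice(cands))
    return int(rng.choice(members))


def _polish(state: _ChainState, members: list[int], cur: float) -> tuple[list[int], float]:
    """Greedy best-improvement local search from a candidate state."""
    # rebuild state at `members`
    for m in list(state.members):
        state.remove(m)
    for m in members:
        state.add(m)
    cur = state.score()
    M = state.covers.shape[0]
    improved = True
    while improved:
        improved = False
        best_delta, best_move = 0.0, None
        for m in list(state.members):
            state.remove(m)
            s = state.score()
            if s - cur > best_delta + 1e-12:
                best_delta, best_move = s - cur, ("rm", m, None)
            state.add(m)
        inside = set(state.members)
        for j in range(M):
            if j in inside:
                continue
            state.add(j)
            s = state.score()
            if s - cur > best_delta + 1e-12:
                best_delta, best_move = s - cur, ("add", j, None)
            state.remove(j)
        # single-rule swaps catch substitutions an add or remove alone
        # cannot reach without passing through a worse state
        for m in list(state.members):
            state.remove(m)
            for j in range(M):
                if j == m or j in inside:
                    continue
                state.add(j)
                s = state.score()
                if s - cur > best_delta + 1e-12:
                    best_delta, best_move = s - cur, ("swap", m, j)
                state.remove(j)
            state.add(m)
        if best_move is not None:
            kind, m, j = best_move
            if kind == "add":
                state.add(m)
            elif kind == "rm":
                state.remove(m)
            else:
                state.remove(m)
                state.add(j)
            cur += best_delta
            improved = True
    return list(state.members), state.score()


def fit(
    features: pd.DataFrame,
    labels: np.ndarray,
    pool: list[Rule],
    prior: PriorParams = PriorParams(),
    lik: LikelihoodParams = LikelihoodParams(),
    chains: ChainConfig = ChainConfig(),
) -> FitResult:
    """Multi-chain annealed stochastic search for the MAP rule set.

    Each chain runs ``n_iters`` add/remove/replace moves under a geometric
    temperature schedule from ``temp_start`` to ``temp_end``, accepting a
    move with probability ``exp(Δ log-posterior / T)``.  The best state ever
    visited by any chain is returned; given the seed the result is fully
    reproducible.
    """
    if not pool:
        raise ValueError(
            "empty rule pool: lower min_support or max_len before fitting"
        )
    labels = np.asarray(labels, dtype=np.uint8)
    col_idx = {name: i for i, name in enumerate(features.columns)}
    X = features.to_numpy(dtype=np.uint8)
    covers = np.empty((len(pool), len(features)), dtype=np.uint8)
    for k, r in enumerate(pool):
        try:
            idx = [col_idx[lit] for lit in r.key]
        except KeyError as e:
            raise KeyError(f"unknown literal {e.args[0]!r}") from None
        covers[k] = X[:, idx].min(axis=1)
    lengths = np.asarray([r.length for r in pool], dtype=int)
    support = covers.sum(axis=1).astype(float)
    tp_counts = (covers @ labels).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(support > 0, tp_counts / support, 0.0)
    add_weights = precision ** chains.precision_power
    ss = np.random.SeedSequence(chains.seed)
    child_seeds = ss.spawn(chains.n_chains)

    temps = chains.temp_start * (chains.temp_end / chains.temp_start) ** (
        np.arange(chains.n_iters) / max(chains.n_iters - 1, 1)
    )

    best_overall: list[int] = []
    best_score_overall = -np.inf
    best_chain = 0
    chain_bests, chain_acc = [], []
    for c in range(chains.n_chains):
        rng = np.random.default_rng(child_seeds[c])
        state = _ChainState(covers, labels, lengths, prior, lik)
        cur = state.score()
        best, best_members = cur, []
        accepted = 0
        for t in range(chains.n_iters):
            u = rng.random()
            p_add, p_rem, _ = chains.move_probs
            guided = rng.random() < chains.guided_prob
            if u < p_add:
                m = _propose_add(state, rng, guided, add_weights)
                if m is None:
                    continue
                state.add(m)
                new = state.score()
                if new >= cur or rng.random() < np.exp((new - cur) / temps[t]):
                    cur = new
                    accepted += 1
                else:
                    state.remove(m)
            elif u < p_add + p_rem:
                m = _propose_remove(state, rng, guided)
                if m is None:
                    continue
                state.remove(m)
                new = state.score()
                if new >= cur or rng.random() < np.exp((new - cur) / temps[t]):
                    cur = new
                    accepted += 1
                else:
                    state.add(m)
            else:
                m_out = _propose_remove(state, rng, guided)
                if m_out is None:
                    continue
                state.remove(m_out)
                m_in = _propose_add(state, rng, guided, add_weights)
                if m_in is None:
                    state.add(m_out)
                    continue
                state.add(m_in)
                new = state.score()
                if new >= cur or rng.random() < np.exp((new - cur) / temps[t]):
                    cur = new
                    accepted += 1
                else:
                    state.remove(m_in)
                    state.add(m_out)
            if cur > best:
                best, best_members = cur, list(state.members)
        chain_bests.append(best)
        chain_acc.append(accepted / chains.n_iters)
        if best > best_score_overall:
            best_score_overall, best_overall = best, best_members
            best_chain = len(chain_bests) - 1
    if chains.polish and best_score_overall > -np.inf:
        state = _ChainState(covers, labels, lengths, prior, lik)
        best_overall, best_score_overall = _polish(state, best_overall, best_score_overall)
        chain_bests[best_chain] = max(chain_bests[best_chain], best_score_overall)
    ruleset = RuleSet(frozenset(pool[m] for m in best_overall))
    return FitResult(
        map_ruleset=ruleset,
        map_score=float(best_score_overall),
        chain_best_scores=[float(b) for b in chain_bests],
        chain_acceptance_rates=[float(a) for a in chain_acc],
        seed=chains.seed,
    )
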