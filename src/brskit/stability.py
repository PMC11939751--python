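"""Bootstrap stability of rules: prevalence, signed coverage, aggregation.

The MAP rule set from a single fit is a point estimate; resampling the rows
with replacement and refitting shows which rules are stable.  For each rule
ever selected, *prevalence* is the fraction of resamples whose MAP set
contains it (exact literal-set identity), and *coverage* is decomposed into
covered true positives (reported positively) and covered false positives
(reported negatively), evaluated on the resample that produced the rule.
The aggregated rule set keeps every rule whose prevalence reaches the
threshold (default 5%: at least 5 appearances in 100 resamples).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .brs_inference import (
    ChainConfig,
    LikelihoodParams,
    PriorParams,
    RuleSet,
    fit,
    pool_scaled_prior,
    predict,
)
from .data_prep import feature_variable
from .rule_mining import MiningConfig, Rule, mine_candidates, rule_cover


@dataclass
class RuleStability:
    rule: Rule
    prevalence: float
    tp_coverage: float       # mean covered true positives (in-bag)
    fp_coverage: float       # mean covered false positives, reported negative
    ci_low: float            # 2.5th percentile of signed coverage
    ci_high: float           # 97.5th percentile of signed coverage

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must be <= ci_high")


@dataclass
class StabilityReport:
    records: list[RuleStability]
    aggregated: RuleSet
    B: int
    seed: int
    prevalence_threshold: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "literals": r.rule.describe(),
                "prevalence": r.prevalence,
                "tp_coverage": r.tp_coverage,
                "fp_coverage_signed": -r.fp_coverage,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "aggregated": r.rule in self.aggregated.rules,
            }
            for r in sorted(self.records, key=lambda x: -x.prevalence)
        ]
        return pd.DataFrame(rows, columns=[
            "literals", "prevalence", "tp_coverage", "fp_coverage_signed",
            "ci_low", "ci_high", "aggregated",
        ])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "B": self.B,
            "seed": self.seed,
            "prevalence_threshold": self.prevalence_threshold,
            "aggregated": [sorted(r.literals) for r in self.aggregated.rules],
            "rules": [
                {
                    "literals": sorted(r.rule.literals),
                    "prevalence": r.prevalence,
                    "tp_coverage": r.tp_coverage,
                    "fp_coverage": r.fp_coverage,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                }
                for r in self.records
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StabilityReport":
        d = json.loads(Path(path).read_text())
        records = [
            RuleStability(
                rule=Rule(literals=frozenset(r["literals"])),
                prevalence=r["prevalence"],
                tp_coverage=r["tp_coverage"],
                fp_coverage=r["fp_coverage"],
                ci_low=r["ci_low"],
                ci_high=r["ci_high"],
            )
            for r in d["rules"]
        ]
        agg = RuleSet(frozenset(Rule(literals=frozenset(ls)) for ls in d["aggregated"]))
        return cls(records, agg, d["B"], d["seed"], d["prevalence_threshold"])


# ---------------------------------------------------------------------------


def coverage_decomposition(
    rule: Rule, features: pd.DataFrame, labels: np.ndarray
) -> tuple[int, int]:
    """(covered true positives, covered false positives) for one rule."""
    cov = rule_cover(rule, features).astype(bool)
    labels = np.asarray(labels).astype(bool)
    return int((cov & labels).sum()), int((cov & ~labels).sum())


def classification_outcomes(
    ruleset: RuleSet, features: pd.DataFrame, labels: np.ndarray
) -> np.ndarray:
    """Per-row confusion label in {TP, TN, FP, FN} for OR-of-ANDs prediction."""
    pred = predict(ruleset, features).astype(bool)
    truth = np.asarray(labels).astype(bool)
    out = np.empty(len(truth), dtype=object)
    out[pred & truth] = "TP"
    out[pred & ~truth] = "FP"
    out[~pred & truth] = "FN"
    out[~pred & ~truth] = "TN"
    return out.astype(str)


def interaction_edges(report: StabilityReport) -> pd.DataFrame:
    """Variable co-occurrence weights over the aggregated rules (chord input)."""
    weights: dict[tuple[str, str], int] = {}
    for rule in report.aggregated.rules:
        variables = sorted({feature_variable(lit) for lit in rule.literals})
        for a, b in combinations(variables, 2):
            weights[(a, b)] = weights.get((a, b), 0) + 1
    rows = [{"var1": a, "var2": b, "weight": w} for (a, b), w in sorted(weights.items())]
    return pd.DataFrame(rows, columns=["var1", "var2", "weight"])


def bootstrap_stability(
    features: pd.DataFrame,
    labels: np.ndarray,
    mining: MiningConfig = MiningConfig(),
    prior: PriorParams | None = None,
    lik: LikelihoodParams = LikelihoodParams(),
    chains: ChainConfig = ChainConfig(),
    B: int = 100,
    seed: int = 0,
    prevalence_threshold: float = 0.05,
    out_of_bag: bool = False,
) -> StabilityReport:
    """Resample B times with replacement; mine + fit each; summarize rules.

    Coverage of a selected rule is evaluated in-bag (on the resample that
    produced it) by default; ``out_of_bag=True`` evaluates on the rows the
    resample missed instead.  When ``prior`` is None each resample uses the
    pool-scaled Poisson prior (see :func:`pool_scaled_prior`).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    labels = np.asarray(labels, dtype=np.uint8)
    n = len(features)
    rng = np.random.default_rng(seed)
    fit_seeds = np.random.SeedSequence(seed).spawn(B)
    appearances: dict[frozenset[str], int] = {}
    signed: dict[frozenset[str], list[float]] = {}
    tps: dict[frozenset[str], list[float]] = {}
    fps: dict[frozenset[str], list[float]] = {}
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        fb = features.iloc[idx].reset_index(drop=True)
        lb = labels[idx]
        if out_of_bag:
            oob = np.setdiff1d(np.arange(n), np.unique(idx))
            eval_f, eval_l = features.iloc[oob].reset_index(drop=True), labels[oob]
        else:
            eval_f, eval_l = fb, lb
        pool = mine_candidates(fb, lb, mining)
        if not pool:
            continue
        chain_seed = int(fit_seeds[b].generate_state(1)[0] % (2**31))
        res = fit(fb, lb, pool,
                  prior if prior is not None else pool_scaled_prior(len(pool)),
                  lik, ChainConfig(**{**chains.__dict__, "seed": chain_seed}))
        for rule in res.map_ruleset.rules:
            key = rule.literals
            appearances[key] = appearances.get(key, 0) + 1
            tp, fp = coverage_decomposition(rule, eval_f, eval_l)
            signed.setdefault(key, []).append(float(tp - fp))
            tps.setdefault(key, []).append(float(tp))
            fps.setdefault(key, []).append(float(fp))
    records = []
    for key, count in appearances.items():
        cov = np.asarray(signed[key])
        lo, hi = np.percentile(cov, [2.5, 97.5])
        records.append(
            RuleStability(
                rule=Rule(literals=key),
                prevalence=count / B,
                tp_coverage=float(np.mean(tps[key])),
                fp_coverage=float(np.mean(fps[key])),
                ci_low=float(lo),
                ci_high=float(hi),
            )
        )
    kept = frozenset(
        r.rule for r in records if r.prevalence >= prevalence_threshold
    )
    if not records:
        warnings.warn("every resample produced an empty MAP rule set", UserWarning)
    return StabilityReport(
        records=records,
        aggregated=RuleSet(kept),
        B=B,
        seed=seed,
        prevalence_threshold=prevalence_threshold,
    )
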