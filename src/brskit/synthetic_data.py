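"""Synthetic survey generator with planted OR-of-ANDs rule structure.

Generates respondent tables in the original survey codings whose job
satisfaction is driven by configurable planted rules: a respondent whose
(discretized) covariates satisfy any planted rule reports high satisfaction
with probability ``1 - noise_rate``, everyone else with probability
``noise_rate``.  Rules are planted on the same discretized categories the
preparation pipeline mines over (e.g. "work time low" = bottom tercile), so
a recovered rule can be compared literal-for-literal with the planted truth.

Because rule supports under independent marginals can fall below the mining
threshold, each planted rule may declare a ``target_support``: the generator
then forces a matching number of rows into (or out of) rule satisfaction by
resampling the literal variables inside (outside) the required category,
before the final discretization and outcome assignment.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_prep
from .survey import (
    OUTCOME_DEFAULT,
    WORKTIME_DEFAULT,
    SurveyTable,
    VariableSpec,
    default_variable_specs,
)


@dataclass(frozen=True)
class PlantedLiteral:
    variable: str
    category: str  # "low" | "low_or_med" | "med_or_high" | "high" | "1" | "0"
    polarity: bool = True  # False = NOT the category

    @property
    def feature_name(self) -> str:
        base = f"{self.variable}_{self.category}"
        return base if self.polarity else f"NOT_{base}"


@dataclass(frozen=True)
class PlantedRule:
    """Conjunction of up to 3 literals with an optional forced support."""

    literals: tuple[PlantedLiteral, ...]
    target_support: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.literals) <= 3:
            raise ValueError("planted rules carry 1-3 literals")
        if self.target_support is not None and not 0.0 < self.target_support < 1.0:
            raise ValueError("target_support must be in (0, 1)")

    @property
    def feature_names(self) -> frozenset[str]:
        return frozenset(l.feature_name for l in self.literals)

    def describe(self) -> str:
        return " & ".join(sorted(l.feature_name for l in self.literals))


def planted_rule(*specs: tuple[str, str], target_support: float | None = None) -> PlantedRule:
    """Convenience constructor: ``planted_rule(("workt", "low"), ...)``."""
    return PlantedRule(
        literals=tuple(PlantedLiteral(v, c) for v, c in specs),
        target_support=target_support,
    )


@dataclass
class SimulationConfig:
    n: int = 1000
    seed: int = 0
    variables: dict[str, VariableSpec] = field(default_factory=default_variable_specs)
    planted_rules: tuple[PlantedRule, ...] = ()
    noise_rate: float = 0.0
    missing_rates: dict[str, float] = field(default_factory=dict)
    outlier_rate: float = 0.0
    outcome_name: str = OUTCOME_DEFAULT
    # aligned-scale distribution of the outcome for rule-negative respondents;
    # positives report the top level.  The distribution is concentrated just
    # under the neutral midpoint so that mean + 1 SD stays at or above the
    # highest negative level for any positive rate from 0 to ~0.45, and the
    # pipeline's mean+1SD split reproduces the planted labels exactly.
    negative_outcome_probs: tuple[float, ...] = (0.05, 0.30, 0.65)
    # for each literal of a support-forced rule, additionally plant
    # contrast_fraction * target_support "near-miss" rows satisfying every
    # OTHER literal but not this one.  Without them a literal that is
    # marginally almost always true (e.g. medium-or-high health) would be
    # statistically indistinguishable from its absence, and the planted rule
    # would not be identifiable from its sub-rules.  0 disables.
    contrast_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        for name, r in self.missing_rates.items():
            if name not in self.variables:
                raise ValueError(f"missing_rates references unknown variable {name!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError("missing rates must be in [0, 1]")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        for rule in self.planted_rules:
            for lit in rule.literals:
                if lit.variable not in self.variables:
                    raise ValueError(
                        f"planted rule references unknown variable {lit.variable!r}"
                    )


class UnsatisfiableRuleError(ValueError):
    """A planted rule's target support cannot be reached given the marginals."""


# ---------------------------------------------------------------------------
# Internals: category membership and forcing, all in *aligned* space
# (reverse-coded variables flipped so higher = more of the construct)


def _bins_for(values: np.ndarray, spec: VariableSpec) -> np.ndarray:
    if spec.kind == "ordinal":
        bins, _ = data_prep.discretize_levels(values, spec.levels)
        return bins
    bins, _ = data_prep.discretize_quantiles(values)
    return bins


def _literal_mask(values: np.ndarray, spec: VariableSpec, lit: PlantedLiteral) -> np.ndarray:
    if spec.kind == "binary":
        hi = max(spec.levels)
        mask = values == (hi if lit.category == "1" else min(spec.levels))
    else:
        mask = data_prep.category_mask(_bins_for(values, spec), lit.category)
    return mask if lit.polarity else ~mask


def _rule_mask(aligned: pd.DataFrame, specs, rule: PlantedRule) -> np.ndarray:
    mask = np.ones(len(aligned), dtype=bool)
    for lit in rule.literals:
        mask &= _literal_mask(aligned[lit.variable].to_numpy(), specs[lit.variable], lit)
    return mask


def _literal_levels(spec: VariableSpec, lit: PlantedLiteral, inside: bool) -> list[int]:
    """Admissible rating levels (binary values) in/out of a literal's category."""
    if spec.kind == "binary":
        hi, lo = max(spec.levels), min(spec.levels)
        in_cat = [hi] if lit.category == "1" else [lo]
    else:
        parts = data_prep.ordinal_level_bins(spec.levels)
        mask = data_prep.category_mask(np.arange(3), lit.category)
        in_cat = [lv for b, part in enumerate(parts) if mask[b] for lv in part]
    want = inside == lit.polarity
    return in_cat if want else [lv for lv in spec.levels if lv not in in_cat]


def _resample_levels(
    rng: np.random.Generator, spec: VariableSpec, lit: PlantedLiteral,
    inside: bool, size: int, rule: PlantedRule,
) -> np.ndarray:
    """Draw from the variable's law restricted to (non-)category levels."""
    allowed = _literal_levels(spec, lit, inside)
    probs = np.asarray(spec.distribution.get("probs", [1.0 / len(spec.levels)] * len(spec.levels)))
    if spec.reverse_coded:  # aligned space: level i carries prob of raw max+1-i
        probs = probs[::-1]
    idx = [i for i, lv in enumerate(spec.levels) if lv in allowed]
    p = probs[idx]
    if not len(idx) or p.sum() <= 0:
        raise UnsatisfiableRuleError(
            f"literal {lit.feature_name!r} of rule [{rule.describe()}] has no "
            f"probability mass to draw from; target_support is infeasible"
        )
    vals = np.asarray([spec.levels[i] for i in idx], dtype=float)
    return rng.choice(vals, size=size, p=p / p.sum())


def _danger_mask(
    aligned: pd.DataFrame, specs, avoid_rules, variable: str
) -> np.ndarray:
    """Rows that would satisfy some avoided rule if only ``variable`` moved.

    Used to screen swap donors: a donor receiving an arbitrary value on
    ``variable`` must not thereby complete a planted rule it already
    satisfies on every other literal.
    """
    danger = np.zeros(len(aligned), dtype=bool)
    for rule in avoid_rules:
        if not any(l.variable == variable for l in rule.literals):
            continue
        partial = np.ones(len(aligned), dtype=bool)
        for l in rule.literals:
            if l.variable != variable:
                partial &= _literal_mask(
                    aligned[l.variable].to_numpy(dtype=float), specs[l.variable], l
                )
        danger |= partial
    return danger


def _force_support(
    rng: np.random.Generator,
    aligned: pd.DataFrame,
    specs,
    rule: PlantedRule,
    protected_extra: np.ndarray,
    avoid_rules: tuple[PlantedRule, ...] = (),
    only_deficit: bool = False,
) -> np.ndarray:
    """Mutate columns in place until ~target_support rows satisfy the rule.

    Ordinal/binary literals are forced by resampling within (outside) the
    category — level-defined bins give no quantile feedback.  Continuous
    literals are forced by swapping values with donor rows, which preserves
    the column's marginal distribution and hence its tercile cutpoints
    exactly.  Rows satisfying previously planted rules are protected, and
    donors that would complete a rule in ``avoid_rules`` through the swapped
    variable are never used.  ``only_deficit`` tops the support up but never
    evicts a surplus (used for near-miss planting, where "at least this
    many" is what matters).
    """
    n = len(aligned)
    target = int(round(rule.target_support * n))
    mask = _rule_mask(aligned, specs, rule)
    have = int(mask.sum())
    if have == target or (only_deficit and have > target):
        return np.empty(0, dtype=int)
    if have < target:
        candidates = np.flatnonzero(~mask & ~protected_extra)
        if len(candidates) < target - have:
            raise UnsatisfiableRuleError(
                f"not enough free rows to force rule [{rule.describe()}]; "
                f"target_support {rule.target_support} is infeasible"
            )
        recruits = rng.choice(candidates, size=target - have, replace=False)
        protected = mask | protected_extra
        protected[recruits] = True
        for lit in rule.literals:
            spec = specs[lit.variable]
            col = aligned[lit.variable].to_numpy(dtype=float).copy()
            litmask = _literal_mask(col, spec, lit)
            need = recruits[~litmask[recruits]]
            if not len(need):
                continue
            if spec.kind in ("ordinal", "binary"):
                col[need] = _resample_levels(rng, spec, lit, True, len(need), rule)
            else:
                # donors receive the recruits' old values.  For a positive
                # literal those values are out-of-category and cannot
                # complete a planted rule; for a negated literal they are
                # in-category, so screen donors against completing one.
                if lit.polarity:
                    danger = np.zeros(n, dtype=bool)
                else:
                    danger = _danger_mask(aligned, specs, avoid_rules, lit.variable)
                donors = np.flatnonzero(litmask & ~protected & ~danger)
                if len(donors) < len(need):
                    raise UnsatisfiableRuleError(
                        f"not enough donor rows for literal {lit.feature_name!r} "
                        f"of rule [{rule.describe()}]; target_support "
                        f"{rule.target_support} is infeasible"
                    )
                picked = rng.choice(donors, size=len(need), replace=False)
                col[need], col[picked] = col[picked].copy(), col[need].copy()
            aligned[lit.variable] = col
        return recruits
    else:
        evict = rng.choice(np.flatnonzero(mask & ~protected_extra),
                           size=min(have - target, int((mask & ~protected_extra).sum())),
                           replace=False)
        # break one literal per evicted row; prefer positive level-coded
        # literals (breaking a negated literal would move rows *into* the
        # category and can complete a related rule)
        lits = sorted(
            rule.literals,
            key=lambda l: (not l.polarity, specs[l.variable].kind == "continuous"),
        )
        lit, spec = None, None
        for cand in lits:
            if specs[cand.variable].kind == "continuous" or \
                    _literal_levels(specs[cand.variable], cand, False):
                lit, spec = cand, specs[cand.variable]
                break
        if lit is None:
            raise UnsatisfiableRuleError(
                f"no literal of rule [{rule.describe()}] can be broken; "
                f"target_support {rule.target_support} is infeasible"
            )
        col = aligned[lit.variable].to_numpy(dtype=float).copy()
        if spec.kind in ("ordinal", "binary"):
            col[evict] = _resample_levels(rng, spec, lit, False, len(evict), rule)
        else:
            if len(rule.literals) == 1:
                raise UnsatisfiableRuleError(
                    f"single continuous-literal rule [{rule.describe()}] has "
                    f"support fixed by its tercile; target_support "
                    f"{rule.target_support} is infeasible"
                )
            litmask = _literal_mask(col, spec, lit)
            others = np.ones(n, dtype=bool)
            for other in rule.literals:
                if other is not lit:
                    others &= _literal_mask(
                        aligned[other.variable].to_numpy(dtype=float),
                        specs[other.variable], other,
                    )
            danger = _danger_mask(aligned, specs, avoid_rules, lit.variable)
            donors = np.flatnonzero(~litmask & ~others & ~protected_extra & ~danger)
            if len(donors) < len(evict):
                raise UnsatisfiableRuleError(
                    f"not enough donor rows to relax rule [{rule.describe()}]; "
                    f"target_support {rule.target_support} is infeasible"
                )
            picked = rng.choice(donors, size=len(evict), replace=False)
            col[evict], col[picked] = col[picked].copy(), col[evict].copy()
        aligned[lit.variable] = col
        return np.empty(0, dtype=int)


# ---------------------------------------------------------------------------
# Public operations


def generate_survey(config: SimulationConfig) -> tuple[SurveyTable, dict]:
    """Generate a survey table plus a truth sidecar (rules, labels, seed).

    The returned table is in raw survey codings (reverse-coded items still
    flipped); the truth dict records the planted rules as canonical feature
    names, the noise-free fired mask, and the realised outcome labels.
    """
    rng = np.random.default_rng(config.seed)
    specs = config.variables
    # 1. independent marginal draws, in aligned space for reverse-coded items
    aligned = pd.DataFrame(index=range(config.n))
    for name, spec in specs.items():
        raw = spec.sample(rng, config.n)
        if spec.reverse_coded:
            raw = (spec.max_level + 1) - raw
        aligned[name] = raw
    # 2. force planted-rule supports (rows claimed by earlier rules protected)
    claimed = np.zeros(config.n, dtype=bool)
    base_rules = config.planted_rules
    for rule in base_rules:
        if rule.target_support is not None:
            _force_support(rng, aligned, specs, rule, claimed,
                           avoid_rules=tuple(r for r in base_rules if r is not rule))
        claimed |= _rule_mask(aligned, specs, rule)
        if (
            rule.target_support is not None
            and config.contrast_fraction > 0
            and len(rule.literals) > 1
        ):
            for k, lit in enumerate(rule.literals):
                flipped = PlantedRule(
                    literals=tuple(
                        PlantedLiteral(l.variable, l.category, not l.polarity)
                        if i == k else l
                        for i, l in enumerate(rule.literals)
                    ),
                    target_support=rule.target_support * config.contrast_fraction,
                )
                # protect only the rows we actively forced: a naturally
                # abundant near-miss set must stay available as donor/
                # recruit material for later rules
                recruits = _force_support(rng, aligned, specs, flipped, claimed,
                                          avoid_rules=base_rules, only_deficit=True)
                claimed[recruits] = True
    # 3. evaluate rules on the final table
    fired = np.zeros(config.n, dtype=bool)
    per_rule = {}
    for rule in config.planted_rules:
        m = _rule_mask(aligned, specs, rule)
        per_rule[rule.describe()] = float(m.mean())
        fired |= m
    # 4. outcome: high iff fired, corrupted at noise_rate
    flip = rng.random(config.n) < config.noise_rate
    labels = np.where(flip, ~fired, fired).astype(np.uint8)
    out_spec = specs[config.outcome_name]
    neg_levels = np.arange(1, len(config.negative_outcome_probs) + 1, dtype=float)
    neg_draws = rng.choice(neg_levels, size=config.n, p=config.negative_outcome_probs)
    outcome_aligned = np.where(labels == 1, float(out_spec.max_level), neg_draws)
    mu, sd = outcome_aligned.mean(), outcome_aligned.std(ddof=1)
    cutoff = mu + sd
    top = float(out_spec.max_level)
    lo_max = float(neg_levels.max())
    if not (lo_max <= cutoff < top):
        raise ValueError(
            f"outcome split degenerate: mean+1SD cutoff {cutoff:.3f} does not "
            f"separate the negative levels (<= {lo_max}) from the top level "
            f"{top}; adjust planted supports or noise_rate"
        )
    aligned[config.outcome_name] = outcome_aligned
    # 5. back to raw codings
    raw = aligned.copy()
    for name, spec in specs.items():
        if spec.reverse_coded:
            raw[name] = (spec.max_level + 1) - raw[name]
    table = SurveyTable(
        data=raw, specs=dict(specs),
        log=[{"op": "generate_survey", "seed": config.seed, "n": config.n}],
    )
    table.validate()
    truth = {
        "seed": config.seed,
        "n": config.n,
        "noise_rate": config.noise_rate,
        "planted_rules": [sorted(r.feature_names) for r in config.planted_rules],
        "planted_supports": per_rule,
        "labels": labels.tolist(),
        "fired": fired.astype(int).tolist(),
    }
    return table, truth


def inject_missingness(
    table: SurveyTable, rates: dict[str, float], seed: int
) -> SurveyTable:
    """Knock out values completely at random, per-variable, at given rates."""
    rng = np.random.default_rng(seed)
    data = table.data.copy()
    for name, rate in rates.items():
        if name not in data.columns:
            raise ValueError(f"unknown variable {name!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must be in [0, 1]")
        if rate == 0.0:
            continue
        mask = rng.random(len(data)) < rate
        col = data[name].to_numpy(dtype=float).copy()
        col[mask] = np.nan
        data[name] = col
    return table.evolve(data, {"op": "inject_missingness", "rates": dict(rates)})


def inject_outliers(
    table: SurveyTable,
    rate: float,
    seed: int,
    work_var: str = WORKTIME_DEFAULT,
) -> SurveyTable:
    """Replace a fraction of work-time entries with >84 h/week values."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if work_var not in table.data.columns:
        raise ValueError(f"work-time variable {work_var!r} not in table")
    rng = np.random.default_rng(seed)
    data = table.data.copy()
    mask = rng.random(len(data)) < rate
    col = data[work_var].to_numpy(dtype=float).copy()
    # 24 h/day for 4-7 days: clearly infeasible weekly totals
    col[mask] = rng.uniform(96.0, 168.0, size=int(mask.sum()))
    data[work_var] = col
    return table.evolve(
        data, {"op": "inject_outliers", "rate": rate, "rows": int(mask.sum())}
    )


def write_simulation(table: SurveyTable, truth: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "survey.csv")
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
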