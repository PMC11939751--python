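"""Candidate rule pool: conjunctions of binary literals with minimum support.

A rule is a conjunction (AND) of up to ``max_len`` feature columns; negated
features are ordinary ``NOT_`` columns, so no separate polarity machinery is
needed.  Mining is a level-wise (apriori-style) search that exploits support
anti-monotonicity: a conjunction can only be frequent if all its
sub-conjunctions are.  Support is counted over all rows — a rule must cover
at least ``ceil(min_support * n)`` observations.  When the pool exceeds
``max_rules`` it is truncated by information gain of the rule's cover with
respect to the class labels.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_prep import complement_name


@dataclass(frozen=True, order=True)
class Rule:
    """Conjunction of 1-3 feature literals, identified by its literal set."""

    literals: frozenset[str] = field(compare=False)
    key: tuple[str, ...] = field(default=None, compare=True)

    def __post_init__(self) -> None:
        object.__setattr__(self, "key", tuple(sorted(self.literals)))
        if not self.literals:
            raise ValueError("empty conjunctions are not allowed")
        for lit in self.literals:
            if complement_name(lit) in self.literals:
                raise ValueError(
                    f"rule contains a feature and its complement: {lit}"
                )

    @property
    def length(self) -> int:
        return len(self.literals)

    def describe(self) -> str:
        return " & ".join(self.key)

    @classmethod
    def parse(cls, text: str) -> "Rule":
        return cls(literals=frozenset(p.strip() for p in text.split("&")))


@dataclass(frozen=True)
class MiningConfig:
    """Pool constraints: length cap, support floor, size cap.

    ``drop_dominated`` removes rules whose cover is identical to one of
    their own sub-conjunctions (a literal that never excludes a row adds
    interpretive noise and search ties without changing predictions).
    """

    max_len: int = 3
    min_support: float = 0.05
    max_rules: int = 5000
    drop_dominated: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.min_support < 1.0:
            raise ValueError("min_support must be in (0, 1)")
        if self.max_rules < 1 or self.max_len < 1:
            raise ValueError("max_rules and max_len must be >= 1")


def rule_cover(rule: Rule, features: pd.DataFrame) -> np.ndarray:
    """Indicator vector: 1 iff the row satisfies every literal of the rule."""
    for lit in rule.literals:
        if lit not in features.columns:
            raise KeyError(f"unknown literal {lit!r}")
    sub = features[list(rule.key)].to_numpy(dtype=np.uint8)
    return sub.all(axis=1).astype(np.uint8)


def _information_gain(tp: np.ndarray, cover: np.ndarray, n_pos: int, n: int) -> np.ndarray:
    """Entropy reduction of the label split induced by each rule's cover."""

    def h(p):
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))

    cover = cover.astype(float)
    tp = tp.astype(float)
    base = h(n_pos / n)
    p_in = np.where(cover > 0, tp / np.maximum(cover, 1), 0.0)
    out = n - cover
    p_out = np.where(out > 0, (n_pos - tp) / np.maximum(out, 1), 0.0)
    return base - (cover / n) * h(p_in) - (out / n) * h(p_out)


def mine_candidates(
    features: pd.DataFrame,
    labels: np.ndarray,
    config: MiningConfig = MiningConfig(),
) -> list[Rule]:
    """Enumerate all supported conjunctions of distinct feature columns.

    Exact duplicate columns are collapsed to their first occurrence (the
    overlapping binarization emits NOT_ columns that duplicate other
    categories), and conjunctions pairing a feature with its complement are
    excluded.  The returned pool is deterministic: sorted by decreasing
    information gain, then length, then literal names, truncated to
    ``max_rules``.
    """
    labels = np.asarray(labels, dtype=np.uint8)
    n = len(features)
    if n != len(labels):
        raise ValueError("features/labels length mismatch")
    min_count = int(np.ceil(config.min_support * n))

    # collapse duplicate columns, keep first occurrence
    X = features.to_numpy(dtype=np.uint8)
    _, first_idx = np.unique(X.T, axis=0, return_index=True)
    keep = np.sort(first_idx)
    names = [features.columns[i] for i in keep]
    X = X[:, keep].astype(np.float64)
    m = X.shape[1]
    comp = {}
    for i, nm in enumerate(names):
        cn = complement_name(nm)
        if cn in names:
            comp[i] = names.index(cn)

    Xp = X[labels == 1]  # positive-row block, for true-positive counts
    supports = X.sum(axis=0)
    tps = Xp.sum(axis=0)
    # weighted row sums fingerprint each cover without materializing it:
    # two conjunctions with identical covers (a literal that excludes no
    # extra row, two variables that happen to coincide in-sample, ...) give
    # identical (support, tp, sig1, sig2); only the first-enumerated — the
    # shortest, earliest-named — representative is kept
    v = np.random.default_rng(140598).random((2, len(features)))
    sv = v @ X  # (2, m) signatures of the single-feature covers

    def _key(cnt, tp, s1, s2):
        return (int(cnt), int(tp), round(float(s1), 6), round(float(s2), 6))

    seen: set[tuple] = set()
    # pool entries: (literal index tuple, support count, true-positive count)
    pool: list[tuple[tuple[int, ...], float, float]] = []
    level: list[tuple[tuple[int, ...], np.ndarray, np.ndarray]] = []
    for i in range(m):
        if supports[i] >= min_count:
            if config.drop_dominated:
                k = _key(supports[i], tps[i], sv[0, i], sv[1, i])
                if k in seen:
                    continue
                seen.add(k)
            pool.append(((i,), float(supports[i]), float(tps[i])))
            if config.max_len > 1:
                level.append(((i,), X[:, i], Xp[:, i]))

    for length in range(2, config.max_len + 1):
        if not level:
            break
        covers = np.stack([c for _, c, _ in level], axis=0)  # (k, n)
        counts = covers @ X  # (k, m) joint supports with every column
        pcounts = np.stack([c for _, _, c in level], axis=0) @ Xp
        if config.drop_dominated:
            sig1 = (covers * v[0]) @ X
            sig2 = (covers * v[1]) @ X
        nxt = []
        for r, (idx, cov, pcov) in enumerate(level):
            last = idx[-1]
            for j in range(last + 1, m):
                cnt = counts[r, j]
                if cnt < min_count:
                    continue
                if any(comp.get(i) == j for i in idx):
                    continue
                dup = False
                if config.drop_dominated:
                    k = _key(cnt, pcounts[r, j], sig1[r, j], sig2[r, j])
                    dup = k in seen
                    seen.add(k)
                if not dup:
                    pool.append(((*idx, j), float(cnt), float(pcounts[r, j])))
                # duplicates still extend: their longer conjunctions can
                # reach covers the kept representative's extensions cannot
                if length < config.max_len:
                    nxt.append(((*idx, j), cov * X[:, j], pcov * Xp[:, j]))
        level = nxt

    if not pool:
        warnings.warn("no rule meets the minimum support", UserWarning)
        return []

    gains = _information_gain(
        np.asarray([t for _, _, t in pool]),
        np.asarray([s for _, s, _ in pool]),
        int(labels.sum()),
        n,
    )
    order = sorted(
        range(len(pool)),
        key=lambda k: (-gains[k], len(pool[k][0]), tuple(names[i] for i in pool[k][0])),
    )
    rules = []
    for k in order[: config.max_rules]:
        idx, _, _ = pool[k]
        rules.append(Rule(literals=frozenset(names[i] for i in idx)))
    return rules


def rule_support(rule: Rule, features: pd.DataFrame) -> float:
    return float(rule_cover(rule, features).mean())


def pool_to_tsv(
    rules: list[Rule], features: pd.DataFrame, labels: np.ndarray, path
) -> None:
    labels = np.asarray(labels, dtype=float)
    rows = []
    n, n_pos = len(labels), labels.sum()
    for i, r in enumerate(rules):
        cov = rule_cover(r, features).astype(float)
        tp = float(cov @ labels)
        gain = float(
            _information_gain(
                np.asarray([tp]), np.asarray([cov.sum()]), int(n_pos), n
            )[0]
        )
        rows.append(
            {"rule_id": i, "literals": r.describe(), "length": r.length,
             "support": cov.mean(), "gain": gain}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def pool_from_tsv(path) -> list[Rule]:
    df = pd.read_csv(path, sep="\t")
    return [Rule.parse(t) for t in df["literals"]]
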