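"""Comparison methods: LASSO interaction screening, tree rules, forests.

These are the standard interpretable-model baselines the rule-set approach
is judged against: (i) LASSO over all products of up to three binary
features with an OLS refit on the selected support, (ii) rules read off the
positive leaves of a complexity-capped classification tree, and (iii)
impurity-decrease variable importance from a random forest.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LassoCV
from sklearn.tree import DecisionTreeClassifier

from .brs_inference import RuleSet
from .data_prep import complement_name
from .rule_mining import Rule


@dataclass
class InteractionDesign:
    """Products of 1-3 binary features, named ``a x b x c``."""

    columns: pd.DataFrame
    terms: list[tuple[str, ...]]


def build_interaction_design(
    features: pd.DataFrame, max_order: int = 3, max_terms: int = 200_000
) -> InteractionDesign:
    """All products of 1..max_order distinct features.

    Products pairing a feature with its complement are identically zero and
    skipped.  ``max_terms`` bounds the design width; exceeding it raises
    with advice to reduce the interaction order, since the full design grows
    combinatorially.
    """
    if max_order < 1 or max_order > 3:
        raise ValueError("max_order must be 1-3")
    names = list(features.columns)
    m = len(names)
    est = sum(
        np.prod([m - k for k in range(o)]) / np.prod(range(1, o + 1))
        for o in range(1, max_order + 1)
    )
    if est > max_terms:
        raise MemoryError(
            f"interaction design would hold ~{int(est)} terms (> {max_terms}); "
            f"reduce max_order or the feature set"
        )
    X = features.to_numpy(dtype=np.uint8)
    cols: dict[str, np.ndarray] = {}
    terms: list[tuple[str, ...]] = []
    for order in range(1, max_order + 1):
        for idx in combinations(range(m), order):
            group = [names[i] for i in idx]
            if any(
                complement_name(a) in group[i + 1:] for i, a in enumerate(group)
            ):
                continue
            col = X[:, idx[0]].copy()
            for j in idx[1:]:
                col = col * X[:, j]
            if not col.any():
                continue
            cols[" x ".join(group)] = col
            terms.append(tuple(group))
    return InteractionDesign(columns=pd.DataFrame(cols, index=features.index), terms=terms)


def lasso_interaction_screen(
    features: pd.DataFrame,
    outcome: np.ndarray,
    max_order: int = 3,
    seed: int = 0,
    alpha_level: float = 0.05,
    max_terms: int = 200_000,
) -> pd.DataFrame:
    """LASSO-screen interaction terms, then OLS-refit the non-zero support.

    Returns one row per selected term with the refit coefficient, SE,
    p-value, and a ``significant`` flag at ``alpha_level`` (no multiplicity
    correction, matching the enumeration-style reporting this mirrors).
    """
    design = build_interaction_design(features, max_order, max_terms)
    y = np.asarray(outcome, dtype=float)
    Xn = design.columns.to_numpy(dtype=float)
    model = LassoCV(cv=5, random_state=seed).fit(Xn, y)
    sel = [c for c, b in zip(design.columns.columns, model.coef_) if abs(b) > 1e-10]
    if not sel:
        warnings.warn("LASSO selected no interaction terms", UserWarning)
        return pd.DataFrame(columns=["coef", "se", "p", "significant"])
    # drop exactly collinear survivors so the refit is well-posed
    sub = design.columns[sel].to_numpy(dtype=float)
    keep_idx: list[int] = []
    for j in range(sub.shape[1]):
        trial = sub[:, keep_idx + [j]]
        if np.linalg.matrix_rank(trial) == len(keep_idx) + 1:
            keep_idx.append(j)
    sel = [sel[j] for j in keep_idx]
    X = sm.add_constant(design.columns[sel].astype(float), has_constant="add")
    res = sm.OLS(y, X).fit()
    out = pd.DataFrame(
        {
            "coef": res.params.drop("const"),
            "se": res.bse.drop("const"),
            "p": res.pvalues.drop("const"),
        }
    )
    out["significant"] = out["p"] < alpha_level
    return out


def tree_to_rules(
    features: pd.DataFrame,
    outcome: np.ndarray,
    max_leaves: int = 4,
    seed: int = 0,
) -> tuple[RuleSet, DecisionTreeClassifier]:
    """Fit a complexity-capped tree; read a rule off each positive leaf.

    Going right at a node (feature = 1) contributes the feature itself as a
    literal; going left contributes its complement column.  The union of the
    positive-leaf rules predicts exactly what the tree predicts on binary
    inputs.  The leaf cap should be chosen comparable to the aggregated
    rule-set solution (number of rules, average length).
    """
    clf = DecisionTreeClassifier(max_leaf_nodes=max_leaves, random_state=seed)
    clf.fit(features.to_numpy(dtype=np.uint8), np.asarray(outcome, dtype=int))
    tree = clf.tree_
    names = list(features.columns)
    rules: list[Rule] = []

    def walk(node: int, path: list[str]) -> None:
        if tree.children_left[node] == -1:  # leaf
            counts = tree.value[node][0]
            pred = int(np.argmax(counts))
            if len(clf.classes_) > 1:
                pred = int(clf.classes_[pred])
            if pred == 1 and path:
                rules.append(Rule(literals=frozenset(path)))
            return
        f = names[tree.feature[node]]
        walk(tree.children_left[node], path + [complement_name(f)])
        walk(tree.children_right[node], path + [f])

    walk(0, [])
    if not rules:
        warnings.warn("tree has no positive leaf; empty rule set", UserWarning)
    return RuleSet(frozenset(rules)), clf


def forest_importance(
    features: pd.DataFrame,
    outcome: np.ndarray,
    n_trees: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Impurity-decrease importances from a bagged forest, ranked descending."""
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(features.to_numpy(dtype=np.uint8), np.asarray(outcome, dtype=int))
    imp = clf.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    out = pd.DataFrame(
        {"feature": features.columns, "importance": imp}
    ).sort_values("importance", ascending=False, kind="stable")
    out["rank"] = range(1, len(out) + 1)
    return out.reset_index(drop=True)
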