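"""Propensity scores, matching, IPW, and rule-indicator mediation models.

This stage turns a fitted rule set into regression columns and asks how a
core variable's high/low contrast propagates to the outcome through a
mediator.  Respondents are split into a treatment group (core variable above
mean + 1 SD) and controls; a logistic propensity model p_i = P(T=1 | W_i)
supports nearest-neighbour / radius / caliper matching or inverse
probability weighting (w = 1/p treated, 1/(1−p) control).  Each rule r of
the rule set becomes an indicator column Rule_r, and three least-squares
equations are fitted:

    (5)  M = α1 + β1·T + γ1'Z + Σ_r λr·Rule_r + u1
    (6)  Y = α2 + β2·T + λ1·M + γ2'Z + u2
    (7)  Y = α3 + β3·T + λ2·M + γ3'Z + Σ_r θr·Rule_r + u3

The indirect effect of rule r on Y through M is the product λr·λ2 (delta-
method standard error); its direct effect is θr.  When no treatment
grouping is used the β·T terms are omitted.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import Lasso, LassoCV
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning


@dataclass
class PropensityModel:
    coefficients: pd.Series  # includes "const"
    scores: np.ndarray
    covariates: list[str]

    def __post_init__(self) -> None:
        if not ((self.scores > 0) & (self.scores < 1)).all():
            raise ValueError("propensity scores must lie strictly in (0, 1)")


@dataclass
class TreatmentAssignment:
    T: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        if self.T.sum() == 0 or self.T.sum() == len(self.T):
            raise ValueError("one treatment group is empty")


@dataclass
class WeightVector:
    weights: np.ndarray
    extreme: np.ndarray  # flags: weight above the 99th percentile


@dataclass
class MediationSpec:
    outcome: str
    mediator: str
    treatment: str | None         # column name of T, or None = no grouping
    controls: list[str] = field(default_factory=list)
    rule_indicators: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        roles = [self.outcome, self.mediator] + self.controls + self.rule_indicators
        if self.treatment is not None:
            roles.append(self.treatment)
        if len(roles) != len(set(roles)):
            raise ValueError("a variable appears in two roles of the mediation spec")


@dataclass
class MediationResult:
    eq5: pd.DataFrame   # mediator model coefficients
    eq6: pd.DataFrame   # outcome on mediator
    eq7: pd.DataFrame   # joint outcome model
    indirect: pd.DataFrame  # per-rule λr·λ2 with delta-method SE
    direct: pd.DataFrame    # per-rule θr
    vif: pd.DataFrame
    rule_overlap: pd.DataFrame

    def to_json(self, path) -> None:
        import json

        payload = {
            k: getattr(self, k).to_dict(orient="index")
            for k in ("eq5", "eq6", "eq7", "indirect", "direct", "vif")
        }
        payload["rule_overlap"] = self.rule_overlap.to_dict()
        from pathlib import Path

        Path(path).write_text(json.dumps(payload, indent=2, default=float))


# ---------------------------------------------------------------------------


def assign_treatment(values: np.ndarray) -> TreatmentAssignment:
    """High group: value strictly above mean + 1 sample SD."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1) if len(v) > 1 else 0.0
    cutoff = v.mean() + sd
    T = (v > cutoff).astype(np.uint8)
    return TreatmentAssignment(T=T, cutoff=float(cutoff))


def _separating_covariates(W: pd.DataFrame, T: np.ndarray) -> list[str]:
    out = []
    for c in W.columns:
        a, b = W[c].to_numpy()[T == 1], W[c].to_numpy()[T == 0]
        if len(a) and len(b) and (a.min() > b.max() or b.min() > a.max()):
            out.append(c)
    return out


def estimate_propensity(W: pd.DataFrame, T: np.ndarray) -> PropensityModel:
    """Maximum-likelihood logistic regression of T on W (with intercept)."""
    T = np.asarray(T, dtype=float)
    if not np.isin(T, (0, 1)).all():
        raise ValueError("T must be binary")
    X = sm.add_constant(W.astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(T, X).fit(disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as e:
        seps = _separating_covariates(W, T.astype(int))
        raise ValueError(
            f"perfect separation in the propensity model; separating "
            f"covariate(s): {seps or 'not identified'}"
        ) from e
    scores = np.asarray(res.predict(X))
    eps = 1e-12
    scores = np.clip(scores, eps, 1 - eps)
    return PropensityModel(
        coefficients=res.params, scores=scores, covariates=list(W.columns)
    )


def match(
    scores: np.ndarray,
    T: np.ndarray,
    method: str = "nearest",
    caliper: float | None = None,
) -> tuple[list[tuple[int, int]], list[int]]:
    """Pair treated rows with controls on propensity-score distance.

    ``nearest``: greedy 1:1 matching without replacement, treated rows
    processed in descending score order, distance ties resolved toward the
    lower control index.  ``caliper``: nearest matching but a pair is only
    formed within the caliper (default 0.2 SD of the logit of the score).
    ``radius``: every (treated, control) pair within the caliper distance.
    Returns (pairs, unmatched treated indices).
    """
    scores = np.asarray(scores, dtype=float)
    T = np.asarray(T, dtype=int)
    treated = np.flatnonzero(T == 1)
    controls = np.flatnonzero(T == 0)
    if not len(treated) or not len(controls):
        raise ValueError("both groups must be non-empty")
    if method not in ("nearest", "caliper", "radius"):
        raise ValueError(f"unknown matching method {method!r}")
    if caliper is None and method in ("caliper", "radius"):
        logit = np.log(scores / (1 - scores))
        caliper = 0.2 * logit.std(ddof=1)
    pairs: list[tuple[int, int]] = []
    unmatched: list[int] = []
    if method == "radius":
        for t in treated:
            close = controls[np.abs(scores[controls] - scores[t]) <= caliper]
            if len(close):
                pairs.extend((int(t), int(c)) for c in close)
            else:
                unmatched.append(int(t))
        if not pairs:
            warnings.warn("radius matching produced no pairs", UserWarning)
        return pairs, unmatched
    available = list(controls)
    order = treated[np.argsort(-scores[treated], kind="stable")]
    for t in order:
        if not available:
            unmatched.append(int(t))
            continue
        avail = np.asarray(available)
        d = np.abs(scores[avail] - scores[t])
        j = int(np.lexsort((avail, d))[0])  # min distance, ties to lower index
        if method == "caliper" and d[j] > caliper:
            unmatched.append(int(t))
            continue
        pairs.append((int(t), int(avail[j])))
        available.remove(int(avail[j]))
    if not pairs:
        warnings.warn("matching produced no pairs", UserWarning)
    return pairs, unmatched


def ipw_weights(scores: np.ndarray, T: np.ndarray) -> WeightVector:
    """w = 1/p for treated, 1/(1−p) for controls, with extreme-weight flags."""
    scores = np.asarray(scores, dtype=float)
    T = np.asarray(T, dtype=int)
    if ((scores <= 0) | (scores >= 1)).any():
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    w = np.where(T == 1, 1.0 / scores, 1.0 / (1.0 - scores))
    extreme = w > np.percentile(w, 99)
    return WeightVector(weights=w, extreme=extreme)


# ---------------------------------------------------------------------------
# Mediation


def _coef_table(res, names) -> pd.DataFrame:
    return pd.DataFrame(
        {"coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues},
        index=names,
    )


def _design(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    X = sm.add_constant(data[cols].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for c in cols:
            rest = [x for x in X.columns if x != c]
            if np.linalg.matrix_rank(X[rest].to_numpy()) == rank:
                bad.append(c)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X


def mediation_fit(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Fit the three mediation equations and decompose rule effects.

    ``data`` holds the outcome, mediator, optional treatment indicator,
    controls, and rule-indicator columns.  Returns coefficient tables for
    all three equations, the per-rule indirect effect λr·λ2 (delta-method
    SE), the per-rule direct effect θr, variance inflation factors for the
    joint model, and the rule-overlap (Jaccard) matrix.
    """
    t = [spec.treatment] if spec.treatment else []
    rules = spec.rule_indicators
    X5 = _design(data, t + spec.controls + rules)
    res5 = sm.OLS(data[spec.mediator].astype(float), X5).fit()
    X6 = _design(data, t + [spec.mediator] + spec.controls)
    res6 = sm.OLS(data[spec.outcome].astype(float), X6).fit()
    X7 = _design(data, t + [spec.mediator] + spec.controls + rules)
    res7 = sm.OLS(data[spec.outcome].astype(float), X7).fit()

    lam2 = res7.params[spec.mediator]
    lam2_var = res7.bse[spec.mediator] ** 2
    ind_rows, dir_rows = [], []
    for r in rules:
        lam_r = res5.params[r]
        lam_r_var = res5.bse[r] ** 2
        est = lam_r * lam2
        se = np.sqrt(lam_r**2 * lam2_var + lam2**2 * lam_r_var)
        ind_rows.append({"rule": r, "estimate": est, "se": se})
        dir_rows.append(
            {"rule": r, "estimate": res7.params[r], "se": res7.bse[r],
             "p": res7.pvalues[r]}
        )
    vif = pd.DataFrame(
        {
            "vif": [
                variance_inflation_factor(X7.to_numpy(), i)
                for i in range(X7.shape[1])
            ]
        },
        index=list(X7.columns),
    )
    if rules:
        R = data[rules].to_numpy(dtype=float)
        inter = R.T @ R
        union = R.sum(0)[:, None] + R.sum(0)[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            jac = np.where(union > 0, inter / union, 0.0)
        overlap = pd.DataFrame(jac, index=rules, columns=rules)
    else:
        overlap = pd.DataFrame()
    return MediationResult(
        eq5=_coef_table(res5, X5.columns),
        eq6=_coef_table(res6, X6.columns),
        eq7=_coef_table(res7, X7.columns),
        indirect=pd.DataFrame(ind_rows).set_index("rule") if ind_rows else pd.DataFrame(),
        direct=pd.DataFrame(dir_rows).set_index("rule") if dir_rows else pd.DataFrame(),
        vif=vif,
        rule_overlap=overlap,
    )


def filter_rules_lasso(
    indicators: pd.DataFrame, outcome: np.ndarray, seed: int = 0
) -> list[str]:
    """Keep rule indicators with non-zero LASSO coefficients.

    The penalty is chosen by 5-fold cross-validation with the one-standard-
    error rule (largest penalty whose CV error is within one SE of the
    minimum), which drives pure-noise indicators to zero rather than letting
    them ride along at the error-minimizing penalty.
    """
    if indicators.shape[1] < 1:
        raise ValueError("need at least one indicator")
    y = np.asarray(outcome, dtype=float)
    X = indicators.to_numpy(dtype=float)
    cv_model = LassoCV(cv=5, random_state=seed).fit(X, y)
    mse = cv_model.mse_path_.mean(axis=1)
    se = cv_model.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv_model.mse_path_.shape[1])
    i_min = int(np.argmin(mse))
    limit = mse[i_min] + se[i_min]
    alpha = float(max(a for a, m in zip(cv_model.alphas_, mse) if m <= limit))
    coefs = Lasso(alpha=alpha).fit(X, y).coef_
    kept = [c for c, b in zip(indicators.columns, coefs) if abs(b) > 1e-10]
    if not kept:
        warnings.warn("LASSO filtering retained no rules", UserWarning)
    return kept
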