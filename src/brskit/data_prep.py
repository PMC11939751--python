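"""Survey preparation: reverse coding, filters, dichotomization, binarization.

The prepared object is a :class:`BinaryFeatureMatrix`: every ordinal or
continuous variable is reduced to three ordered bins (bottom / middle / top)
and expanded into four *overlapping* binary features

    ``low``         = bottom bin
    ``low_or_med``  = bottom or middle
    ``med_or_high`` = middle or top
    ``high``        = top bin

plus an exact ``NOT_`` complement column for each, so short conjunctions can
express threshold conditions in either direction.  Binary variables
contribute their indicator and its complement.  The outcome column is
dichotomized at mean + 1 SD and kept out of the feature block.

Continuous variables are binned at their empirical 1/3 and 2/3 quantiles
(linear-interpolation, "type 7"); ordinal variables are binned by splitting
their rating levels into three contiguous, as-equal-as-possible groups
(remainder to the lower bins), so a 4-level item bins as {1,2} / {3} / {4}
and a 5-level item as {1,2} / {3,4} / {5}.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survey import (
    OUTCOME_DEFAULT,
    REVERSE_CODED_DEFAULT,
    WORKTIME_DEFAULT,
    SurveyTable,
    VariableSpec,
)

CATEGORIES = ("low", "low_or_med", "med_or_high", "high")


class DegenerateSplitWarning(UserWarning):
    """Raised when ties or zero variance make a cut degenerate."""


# ---------------------------------------------------------------------------
# Reverse coding


def reverse_code(
    table: SurveyTable, variables: tuple[str, ...] | None = None
) -> SurveyTable:
    """Flip the scoring of reverse-coded items: v' = (max_level + 1) - v.

    By default flips every variable whose spec carries ``reverse_coded=True``
    (job satisfaction, autonomy, sleep quality in the default instrument).
    Applying the transform twice restores the original table.
    """
    if variables is None:
        variables = tuple(
            name for name, s in table.specs.items() if s.reverse_coded
        )
    data = table.data.copy()
    for name in variables:
        spec = table.specs[name]
        col = data[name].to_numpy(dtype=float)
        valid = ~np.isnan(col)
        if not spec.admissible(col).all():
            raise ValueError(f"{name}: value outside declared level set")
        col[valid] = (spec.max_level + 1) - col[valid]
        data[name] = col
    return table.evolve(data, {"op": "reverse_code", "variables": list(variables)})


# ---------------------------------------------------------------------------
# Filters


def filter_missing_variables(
    table: SurveyTable,
    threshold: float = 0.10,
    outcome: str = OUTCOME_DEFAULT,
    listwise: bool = True,
) -> SurveyTable:
    """Drop variables with missing fraction > threshold, then rows listwise.

    The outcome variable is never dropped; if its own missing fraction
    exceeds the threshold the prep is not salvageable and an error is raised.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    frac = table.data.isna().mean()
    if outcome in frac.index and frac[outcome] > threshold:
        raise ValueError(
            f"outcome {outcome!r} has missing fraction {frac[outcome]:.3f} "
            f"> threshold {threshold}"
        )
    keep = [c for c in table.data.columns if frac[c] <= threshold]
    dropped = [c for c in table.data.columns if c not in keep]
    data = table.data[keep]
    n_before = len(data)
    if listwise:
        data = data.dropna(axis=0)
    entry = {
        "op": "filter_missing_variables",
        "threshold": threshold,
        "dropped_variables": dropped,
        "rows_removed_listwise": n_before - len(data),
    }
    return table.evolve(data.reset_index(drop=True), entry)


def remove_outliers(
    table: SurveyTable, work_var: str = WORKTIME_DEFAULT, max_weekly: float = 84.0
) -> SurveyTable:
    """Drop rows whose weekly work time is implausible (> 84 h/week).

    84 hours is 12 h x 7 days; anything above it, including encodings that
    imply >= 24 h/day, is treated as a reporting error.  A row at exactly the
    bound is retained.
    """
    if work_var not in table.data.columns:
        raise ValueError(f"work-time variable {work_var!r} not in table")
    col = table.data[work_var].to_numpy(dtype=float)
    bad = col > max_weekly  # NaN compares False -> retained for the missing filter
    data = table.data.loc[~bad].reset_index(drop=True)
    if bad.all():
        warnings.warn("outlier filter removed every row", UserWarning)
    entry = {"op": "remove_outliers", "rows_removed": int(bad.sum())}
    return table.evolve(data, entry)


# ---------------------------------------------------------------------------
# Outcome dichotomization and discretization


def dichotomize_outcome(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Label 1 iff v > mean + 1 sample SD; returns (labels, cutoff)."""
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("outcome contains missing values")
    sd = v.std(ddof=1) if len(v) > 1 else 0.0
    cutoff = v.mean() + sd
    if sd == 0.0:
        warnings.warn(
            "outcome has zero variance; all labels 0", DegenerateSplitWarning
        )
    return (v > cutoff).astype(np.uint8), float(cutoff)


def tercile_cutpoints(values: np.ndarray) -> tuple[float, float]:
    """Empirical 1/3 and 2/3 quantiles (type-7 / linear interpolation)."""
    v = np.asarray(values, dtype=float)
    q1, q2 = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0], method="linear")
    return float(q1), float(q2)


def discretize_quantiles(values: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Assign tercile bins 0/1/2: v <= q1/3 -> 0, q1/3 < v <= q2/3 -> 1, else 2.

    Ties sitting on a cutpoint go left (bottom of the two bins).  When heavy
    ties collapse the cutpoints a warning is emitted and the degenerate bins
    are simply empty.
    """
    v = np.asarray(values, dtype=float)
    q1, q2 = tercile_cutpoints(v)
    if q1 == q2 or v.min() == v.max():
        warnings.warn(
            "degenerate tercile cutpoints (heavy ties or constant values)",
            DegenerateSplitWarning,
        )
    bins = np.where(v <= q1, 0, np.where(v <= q2, 1, 2)).astype(np.int8)
    return bins, (q1, q2)


def ordinal_level_bins(levels: tuple[int, ...]) -> list[list[int]]:
    """Split rating levels into three contiguous, near-equal groups."""
    parts = np.array_split(np.asarray(sorted(levels)), 3)
    return [list(map(int, p)) for p in parts]


def discretize_levels(
    values: np.ndarray, levels: tuple[int, ...]
) -> tuple[np.ndarray, list[list[int]]]:
    """Assign bins 0/1/2 to an ordinal column by its rating-level thirds."""
    parts = ordinal_level_bins(levels)
    v = np.asarray(values, dtype=float)
    bins = np.full(len(v), -1, dtype=np.int8)
    for b, part in enumerate(parts):
        bins[np.isin(v, np.asarray(part, dtype=float))] = b
    if (bins < 0).any():
        raise ValueError("value outside declared level set")
    return bins, parts


def category_mask(bins: np.ndarray, category: str) -> np.ndarray:
    """Overlapping-category membership from tercile bins 0/1/2."""
    if category == "low":
        return bins == 0
    if category == "low_or_med":
        return bins <= 1
    if category == "med_or_high":
        return bins >= 1
    if category == "high":
        return bins == 2
    raise ValueError(f"unknown category {category!r}")


def complement_name(feature: str) -> str:
    return feature[4:] if feature.startswith("NOT_") else f"NOT_{feature}"


def feature_variable(feature: str) -> str:
    """Recover the variable a feature column encodes (names contain no '_')."""
    base = feature[4:] if feature.startswith("NOT_") else feature
    return base.split("_", 1)[0]


# ---------------------------------------------------------------------------
# Binarization


@dataclass
class BinaryFeatureMatrix:
    """n x m binary feature block plus the dichotomized outcome labels."""

    features: pd.DataFrame
    outcome: np.ndarray
    outcome_name: str
    cutoff: float
    cutpoints: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.features) != len(self.outcome):
            raise ValueError("features/outcome length mismatch")
        vals = self.features.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("feature matrix must be strictly 0/1")

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def names(self) -> list[str]:
        return list(self.features.columns)

    def to_csv(self, path) -> None:
        out = self.features.copy()
        out[self.outcome_name] = self.outcome
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, outcome_name: str) -> "BinaryFeatureMatrix":
        df = pd.read_csv(path)
        outcome = df.pop(outcome_name).to_numpy(dtype=np.uint8)
        return cls(
            features=df.astype(np.uint8), outcome=outcome,
            outcome_name=outcome_name, cutoff=float("nan"),
        )


def binarize(table: SurveyTable, outcome_name: str = OUTCOME_DEFAULT) -> BinaryFeatureMatrix:
    """Expand a prepared table into overlapping binary features + labels.

    For every non-outcome variable: three-bin variables emit the four
    overlapping categories and their NOT_ complements (in that order, so the
    positively-named columns come first); binary variables emit the
    ``<var>_1`` indicator and its complement.  The outcome is dichotomized at
    mean + 1 SD and excluded from the feature block.
    """
    if table.data.isna().any().any():
        raise ValueError("binarize requires a complete table (run filters first)")
    if outcome_name not in table.data.columns:
        raise ValueError(f"outcome {outcome_name!r} not in table")
    cols: dict[str, np.ndarray] = {}
    cutpoints: dict[str, tuple] = {}
    for name, spec in table.specs.items():
        if name == outcome_name:
            continue
        values = table.data[name].to_numpy(dtype=float)
        if spec.kind == "binary":
            hi = max(spec.levels)
            ind = (values == hi).astype(np.uint8)
            cols[f"{name}_1"] = ind
            cols[f"NOT_{name}_1"] = (1 - ind).astype(np.uint8)
            continue
        if spec.kind == "ordinal":
            bins, parts = discretize_levels(values, spec.levels)
            cutpoints[name] = ("levels", parts)
        else:
            bins, (q1, q2) = discretize_quantiles(values)
            cutpoints[name] = ("quantiles", (q1, q2))
        for cat in CATEGORIES:
            cols[f"{name}_{cat}"] = category_mask(bins, cat).astype(np.uint8)
        for cat in CATEGORIES:
            cols[f"NOT_{name}_{cat}"] = (1 - cols[f"{name}_{cat}"]).astype(np.uint8)
    labels, cutoff = dichotomize_outcome(table.data[outcome_name].to_numpy(dtype=float))
    features = pd.DataFrame(cols, index=range(table.n))
    if outcome_name in features.columns:
        raise ValueError("outcome leaked into the feature block")
    return BinaryFeatureMatrix(
        features=features, outcome=labels, outcome_name=outcome_name,
        cutoff=cutoff, cutpoints=cutpoints,
    )


# ---------------------------------------------------------------------------
# Full prep pipeline


def prepare(
    table: SurveyTable,
    missing_threshold: float = 0.10,
    outcome_name: str = OUTCOME_DEFAULT,
    work_var: str = WORKTIME_DEFAULT,
) -> tuple[SurveyTable, BinaryFeatureMatrix]:
    """Run the full preparation chain and return (prepared table, features).

    Order: reverse coding -> variable-level missingness filter -> work-time
    outlier removal -> listwise deletion -> discretization/binarization.
    """
    t = reverse_code(table)
    t = filter_missing_variables(t, missing_threshold, outcome=outcome_name, listwise=False)
    if work_var in t.data.columns:
        t = remove_outliers(t, work_var=work_var)
    t = t.evolve(t.data.dropna(axis=0).reset_index(drop=True), {"op": "listwise_deletion"})
    return t, binarize(t, outcome_name)
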