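"""Survey table container and per-variable metadata.

A survey table is a respondents-by-variables grid in the questionnaire's
original codings, carried around together with a :class:`VariableSpec` per
column and an append-only log of the transforms applied to it.  The default
variable set mirrors an 18-item national social-survey instrument: ordinal
attitude/health items on 1-4 or 1-5 scales, a 1-10 social-class ladder,
continuous weekly work hours, weekday sleep hours, one-way commute minutes,
age, yearly income, and three binary demographics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

KINDS = ("ordinal", "continuous", "binary")


@dataclass(frozen=True)
class VariableSpec:
    """Declares one survey variable: admissible values and sampling law.

    Parameters
    ----------
    name:
        Short column identifier (no underscores; feature names are built as
        ``<name>_<category>``).
    kind:
        ``ordinal`` (integer rating levels), ``continuous`` (bounded real),
        or ``binary`` (two levels, canonically 0/1).
    levels:
        Admissible integer levels for ordinal/binary variables.
    bounds:
        ``(low, high)`` admissible range for continuous variables.
    reverse_coded:
        Whether the raw coding runs opposite to the construct (higher raw
        value = less of the construct) and must be flipped during prep.
    distribution:
        Sampling law for the synthetic generator.  Ordinal/binary:
        ``{"probs": [...]}`` over ``levels``.  Continuous:
        ``{"family": "truncnorm", "mean": m, "sd": s}`` (truncated at
        ``bounds``) or ``{"family": "lognormal", "mu": m, "sigma": s}``
        (clipped at ``bounds``).
    """

    name: str
    kind: str
    levels: tuple[int, ...] | None = None
    bounds: tuple[float, float] | None = None
    reverse_coded: bool = False
    distribution: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if "_" in self.name:
            raise ValueError(f"variable name {self.name!r} may not contain '_'")
        if self.kind in ("ordinal", "binary"):
            if not self.levels:
                raise ValueError(f"{self.name}: {self.kind} variable needs levels")
            if self.kind == "binary" and len(self.levels) != 2:
                raise ValueError(f"{self.name}: binary variable needs 2 levels")
            probs = self.distribution.get("probs")
            if probs is not None:
                if len(probs) != len(self.levels):
                    raise ValueError(f"{self.name}: probs/levels length mismatch")
                if abs(sum(probs) - 1.0) > 1e-8:
                    raise ValueError(f"{self.name}: probs must sum to 1")
        elif self.bounds is None:
            raise ValueError(f"{self.name}: continuous variable needs bounds")

    @property
    def max_level(self) -> int:
        if self.levels is None:
            raise ValueError(f"{self.name} has no levels")
        return max(self.levels)

    def admissible(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of values inside the declared level set / range."""
        v = np.asarray(values, dtype=float)
        ok = np.isnan(v)
        if self.kind == "continuous":
            lo, hi = self.bounds
            return ok | ((v >= lo) & (v <= hi))
        return ok | np.isin(v, np.asarray(self.levels, dtype=float))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` raw-coded values from the declared distribution."""
        if self.kind in ("ordinal", "binary"):
            probs = self.distribution.get("probs")
            if probs is None:
                probs = [1.0 / len(self.levels)] * len(self.levels)
            return rng.choice(np.asarray(self.levels, dtype=float), size=n, p=probs)
        fam = self.distribution.get("family", "truncnorm")
        lo, hi = self.bounds
        if fam == "truncnorm":
            m = float(self.distribution["mean"])
            s = float(self.distribution["sd"])
            a, b = (lo - m) / s, (hi - m) / s
            return stats.truncnorm.rvs(a, b, loc=m, scale=s, size=n, random_state=rng)
        if fam == "lognormal":
            draws = rng.lognormal(
                float(self.distribution["mu"]), float(self.distribution["sigma"]), n
            )
            return np.clip(draws, lo, hi)
        raise ValueError(f"{self.name}: unknown distribution family {fam!r}")


@dataclass
class SurveyTable:
    """Respondents x variables in original codings, with provenance log."""

    data: pd.DataFrame
    specs: dict[str, VariableSpec]
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in self.specs]
        if missing:
            raise ValueError(f"columns without a VariableSpec: {missing}")
        self.specs = {c: self.specs[c] for c in self.data.columns}

    @property
    def n(self) -> int:
        return len(self.data)

    def variables(self) -> list[str]:
        return list(self.data.columns)

    def evolve(self, data: pd.DataFrame, entry: dict) -> "SurveyTable":
        """Return a new table with ``entry`` appended to the transform log."""
        specs = {c: self.specs[c] for c in data.columns}
        return SurveyTable(data=data, specs=specs, log=self.log + [entry])

    def validate(self) -> None:
        for name, spec in self.specs.items():
            bad = ~spec.admissible(self.data[name].to_numpy())
            if bad.any():
                raise ValueError(
                    f"{name}: {int(bad.sum())} values outside the admissible set"
                )

    # ----- I/O -------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(
        cls, path: str | Path, specs: Mapping[str, VariableSpec]
    ) -> "SurveyTable":
        data = pd.read_csv(path)
        return cls(data=data, specs=dict(specs), log=[{"op": "read_csv", "path": str(path)}])


# ---------------------------------------------------------------------------
# Spec (de)serialisation


def specs_to_yaml(specs: Mapping[str, VariableSpec], path: str | Path) -> None:
    out = []
    for s in specs.values():
        d = {
            "name": s.name,
            "kind": s.kind,
            "reverse_coded": s.reverse_coded,
            "distribution": dict(s.distribution),
        }
        if s.levels is not None:
            d["levels"] = list(s.levels)
        if s.bounds is not None:
            d["bounds"] = list(s.bounds)
        out.append(d)
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def specs_from_yaml(path: str | Path) -> dict[str, VariableSpec]:
    raw = yaml.safe_load(Path(path).read_text())
    specs = {}
    for d in raw:
        specs[d["name"]] = VariableSpec(
            name=d["name"],
            kind=d["kind"],
            levels=tuple(d["levels"]) if "levels" in d else None,
            bounds=tuple(d["bounds"]) if "bounds" in d else None,
            reverse_coded=bool(d.get("reverse_coded", False)),
            distribution=d.get("distribution", {}),
        )
    return specs


# ---------------------------------------------------------------------------
# Default instrument


def _ordinal(name, probs, reverse=False, levels=None):
    levels = tuple(levels or range(1, len(probs) + 1))
    return VariableSpec(
        name=name, kind="ordinal", levels=levels, reverse_coded=reverse,
        distribution={"probs": list(probs)},
    )


def _binary(name, p_one):
    return VariableSpec(
        name=name, kind="binary", levels=(0, 1),
        distribution={"probs": [1.0 - p_one, p_one]},
    )


def _ladder_probs(levels: Iterable[int], mean: float, sd: float) -> list[float]:
    x = np.asarray(list(levels), dtype=float)
    w = np.exp(-0.5 * ((x - mean) / sd) ** 2)
    w = w / w.sum()
    return [float(p) for p in w]


def default_variable_specs() -> dict[str, VariableSpec]:
    """The 18-variable instrument the analysis was designed around.

    Categorical probabilities and continuous-law parameters are chosen so the
    simulated marginals approximate the published descriptive statistics of
    the survey wave (means/SDs/ranges); income is log-normal to match its
    extreme right skew.  Raw codings are emitted: the three reverse-coded
    items (job satisfaction, autonomy, sleep quality) run high-raw = low
    construct until prep flips them.
    """
    specs = [
        # outcome: job satisfaction, 1-5, reverse coded
        _ordinal("Jobs", [0.02, 0.10, 0.35, 0.43, 0.10], reverse=True),
        VariableSpec(
            name="workt", kind="continuous", bounds=(0.0, 84.0),
            distribution={"family": "truncnorm", "mean": 48.35, "sd": 17.06},
        ),
        _ordinal("Selfd", [0.15, 0.45, 0.28, 0.12], reverse=True),   # autonomy 1-4
        _ordinal("Workf", [0.03, 0.07, 0.14, 0.30, 0.46]),           # work-family conflict
        _ordinal("Famw", [0.01, 0.02, 0.08, 0.31, 0.58]),            # family-work conflict
        VariableSpec(
            name="Roadt", kind="continuous", bounds=(0.0, 480.0),
            distribution={"family": "lognormal", "mu": 2.9, "sigma": 1.0},
        ),
        VariableSpec(
            name="income", kind="continuous", bounds=(0.0, 1_500_000.0),
            distribution={"family": "lognormal", "mu": 10.62, "sigma": 1.14},
        ),
        _ordinal("class", _ladder_probs(range(1, 11), 4.5, 1.65)),   # 1-10 ladder
        _ordinal("fair", [0.04, 0.12, 0.31, 0.43, 0.10]),
        _ordinal("Trusto", [0.03, 0.09, 0.23, 0.50, 0.15]),
        _ordinal("Sleepq", [0.17, 0.65, 0.15, 0.03], reverse=True),  # 1-4, 1 = very good
        VariableSpec(
            name="sleept", kind="continuous", bounds=(6.0, 12.0),
            distribution={"family": "truncnorm", "mean": 7.44, "sd": 0.94},
        ),
        _binary("marry", 0.77),
        _binary("gender", 0.502),
        _binary("Partj", 0.071),
        VariableSpec(
            name="age", kind="continuous", bounds=(18.0, 65.0),
            distribution={"family": "truncnorm", "mean": 40.07, "sd": 11.44},
        ),
        # education recoded to 5 bands; probabilities from the published
        # sample composition (below HS / HS / associate / bachelor / graduate)
        _ordinal("edul", [0.117, 0.393, 0.055, 0.134, 0.301]),
        _ordinal("health", [0.02, 0.05, 0.22, 0.49, 0.22]),          # 1-5
    ]
    return {s.name: s for s in specs}


REVERSE_CODED_DEFAULT = ("Jobs", "Selfd", "Sleepq")
OUTCOME_DEFAULT = "Jobs"
WORKTIME_DEFAULT = "workt"
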