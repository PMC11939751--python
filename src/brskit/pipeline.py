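"""End-to-end orchestration: simulate/ingest → prep → mine → fit → bootstrap
→ optional mediation/baselines, with a manifest and deterministic seeding.

Every stage draws its seed deterministically from the master seed via
``numpy.random.SeedSequence`` spawning, so reruns with the same config are
byte-identical and stages remain individually reproducible.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baselines as bl
from . import causal, data_prep, stability, synthetic_data
from .brs_inference import ChainConfig, LikelihoodParams, PriorParams, fit, pool_scaled_prior
from .rule_mining import MiningConfig, mine_candidates, pool_to_tsv, rule_cover
from .survey import OUTCOME_DEFAULT, SurveyTable, specs_from_yaml

log = logging.getLogger("brskit")


@dataclasses.dataclass
class RunConfig:
    seed: int
    out_dir: str
    input_csv: str | None = None          # ingest mode
    spec_yaml: str | None = None
    simulation: synthetic_data.SimulationConfig | None = None  # simulate mode
    missing_threshold: float = 0.10
    mining: MiningConfig = dataclasses.field(default_factory=MiningConfig)
    prior: PriorParams | None = None  # None -> pool-scaled Poisson prior
    likelihood: LikelihoodParams = dataclasses.field(default_factory=LikelihoodParams)
    chains: ChainConfig = dataclasses.field(default_factory=ChainConfig)
    bootstrap_B: int = 100
    prevalence_threshold: float = 0.05
    run_mediation: bool = False
    mediation_core: str = "Sleepq"        # core variable defining the high group
    mediation_mediator: str = "health"
    run_baselines: bool = False

    def __post_init__(self) -> None:
        if self.input_csv is None and self.simulation is None:
            raise ValueError("config needs either input_csv or a simulation block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = None
        if "simulation" in raw:
            s = dict(raw["simulation"])
            rules = []
            for r in s.pop("planted_rules", []):
                rules.append(
                    synthetic_data.PlantedRule(
                        literals=tuple(
                            synthetic_data.PlantedLiteral(
                                l["variable"], str(l["category"]),
                                bool(l.get("polarity", True)),
                            )
                            for l in r["literals"]
                        ),
                        target_support=r.get("target_support"),
                    )
                )
            sim = synthetic_data.SimulationConfig(
                planted_rules=tuple(rules), **s
            )
        kw = {k: v for k, v in raw.items() if k not in
              ("simulation", "mining", "prior", "likelihood", "chains")}
        return cls(
            simulation=sim,
            mining=MiningConfig(**raw.get("mining", {})),
            prior=PriorParams(**{
                k: tuple(v) if k == "length_weights" else v
                for k, v in raw.get("prior", {}).items()
            }) if "prior" in raw else None,
            likelihood=LikelihoodParams(**raw.get("likelihood", {})),
            chains=ChainConfig(**{
                k: tuple(v) if k == "move_probs" else v
                for k, v in raw.get("chains", {}).items()
            }),
            **kw,
        )


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence(master).spawn(stage + 1)[stage].generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage, writing artifacts + manifest into the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    stage = "simulate/ingest"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=_stage_seed(config.seed, 0))
            table, truth = synthetic_data.generate_survey(sim)
            if sim.missing_rates:
                table = synthetic_data.inject_missingness(
                    table, sim.missing_rates, _stage_seed(config.seed, 1)
                )
            if sim.outlier_rate > 0:
                table = synthetic_data.inject_outliers(
                    table, sim.outlier_rate, _stage_seed(config.seed, 2)
                )
            synthetic_data.write_simulation(table, truth, out)
            outcome = sim.outcome_name
        else:
            specs = specs_from_yaml(config.spec_yaml)
            table = SurveyTable.read_csv(config.input_csv, specs)
            outcome = OUTCOME_DEFAULT
        manifest["stages"]["input"] = {"rows": table.n, "variables": len(table.variables())}

        stage = "prep"
        prepared, matrix = data_prep.prepare(
            table, missing_threshold=config.missing_threshold, outcome_name=outcome
        )
        matrix.to_csv(out / "binary_matrix.csv")
        (out / "transform_log.json").write_text(json.dumps(prepared.log, indent=2, default=str))
        manifest["stages"]["prep"] = {
            "rows": matrix.n, "features": len(matrix.names), "cutoff": matrix.cutoff,
        }

        stage = "mine"
        pool = mine_candidates(matrix.features, matrix.outcome, config.mining)
        pool_to_tsv(pool, matrix.features, matrix.outcome, out / "pool.tsv")
        manifest["stages"]["mine"] = {"pool_size": len(pool)}

        stage = "fit"
        chains = dataclasses.replace(config.chains, seed=_stage_seed(config.seed, 3))
        prior = config.prior if config.prior is not None else pool_scaled_prior(len(pool))
        result = fit(matrix.features, matrix.outcome, pool,
                     prior, config.likelihood, chains)
        result.to_json(out / "fit.json")
        manifest["stages"]["fit"] = {
            "map_rules": sorted(r.describe() for r in result.map_ruleset.rules),
            "map_score": result.map_score,
        }

        stage = "bootstrap"
        report = stability.bootstrap_stability(
            matrix.features, matrix.outcome,
            mining=config.mining, prior=config.prior, lik=config.likelihood,
            chains=config.chains, B=config.bootstrap_B,
            seed=_stage_seed(config.seed, 4),
            prevalence_threshold=config.prevalence_threshold,
        )
        report.to_tsv(out / "stability.tsv")
        report.to_json(out / "stability.json")
        stability.interaction_edges(report).to_csv(
            out / "interaction_edges.tsv", sep="\t", index=False
        )
        labels_df = pd.DataFrame(
            {"outcome": matrix.outcome,
             "confusion": stability.classification_outcomes(
                 report.aggregated, matrix.features, matrix.outcome)}
        )
        labels_df.to_csv(out / "classification_outcomes.tsv", sep="\t", index=False)
        manifest["stages"]["bootstrap"] = {
            "B": report.B,
            "aggregated_rules": sorted(r.describe() for r in report.aggregated.rules),
        }

        if config.run_mediation:
            stage = "mediate"
            manifest["stages"]["mediate"] = _mediate(config, prepared, matrix, report, out)
        if config.run_baselines:
            stage = "baselines"
            manifest["stages"]["baselines"] = _baselines(config, matrix, out)
    except Exception as e:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        log.error("pipeline failed at stage %s: %s", stage, e)
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _mediate(config, prepared, matrix, report, out: Path) -> dict:
    rules = sorted(report.aggregated.rules, key=lambda r: r.key)
    data = pd.DataFrame(index=range(matrix.n))
    names = []
    for i, r in enumerate(rules, 1):
        name = f"Rule{i}"
        data[name] = rule_cover(r, matrix.features)
        names.append(name)
    core = prepared.data[config.mediation_core].to_numpy(dtype=float)
    T = causal.assign_treatment(core)
    model = causal.estimate_propensity(
        prepared.data.drop(columns=[config.mediation_core, config.mediation_mediator,
                                    matrix.outcome_name]),
        T.T,
    )
    wv = causal.ipw_weights(model.scores, T.T)
    data["T"] = T.T
    data["M"] = prepared.data[config.mediation_mediator].to_numpy(dtype=float)
    data["Y"] = prepared.data[matrix.outcome_name].to_numpy(dtype=float)
    spec = causal.MediationSpec(
        outcome="Y", mediator="M", treatment="T", rule_indicators=names
    )
    res = causal.mediation_fit(data, spec)
    res.to_json(out / "mediation.json")
    pd.DataFrame({"weight": wv.weights, "extreme": wv.extreme}).to_csv(
        out / "ipw_weights.tsv", sep="\t", index=False
    )
    return {"rules": [r.describe() for r in rules],
            "extreme_weights": int(wv.extreme.sum())}


def _baselines(config, matrix, out: Path) -> dict:
    seed = _stage_seed(config.seed, 5)
    tree_rules, _ = bl.tree_to_rules(matrix.features, matrix.outcome, seed=seed)
    imp = bl.forest_importance(matrix.features, matrix.outcome, seed=seed)
    imp.to_csv(out / "forest_importance.tsv", sep="\t", index=False)
    (out / "tree_rules.json").write_text(json.dumps(
        [sorted(r.literals) for r in tree_rules.rules], indent=2))
    lasso = bl.lasso_interaction_screen(matrix.features, matrix.outcome, seed=seed)
    lasso.to_csv(out / "lasso_terms.tsv", sep="\t")
    return {"tree_rules": len(tree_rules.rules), "lasso_terms": len(lasso)}


def compare_runs(dir_a: str | Path, dir_b: str | Path) -> dict:
    """Concordance of two completed runs: Jaccard of aggregated rule sets."""
    out = {}
    frames = []
    for label, d in (("a", Path(dir_a)), ("b", Path(dir_b))):
        f = d / "stability.json"
        if not f.exists():
            raise FileNotFoundError(f"incomplete run directory: {d}")
        rep = stability.StabilityReport.from_json(f)
        out[label] = sorted(r.describe() for r in rep.aggregated.rules)
        df = rep.to_frame()[["literals", "prevalence"]]
        df = df.rename(columns={"prevalence": f"prevalence_{label}"})
        frames.append(df)
    sa = {tuple(sorted(r.split(" & "))) for r in out["a"]}
    sb = {tuple(sorted(r.split(" & "))) for r in out["b"]}
    union = sa | sb
    jaccard = len(sa & sb) / len(union) if union else 1.0
    table = frames[0].merge(frames[1], on="literals", how="outer").fillna(0.0)
    return {
        "jaccard": jaccard,
        "aggregated_a": out["a"],
        "aggregated_b": out["b"],
        "prevalence_table": table.to_dict(orient="records"),
    }
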