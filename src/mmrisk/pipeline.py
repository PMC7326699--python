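"""End-to-end challenge runs: simulate/load -> fit -> predict -> score -> rank.

A :class:`RunConfig` (YAML or JSON) names the cohorts (either a simulation
block or a fixture directory), the model specs, the threshold grid, the
bootstrap size and the master seed.  :func:`run_challenge` trains every model
on training cohorts only, predicts on validation cohorts only, evaluates them
through the challenge harness, ranks genes on the training cohorts, and writes
a leaderboard, a meta-z table and a run manifest.  Re-running the same config
and seed reproduces every output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .evaluate import (
    EvaluationResult,
    RiskPrediction,
    ThresholdGrid,
    bootstrap_wiauc,
    evaluate_model,
    leaderboard_frame,
    rank_models,
)
from .io import read_fixture, read_signature_file
from .metarank import MetaZTable, rank_genes
from .signatures import (
    BaselineClinicalModel,
    FourFeatureCoxModel,
    RandomScoreModel,
    SignatureRiskModel,
)
from .simulate import Cohort, SimulationConfig, simulate_challenge

__all__ = ["RunConfig", "RunResult", "run_challenge", "build_model"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Everything one reproducible challenge run needs."""

    models: list[dict]
    simulation: SimulationConfig | None = None
    cohort_dir: str | None = None
    n_train: int = 4
    n_validation: int = 4
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    n_bootstrap: int = 1000
    seed: int = 0
    output_dir: str = "mmrisk_run"
    include_validation_in_ranking: bool = False
    ranking_endpoint: str = "pfs"
    ranking_weighting: str = "high_risk_count"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.models:
            raise ConfigError("at least one model spec is required")
        if self.simulation is None and self.cohort_dir is None:
            raise ConfigError("config needs either a simulation block or "
                              "a cohort_dir")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if raw.get("simulation"):
            raw["simulation"] = SimulationConfig.from_dict(raw["simulation"])
        if raw.get("grid"):
            raw["grid"] = ThresholdGrid(**raw["grid"])
        cfg = cls(**raw)
        for spec in cfg.models:
            if spec.get("type") == "signature":
                p = Path(spec["file"])
                if not p.exists():
                    raise ConfigError(f"signature file not found: {p}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        d["grid"] = dataclasses.asdict(self.grid)
        return d

    def content_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    leaderboard: pd.DataFrame
    evaluations: list[EvaluationResult]
    meta_z: MetaZTable
    output_files: dict[str, str]


def build_model(spec: dict, seed: int = 0):
    """Instantiate a risk model from a config spec dict."""
    kind = spec.get("type")
    if kind == "baseline":
        return BaselineClinicalModel(
            use_age=spec.get("use_age", True),
            use_iss=spec.get("use_iss", True),
            model_id=spec.get("model_id", "baseline"),
        )
    if kind == "four_feature":
        return FourFeatureCoxModel(
            phf19_gene=spec.get("phf19_gene", "PHF19"),
            mmset_gene=spec.get("mmset_gene", "MMSET"),
            model_id=spec.get("model_id", "four_feature"),
        )
    if kind == "signature":
        signature = read_signature_file(spec["file"], name=spec.get("name"))
        return SignatureRiskModel(
            signature,
            use_age=spec.get("use_age", False),
            use_iss=spec.get("use_iss", False),
            model_id=spec.get("model_id"),
        )
    if kind == "noise":
        return RandomScoreModel(seed=spec.get("seed", seed),
                                model_id=spec.get("model_id", "noise"))
    raise ConfigError(f"unknown model type {kind!r}")


def _load_cohorts(config: RunConfig) -> tuple[list[Cohort], list[Cohort]]:
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation)
        return simulate_challenge(sim, config.n_train, config.n_validation)
    cohorts, _ = read_fixture(config.cohort_dir)
    if config.n_train + config.n_validation != len(cohorts):
        raise ConfigError(
            f"fixture has {len(cohorts)} cohorts; n_train + n_validation = "
            f"{config.n_train + config.n_validation}"
        )
    return cohorts[: config.n_train], cohorts[config.n_train:]


def run_challenge(config: RunConfig) -> RunResult:
    """Execute one full challenge run and write its reports.

    Stages: load/simulate cohorts; fit models on training cohorts only;
    predict on validation cohorts only; point + bootstrap evaluation; Bayes
    factor tie detection and ranking; gene meta-z ranking on training cohorts
    (plus validation if configured); leaderboard/meta-z/manifest output.
    """
    logging.basicConfig(level=config.log_level)
    train, validation = _load_cohorts(config)
    if not validation:
        raise ConfigError("no validation cohorts: refusing to evaluate on "
                          "training data")
    if not train:
        raise ConfigError("no training cohorts")
    train_ids = {c.cohort_id for c in train}
    val_ids = {c.cohort_id for c in validation}
    if train_ids & val_ids:
        raise ConfigError(f"cohort id overlap: {sorted(train_ids & val_ids)}")
    logger.info("stage=load train=%d validation=%d", len(train), len(validation))

    models = [build_model(spec, seed=config.seed) for spec in config.models]
    ids = [m.model_id for m in models]
    if len(set(ids)) != len(ids):
        raise ConfigError(f"duplicate model ids: {ids}")

    predictions: list[RiskPrediction] = []
    for model in models:
        logger.info("stage=fit model=%s", model.model_id)
        try:
            model.fit(train)
        except Exception as exc:
            raise RuntimeError(
                f"stage=fit model={model.model_id}: {exc}"
            ) from exc
        for cohort in validation:
            try:
                scores = model.predict(cohort)
            except Exception as exc:
                raise RuntimeError(
                    f"stage=predict model={model.model_id} "
                    f"cohort={cohort.cohort_id}: {exc}"
                ) from exc
            predictions.append(
                RiskPrediction(model.model_id, cohort.cohort_id, scores)
            )

    logger.info("stage=evaluate B=%d", config.n_bootstrap)
    evaluations = [
        evaluate_model(m.model_id, predictions, validation, config.grid)
        for m in models
    ]
    draws = bootstrap_wiauc(
        predictions, validation, config.grid,
        B=config.n_bootstrap, seed=config.seed,
    )
    for ev in evaluations:
        ev.bootstrap_wiaucs = draws[ev.model_id]
    evaluations = rank_models(evaluations)
    leaderboard = leaderboard_frame(evaluations)

    ranking_cohorts = train + (validation if config.include_validation_in_ranking
                               else [])
    logger.info("stage=rank_genes cohorts=%d endpoint=%s",
                len(ranking_cohorts), config.ranking_endpoint)
    meta_z = rank_genes(
        ranking_cohorts,
        endpoint=config.ranking_endpoint,
        weighting=config.ranking_weighting,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    lb_csv = out / "leaderboard.csv"
    leaderboard.to_csv(lb_csv, index=False, float_format=_FLOAT_FMT)
    files["leaderboard_csv"] = str(lb_csv)
    lb_json = out / "leaderboard.json"
    lb_json.write_text(
        json.dumps(
            json.loads(leaderboard.to_json(orient="records")),
            indent=2, sort_keys=True,
        ) + "\n"
    )
    files["leaderboard_json"] = str(lb_json)
    mz_csv = out / "meta_z.csv"
    meta_z.to_csv(mz_csv)
    files["meta_z_csv"] = str(mz_csv)
    mz_json = out / "meta_z.json"
    meta_z.to_json(mz_json)
    files["meta_z_json"] = str(mz_json)

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "models": ids,
        "train_cohorts": sorted(train_ids),
        "validation_cohorts": sorted(val_ids),
        "seed_streams": {
            "simulation": "SeedSequence(simulation.seed, spawn_key=(0|1, cohort))",
            "bootstrap": f"SeedSequence({config.seed})",
            "noise_models": f"SeedSequence({config.seed}, spawn_key=(crc32(cohort_id),))",
        },
        "files": files,
    }
    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    files["manifest"] = str(manifest_path)
    return RunResult(leaderboard, evaluations, meta_z, files)
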