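"""Pipeline configuration and end-to-end orchestration.

One structured YAML config drives the whole pipeline: curation rules,
featurization, splitting, tuning budget, validation protocols, and
profiling thresholds. Defaults follow the reference protocol wherever it
states a value (80/20 stratified split, 5-fold CV, 90/10 bootstrap,
Tc > 0.7 applicability domain, concern cutoff 6.5, EF at 1/5/10% with 2%
active labeling); iteration counts default to a desk-scale 20 with the
full-scale 100 available as the ``paper`` preset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from . import curation, featurization, modeling, profiling, validation
from .splitting import SplitSpec, split_dataset


log = logging.getLogger("liabprof")

#: Full-scale iteration count used by the reference protocol.
PAPER_ITERATIONS = 100
#: Full-scale tuning wall-clock budget (seconds) used by the reference protocol.
PAPER_TIME_BUDGET = 100 * 60.0


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters; every field is YAML-serialisable."""

    seed: int = 0
    # curation
    activity_types: list[str] = field(default_factory=lambda: ["IC50", "EC50", "Ki", "Kd"])
    # splitting
    split_strategy: str = "stratified"
    train_fraction: float = 0.8
    # tuning
    tune: bool = True
    algorithms: list[str] = field(default_factory=lambda: ["mlr", "rf", "gb"])
    tune_n_init: int = 8
    tune_population: int = 8
    tune_generations: int = 5
    tune_stagnation: int = 5
    tune_time_budget: float = 300.0
    # validation
    protocols: list[str] = field(default_factory=lambda: ["cv", "bootstrap", "y_scrambling"])
    iterations: int = 20
    cv_folds: int = 5
    bootstrap_holdout: float = 0.1
    ef_levels: list[float] = field(default_factory=lambda: [0.01, 0.05, 0.10])
    active_fraction: float = 0.02
    # profiling
    ad_threshold: float = 0.7
    concern_cutoff: float = 6.5
    mapping_file: str | None = None
    profile_smiles: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1): an external test set is required")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        unknown = set(self.algorithms) - {"mlr", "rf", "gb"}
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def paper_preset(cls, **overrides) -> "PipelineConfig":
        """Full-scale preset: 100 validation iterations, 100-min tuning budget."""
        base = dict(iterations=PAPER_ITERATIONS, tune_time_budget=PAPER_TIME_BUDGET)
        base.update(overrides)
        return cls(**base)


def run_pipeline(config: PipelineConfig, raw_path, outdir) -> dict:
    """Run curation -> features -> splitting -> tuning/training -> validation
    -> champion selection (-> profiling) on a raw activity table.

    Writes per-stage artifacts under ``outdir`` and returns a summary dict
    (also written as ``summary.json``). Deterministic under the config seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rules = curation.FilterRules(activity_types=frozenset(config.activity_types))
    grouped = curation.read_records_csv(raw_path)
    registry: dict[str, modeling.QSARRegressor] = {}
    summary: dict = {"config": asdict(config), "targets": {}}

    for target, records in sorted(grouped.items()):
        log.info("curating target %s (%d raw records)", target, len(records))
        ds = curation.curate(records, rules, target_id=target or "T")
        tname = target or "T"
        tdir = outdir / tname
        tdir.mkdir(exist_ok=True)
        curation.write_curated_csv(ds, tdir / "curated.csv", tdir / "provenance.json")

        X, _ = featurization.build_feature_matrix(ds)
        fps = featurization.similarity_matrix_from_smiles(ds.smiles)
        y = ds.pactivity
        spec = SplitSpec(config.split_strategy, config.train_fraction, config.seed)
        train_idx, test_idx = split_dataset(ds, spec)
        Xtr, ytr, Xte, yte = X[train_idx], y[train_idx], X[test_idx], y[test_idx]

        target_report: dict = {"n_compounds": len(ds), "n_train": len(train_idx),
                               "n_test": len(test_idx), "provenance": ds.provenance_log,
                               "models": {}}
        candidates = []
        for algo in config.algorithms:
            params = None
            if config.tune and algo in ("rf", "gb"):
                tuner = modeling.GeneticTuner(
                    algorithm=algo,
                    n_init=config.tune_n_init,
                    population_size=config.tune_population,
                    max_generations=config.tune_generations,
                    stagnation_limit=config.tune_stagnation,
                    time_budget=config.tune_time_budget,
                    cv=config.cv_folds,
                    seed=config.seed,
                ).fit(Xtr, ytr)
                params = tuner.best_params_
            model = modeling.fit_model(Xtr, ytr, algo, params, config.seed,
                                       fingerprints=fps[train_idx])
            ext = validation.external_validate(model, Xte, yte, train_idx, test_idx)
            report = {"external": ext.as_dict(), "hyperparameters": params,
                      "ridge_fallback": bool(model.ridge_fallback_)}
            for protocol in config.protocols:
                rep = validation.internal_validate(
                    Xtr, ytr, algo, params, protocol,
                    iterations=config.iterations, seed=config.seed,
                    cv_folds=config.cv_folds, holdout_fraction=config.bootstrap_holdout,
                )
                report[protocol] = rep.as_dict()
            pred = model.predict(Xte)
            report["enrichment"] = {
                str(chi): asdict(validation.enrichment_factor(
                    yte, pred, chi, config.active_fraction, tiebreak=[ds.smiles[i] for i in test_idx]))
                for chi in config.ef_levels
            }
            target_report["models"][algo] = report
            if algo in ("rf", "gb"):
                candidates.append((model, ext.r_mean))
        champion = modeling.select_champion(candidates) if candidates else model
        target_report["champion"] = champion.algorithm
        registry[tname] = champion
        joblib.dump(champion, tdir / "champion.joblib")
        with open(tdir / "report.json", "w") as fh:
            json.dump(target_report, fh, indent=2)
        summary["targets"][tname] = target_report

    if config.profile_smiles:
        mapping = (profiling.LiabilityMapping.from_yaml(config.mapping_file)
                   if config.mapping_file else None)
        try:
            profiles = profiling.profile_compounds(
                config.profile_smiles, registry, mapping,
                cutoff=config.concern_cutoff, ad_threshold=config.ad_threshold,
            )
        except ValueError:
            # registry targets not present in the liability mapping: report
            # raw predictions only
            profiles = []
        summary["profiles"] = [asdict(p) if hasattr(p, "__dataclass_fields__") else p
                               for p in profiles]
        with open(outdir / "profiles.json", "w") as fh:
            json.dump(_jsonable(summary.get("profiles", [])), fh, indent=2)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2)
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj
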