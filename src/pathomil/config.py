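"""Experiment configuration and the seeded end-to-end runner.

An :class:`ExperimentConfig` (YAML-loadable, schema-validated with pydantic)
drives the whole synthetic experiment: generate a source/shifted cohort pair,
cross-validate on the source cohort per target, deploy the fold models on the
shifted cohort, run the cross-target sensitivity check, and export score
density summaries — with every stage seeded from a single top-level seed and
logged, and all resolved defaults written into the run manifest so each run is
self-describing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import evaluation, synthetic, training

log = logging.getLogger("pathomil")


class BagSection(BaseModel):
    n_patients: int = 200
    tiles_min: int = 100
    tiles_max: int = 300
    feature_dim: int = 64
    witness_rate: float = Field(0.1, gt=0.0, le=1.0)
    effect_size: float = Field(2.0, ge=0.0)
    prevalences: dict[str, float] = Field(
        default_factory=lambda: dict(synthetic.DEFAULT_PREVALENCES)
    )
    label_correlation: float = Field(0.0, ge=-1.0, le=1.0)

    @field_validator("prevalences")
    @classmethod
    def _check_prev(cls, v):
        for t, p in v.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"prevalence for {t} must be in (0,1)")
        return v


class ShiftSection(BaseModel):
    mode: str = "label_decoupling"
    decoupling_fraction: float = Field(0.7, ge=0.0, le=1.0)


class TrainSection(BaseModel):
    K: int = 512
    epochs: int = 32
    max_lr: float = 1e-4
    warmup_epochs: int = 8
    weight_decay: float = 0.01
    batch_patients: int = 64
    momentum_inverted: bool = False
    class_weighting: bool = False


class ExperimentConfig(BaseModel):
    """Validated top-level configuration (see module docstring)."""

    out_dir: str = "results"
    seed: int = 0
    targets: list[str] = Field(default_factory=lambda: ["ER", "PR"])
    normalisation: bool = True
    k_folds: int = 5
    n_perm: int = 1000
    bag: BagSection = Field(default_factory=BagSection)
    shift: ShiftSection = Field(default_factory=ShiftSection)
    train: TrainSection = Field(default_factory=TrainSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic fan-out of one top-level seed into per-stage seeds."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _bag_spec(cfg: ExperimentConfig, seed: int) -> synthetic.BagSpec:
    b = cfg.bag
    return synthetic.BagSpec(
        n_patients=b.n_patients,
        tiles_per_patient_range=(b.tiles_min, b.tiles_max),
        feature_dim=b.feature_dim,
        witness_rate=b.witness_rate,
        effect_size=b.effect_size,
        prevalence=dict(b.prevalences),
        label_correlation=b.label_correlation,
        seed=seed,
    )


def _train_cfg(cfg: ExperimentConfig, seed: int) -> training.TrainConfig:
    t = cfg.train
    return training.TrainConfig(
        K=t.K,
        epochs=t.epochs,
        max_lr=t.max_lr,
        warmup_epochs=t.warmup_epochs,
        weight_decay=t.weight_decay,
        batch_patients=t.batch_patients,
        momentum_inverted=t.momentum_inverted,
        class_weighting=t.class_weighting,
        seed=seed,
    )


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full synthetic experiment described by ``cfg``.

    Returns (and writes to ``<out_dir>/manifest.json``) a summary mapping each
    stage to its outputs; any stage failure surfaces as an exception naming
    the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    manifest: dict = {
        "config": cfg.model_dump(),
        "stage_seeds": seeds,
        "stages": {},
        "reports": {},
    }
    log.info("stage simulate: cohort pair (seed %d)", seeds[0])
    try:
        pair = synthetic.generate_cohort_pair(
            _bag_spec(cfg, seeds[0]),
            synthetic.ShiftSpec(
                mode=cfg.shift.mode, decoupling_fraction=cfg.shift.decoupling_fraction
            ),
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage name
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    manifest["stages"]["simulate"] = {
        "n_source": len(pair.source),
        "n_shifted": len(pair.shifted),
        "expect_auroc_drop": pair.expect_auroc_drop,
    }

    all_reports = []
    models_by_target = {}
    for i, target in enumerate(cfg.targets):
        tcfg = _train_cfg(cfg, seeds[1] + i)
        log.info("stage crossval: target %s", target)
        try:
            models, cv_report, plan, hists = evaluation.cross_validate(
                pair.source, target, tcfg, k=cfg.k_folds, seed=seeds[2] + i,
                n_perm=cfg.n_perm, cohort="source",
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'crossval[{target}]' failed: {exc}") from exc
        models_by_target[target] = models
        cv_report.normalised = cfg.normalisation
        cv_report.scores.to_csv(out / f"cv_scores_{target}.csv", index=False)
        cv_report.to_json(out / f"cv_report_{target}.json")
        for f, h in enumerate(hists):
            h.to_frame().to_csv(out / f"train_log_{target}_fold{f}.csv", index=False)
        log.info("stage deploy: target %s on shifted cohort", target)
        try:
            dep_report = evaluation.deploy(
                models, pair.shifted, target, n_perm=cfg.n_perm,
                seed=seeds[3] + i, cohort="shifted",
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'deploy[{target}]' failed: {exc}") from exc
        dep_report.normalised = cfg.normalisation
        dep_report.scores.to_csv(out / f"deploy_scores_{target}.csv", index=False)
        dep_report.to_json(out / f"deploy_report_{target}.json")
        all_reports.extend([cv_report, dep_report])
        manifest["reports"][target] = {
            "cv_mean_auroc": cv_report.mean_auroc,
            "cv_sd_auroc": cv_report.sd_auroc,
            "cv_p_value": cv_report.p_value,
            "deploy_mean_auroc": dep_report.mean_auroc,
            "deploy_sd_auroc": dep_report.sd_auroc,
            "auroc_drop": cv_report.mean_auroc - dep_report.mean_auroc,
        }

    if len(cfg.targets) >= 2:
        a, b = cfg.targets[0], cfg.targets[1]
        log.info("stage crosstarget: %s model vs %s labels (and vice versa)", a, b)
        try:
            rep_ab = evaluation.cross_target_eval(
                models_by_target[a], pair.source, b, score_target=a,
                n_perm=cfg.n_perm, seed=seeds[4], cohort="source",
            )
            rep_ba = evaluation.cross_target_eval(
                models_by_target[b], pair.source, a, score_target=b,
                n_perm=cfg.n_perm, seed=seeds[4] + 1, cohort="source",
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'crosstarget' failed: {exc}") from exc
        manifest["reports"]["cross_target"] = {
            f"{a}_model_on_{b}_labels": rep_ab.mean_auroc,
            f"{b}_model_on_{a}_labels": rep_ba.mean_auroc,
        }

    log.info("stage densities")
    density = evaluation.score_density_summary(all_reports)
    density.to_csv(out / "score_densities.csv", index=False)
    manifest["stages"]["densities"] = {"path": "score_densities.csv"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
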