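"""Patient-level evaluation: stratified cross-validation, AUROC with
permutation p-values, external deployment, cross-target sensitivity, and
prediction-score density diagnostics for domain shift.

The primary endpoint throughout is the AUROC computed at patient level (one
score per patient).  Cross-validated performance is reported as the mean and
standard deviation across the five fold models; external cohorts are scored
by each fold model independently and summarised the same way.  Significance
against chance is assessed with a two-sided label-permutation test of
``|AUROC - 0.5|``, which is distribution-free and needs no assumption about
the score distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import FeatureBag
from .model import AttMILParams, predict_scores


@dataclass
class FoldPlan:
    """Patient-disjoint stratified k-fold assignment with inner tune subsets.

    ``assignments`` maps patient_id -> test-fold index; ``tune_subsets[f]`` is
    the quarter of fold ``f``'s training patients reserved to monitor
    overfitting (disjoint from fold ``f``'s test set by construction).
    """

    k: int
    assignments: dict[str, int]
    tune_subsets: dict[int, frozenset[str]]
    seed: int

    def test_patients(self, fold: int) -> list[str]:
        return [p for p, f in self.assignments.items() if f == fold]

    def train_patients(self, fold: int) -> list[str]:
        """Training patients of ``fold`` excluding its tune subset."""
        tune = self.tune_subsets[fold]
        return [p for p, f in self.assignments.items() if f != fold and p not in tune]


@dataclass
class EvalReport:
    """AUROC summary for one cohort/target, plus the per-patient score table."""

    cohort: str
    target: str
    per_model_auroc: list[float]
    mean_auroc: float
    sd_auroc: float
    p_value: float
    scores: pd.DataFrame  # columns: patient_id, label, score (+ per-model cols)
    normalised: bool | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "cohort": self.cohort,
            "target": self.target,
            "per_model_auroc": self.per_model_auroc,
            "mean_auroc": self.mean_auroc,
            "sd_auroc": self.sd_auroc,
            "p_value": self.p_value,
            "normalised": self.normalised,
            **self.extra,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


# ---------------------------------------------------------------------------
# folds


def make_folds(
    patients: Sequence[str],
    labels: Sequence[int],
    k: int = 5,
    seed: int = 0,
    tune_fraction: float = 0.25,
) -> FoldPlan:
    """Biomarker-stratified k-fold partition of patients.

    Test folds partition the cohort with per-fold label ratios within one
    patient of the global ratio; within each fold's training patients a
    stratified ``tune_fraction`` (rounded) is reserved for tuning.  Raises a
    descriptive error when a class has fewer than ``k`` members.
    """
    patients = list(patients)
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"cannot stratify {k} folds: class counts {counts.tolist()} "
            f"(need >= {k} patients per class)"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments: dict[str, int] = {}
    tune_subsets: dict[int, frozenset[str]] = {}
    splits = list(skf.split(patients, y))
    for fold, (train_idx, test_idx) in enumerate(splits):
        for i in test_idx:
            assignments[patients[i]] = fold
    for fold, (train_idx, test_idx) in enumerate(splits):
        n_tune = int(round(tune_fraction * len(train_idx)))
        if n_tune >= 1 and len(np.unique(y[train_idx])) > 1:
            _, tune_idx = train_test_split(
                train_idx,
                test_size=n_tune,
                stratify=y[train_idx],
                random_state=seed + fold,
            )
        else:
            tune_idx = train_idx[:n_tune]
        tune_subsets[fold] = frozenset(patients[i] for i in tune_idx)
    return FoldPlan(k=k, assignments=assignments, tune_subsets=tune_subsets, seed=seed)


# ---------------------------------------------------------------------------
# AUROC


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Patient-level AUROC in its Mann-Whitney form.

    Equals (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg): the
    probability that a random positive patient is scored above a random
    negative one.  Computed from average ranks, which handles ties exactly.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: need both classes")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auroc_pvalue(
    scores: Sequence[float],
    labels: Sequence[int],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided label-permutation p-value for AUROC vs chance.

    Permutes labels ``n_perm`` times, recomputes AUROC, and reports
    ``p = (1 + #{|AUROC_perm - 0.5| >= |AUROC_obs - 0.5|}) / (1 + n_perm)``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    obs = abs(auroc(s, y) - 0.5)
    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(s)
    n = len(y)
    n_pos = int((y == 1).sum())
    n_neg = n - n_pos
    base = n_pos * (n_pos + 1) / 2.0
    # vectorised label permutations: each row of a random matrix argsorted
    # yields a uniform permutation; the first n_pos columns are the permuted
    # positives, whose rank sum gives the permuted AUROC directly
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_pos]
    perm_auc = (ranks[perm_idx].sum(axis=1) - base) / (n_pos * n_neg)
    count = int(np.sum(np.abs(perm_auc - 0.5) >= obs - 1e-12))
    return float((1 + count) / (1 + n_perm))


def delong_pvalue(scores: Sequence[float], labels: Sequence[int]) -> float:
    """DeLong-style p-value for AUROC vs 0.5 via the Mann-Whitney normal
    approximation (alternative to the permutation test)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    res = stats.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# cross-validation / deployment


def _bags_by_id(bags: Sequence[FeatureBag]) -> dict[str, FeatureBag]:
    return {b.patient_id: b for b in bags}


def _labelled(bags: Sequence[FeatureBag], target: str) -> list[FeatureBag]:
    """Patients with a known label for ``target``; others are excluded."""
    return [b for b in bags if b.labels.get(target) is not None]


def cross_validate(
    bags: Sequence[FeatureBag],
    target: str,
    cfg,
    k: int = 5,
    seed: int = 0,
    fold_plan: FoldPlan | None = None,
    n_perm: int = 1000,
    cohort: str = "source",
) -> tuple[list[AttMILParams], EvalReport, FoldPlan, list]:
    """Patient-level stratified k-fold cross-validation.

    One model per fold is trained on that fold's training patients (minus the
    tune quarter) and scored on its held-out test fold, so every patient is
    scored exactly once.  Returns the fold models, the aggregated report
    (mean +/- sd AUROC over folds; permutation p on the pooled out-of-fold
    scores), the fold plan and the per-fold training histories.
    """
    from . import training  # deferred: training depends on auroc above

    bags = _labelled(bags, target)
    by_id = _bags_by_id(bags)
    pids = [b.patient_id for b in bags]
    y = np.array([b.labels[target] for b in bags], dtype=int)
    if fold_plan is None:
        fold_plan = make_folds(pids, y, k=k, seed=seed)
    models, histories = [], []
    rows = []
    fold_aucs = []
    for fold in range(fold_plan.k):
        train_ids = fold_plan.train_patients(fold)
        tune_ids = sorted(fold_plan.tune_subsets[fold])
        test_ids = fold_plan.test_patients(fold)
        fold_cfg = training.TrainConfig(
            **{**training.config_dict(cfg), "seed": cfg.seed + fold}
        )
        params, hist = training.train_model(
            [by_id[p] for p in train_ids], [by_id[p] for p in tune_ids], fold_cfg,
            target=target,
        )
        models.append(params)
        histories.append(hist)
        test_bags = [by_id[p] for p in test_ids]
        scores = predict_scores([b.features for b in test_bags], params)
        labels = np.array([b.labels[target] for b in test_bags], dtype=int)
        fold_aucs.append(auroc(scores, labels))
        rows.extend(
            {"patient_id": p, "label": int(l), "score": float(s), "fold": fold}
            for p, l, s in zip(test_ids, labels, scores)
        )
    table = pd.DataFrame(rows)
    p = auroc_pvalue(table["score"], table["label"], n_perm=n_perm, seed=seed)
    report = EvalReport(
        cohort=cohort,
        target=target,
        per_model_auroc=[float(a) for a in fold_aucs],
        mean_auroc=float(np.mean(fold_aucs)),
        sd_auroc=float(np.std(fold_aucs, ddof=1)),
        p_value=p,
        scores=table,
    )
    return models, report, fold_plan, histories


def deploy(
    models: Sequence[AttMILParams],
    bags: Sequence[FeatureBag],
    target: str,
    n_perm: int = 1000,
    seed: int = 0,
    cohort: str = "external",
) -> EvalReport:
    """Deploy trained fold models on an external cohort.

    Each model scores the full cohort independently; the report summarises the
    per-model AUROCs (mean +/- sd) and attaches a permutation p-value computed
    on the ensemble-mean scores, which are also retained per patient for
    density diagnostics.
    """
    bags = _labelled(bags, target)
    if not bags:
        raise ValueError(f"no patients with known {target!r} labels")
    d = bags[0].dim
    for m in models:
        if m.input_dim != d:
            raise ValueError(
                f"extractor mismatch: model expects d={m.input_dim}, cohort has d={d}"
            )
    y = np.array([b.labels[target] for b in bags], dtype=int)
    feats = [b.features for b in bags]
    per_model_scores = np.stack([predict_scores(feats, m) for m in models])
    per_model_auc = [float(auroc(s, y)) for s in per_model_scores]
    mean_scores = per_model_scores.mean(axis=0)
    p = auroc_pvalue(mean_scores, y, n_perm=n_perm, seed=seed)
    table = pd.DataFrame(
        {"patient_id": [b.patient_id for b in bags], "label": y, "score": mean_scores}
    )
    for i, s in enumerate(per_model_scores):
        table[f"score_model{i}"] = s
    return EvalReport(
        cohort=cohort,
        target=target,
        per_model_auroc=per_model_auc,
        mean_auroc=float(np.mean(per_model_auc)),
        sd_auroc=float(np.std(per_model_auc, ddof=1)) if len(models) > 1 else 0.0,
        p_value=p,
        scores=table,
        extra={"ensemble_auroc": float(auroc(mean_scores, y))},
    )


def cross_target_eval(
    models: Sequence[AttMILParams],
    bags: Sequence[FeatureBag],
    label_target: str,
    score_target: str | None = None,
    **kwargs,
) -> EvalReport:
    """Evaluate models trained on one target against another target's labels.

    A model specific to its own biomarker should perform near chance here
    unless the two targets are correlated.  ``label_target`` names the labels
    to score against; raises when they are absent.
    """
    if not any(b.labels.get(label_target) is not None for b in bags):
        raise ValueError(f"cohort has no labels for target {label_target!r}")
    report = deploy(models, bags, label_target, **kwargs)
    report.extra["scored_as"] = score_target or "other-target model"
    return report


# ---------------------------------------------------------------------------
# score-density / domain-shift diagnostics


def score_density_summary(
    reports: Sequence[EvalReport], grid_points: int = 201
) -> pd.DataFrame:
    """Per-cohort prediction-score distribution summaries.

    For each report: quantiles, moment skewness (scores piling up near 1 give
    negative, i.e. left, skew), and a Gaussian kernel-density estimate on a
    common [0, 1] grid, exported as a tidy plot-ready table.
    """
    if not reports:
        raise ValueError("need at least one report")
    grid = np.linspace(0.0, 1.0, grid_points)
    frames = []
    for rep in reports:
        s = np.asarray(rep.scores["score"], dtype=float)
        q = np.percentile(s, [5, 25, 50, 75, 95])
        try:
            dens = stats.gaussian_kde(s)(grid)
        except np.linalg.LinAlgError:  # zero-variance degenerate scores
            dens = np.zeros_like(grid)
        frames.append(
            pd.DataFrame(
                {
                    "cohort": rep.cohort,
                    "target": rep.target,
                    "normalised": rep.normalised,
                    "grid": grid,
                    "density": dens,
                    "q05": q[0],
                    "q25": q[1],
                    "median": q[2],
                    "q75": q[3],
                    "q95": q[4],
                    "skewness": float(stats.skew(s)) if s.std() > 0 else 0.0,
                    "mean_score": s.mean(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def max_cdf_gap(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Two-sample Kolmogorov-Smirnov statistic between score distributions."""
    return float(stats.ks_2samp(scores_a, scores_b).statistic)
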