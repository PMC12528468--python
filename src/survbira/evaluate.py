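"""Metrics and study harnesses: MAE, concordance index, patient-grouped
cross-validation, cross-cohort transfer, cascade ablation, and a
permutation test for group comparisons.

All metrics are computed at the patient level on uncensored survival
times.  The concordance index here is the uncensored special case: every
pair of patients with distinct observed times is comparable; a pair
scores 1 when the predicted ordering matches the observed ordering, 0.5
when the predictions tie, 0 otherwise; pairs tied in observed time are
excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from survbira.manifest import FoldSplit, PatientRecord, SlideRecord
from survbira.pipeline import PipelineConfig, SurBiRaPipeline


@dataclass
class EvaluationResult:
    """Patient-level performance under one evaluation condition."""

    mae_days: float
    c_index: float | None
    n_patients: int
    fold: int | None = None
    condition: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "fold": self.fold,
            "n_patients": self.n_patients,
            "mae_days": self.mae_days,
            "c_index": self.c_index,
            **self.condition,
        }


def mae(truth: Sequence[float], pred: Sequence[float]) -> float:
    """Mean absolute error in days."""
    t = np.asarray(truth, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise ValueError(
            f"truth and prediction must be equal-length non-empty 1-d arrays, "
            f"got {t.shape} and {p.shape}"
        )
    return float(np.mean(np.abs(t - p)))


def concordance_index(truth: Sequence[float], pred: Sequence[float]) -> float:
    """Concordance between predicted and observed survival orderings.

    Over all pairs with distinct observed times: 1 for a concordant pair,
    0.5 for a prediction tie, 0 for a discordant pair; the mean is
    returned.  Undefined (raises) for fewer than two subjects or when all
    observed times tie.
    """
    t = np.asarray(truth, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("truth and prediction must be equal-length 1-d arrays")
    if t.size < 2:
        raise ValueError("concordance index needs at least two subjects")
    dt = t[:, None] - t[None, :]
    dp = p[:, None] - p[None, :]
    upper = np.triu(np.ones_like(dt, dtype=bool), k=1)
    comparable = upper & (dt != 0)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("all observed times are tied; concordance undefined")
    concordant = (np.sign(dp) == np.sign(dt)) & comparable
    tied_pred = (dp == 0) & comparable
    score = concordant.sum() + 0.5 * tied_pred.sum()
    return float(score / n_pairs)


def _score_predictions(
    patients: list[PatientRecord],
    predictions: dict[str, "object"],
    fold: int | None = None,
    condition: dict | None = None,
) -> EvaluationResult:
    truth = [p.survival_days for p in patients if p.patient_id in predictions]
    pred = [predictions[p.patient_id].predicted_days
            for p in patients if p.patient_id in predictions]
    ci: float | None
    try:
        ci = concordance_index(truth, pred)
    except ValueError:
        ci = None
    return EvaluationResult(
        mae_days=mae(truth, pred),
        c_index=ci,
        n_patients=len(truth),
        fold=fold,
        condition=condition or {},
    )


def _run_cv_variants(
    patients: list[PatientRecord],
    slides: list[SlideRecord],
    folds: FoldSplit,
    config: PipelineConfig,
    variants: tuple[str, ...],
) -> dict[str, tuple[list[EvaluationResult], EvaluationResult, pd.DataFrame]]:
    """Shared CV driver: one Survpatch training per fold, reused by every
    requested cascade variant."""
    by_id = {p.patient_id: p for p in patients}
    missing = set(by_id) - set(folds.assignments)
    if missing:
        raise ValueError(f"patients missing from the fold split: {sorted(missing)}")

    per_fold: dict[str, list[EvaluationResult]] = {v: [] for v in variants}
    rows: dict[str, list[dict]] = {v: [] for v in variants}
    for fold in range(folds.k):
        test_ids = set(folds.fold_patients(fold)) & set(by_id)
        train_pat = [p for p in patients if p.patient_id not in test_ids]
        test_pat = [p for p in patients if p.patient_id in test_ids]
        if not test_pat:
            continue
        pipe = SurBiRaPipeline(config).fit(train_pat, slides)
        for variant in variants:
            preds = pipe.predict_patients(test_pat, slides, variant=variant)
            per_fold[variant].append(
                _score_predictions(
                    test_pat, preds, fold=fold, condition={"variant": variant}
                )
            )
            rows[variant] += [
                {
                    "patient_id": pid,
                    "fold": fold,
                    "truth_days": by_id[pid].survival_days,
                    "predicted_days": rec.predicted_days,
                }
                for pid, rec in preds.items()
            ]

    out = {}
    for variant in variants:
        table = pd.DataFrame(rows[variant])
        pooled_truth = table["truth_days"].to_numpy()
        pooled_pred = table["predicted_days"].to_numpy()
        try:
            ci = concordance_index(pooled_truth, pooled_pred)
        except ValueError:
            ci = None
        pooled = EvaluationResult(
            mae_days=mae(pooled_truth, pooled_pred),
            c_index=ci,
            n_patients=len(table),
            condition={"variant": variant, "pooled": True},
        )
        out[variant] = (per_fold[variant], pooled, table)
    return out


def run_cross_validation(
    patients: list[PatientRecord],
    slides: list[SlideRecord],
    folds: FoldSplit,
    config: PipelineConfig,
) -> tuple[list[EvaluationResult], EvaluationResult, pd.DataFrame]:
    """Patient-grouped k-fold CV of the full cascade.

    Each fold trains Survpatch and the forest on the other folds' slides
    and predicts the fold's patients; every patient is predicted exactly
    once.  Returns per-fold results, the pooled result over all held-out
    predictions, and the pooled prediction table.
    """
    res = _run_cv_variants(patients, slides, folds, config, ("full",))
    return res["full"]


def run_ablation(
    patients: list[PatientRecord],
    slides: list[SlideRecord],
    folds: FoldSplit,
    config: PipelineConfig,
) -> dict[str, tuple[list[EvaluationResult], EvaluationResult, pd.DataFrame]]:
    """Evaluate the three cascade depths on identical folds and seeds.

    ``patch_mean``: patient prediction is the direct mean of patch
    predictions.  ``bin_mean``: binning is applied, each slide predicted
    by its feature-vector mean, no forest.  ``full``: the whole cascade.
    The patch model is trained once per fold and shared across variants.
    """
    return _run_cv_variants(
        patients, slides, folds, config, ("patch_mean", "bin_mean", "full")
    )


def run_cross_cohort(
    train: tuple[list[PatientRecord], list[SlideRecord]],
    test: tuple[list[PatientRecord], list[SlideRecord]],
    config: PipelineConfig,
) -> EvaluationResult:
    """Train the cascade on one cohort, evaluate on another, no refit.

    Overlapping patient ids are rejected: a shared patient would make the
    two cohorts statistically dependent.
    """
    train_pat, train_slides = train
    test_pat, test_slides = test
    overlap = {p.patient_id for p in train_pat} & {p.patient_id for p in test_pat}
    if overlap:
        raise ValueError(f"train and test cohorts share patient ids: {sorted(overlap)}")
    pipe = SurBiRaPipeline(config).fit(train_pat, train_slides)
    preds = pipe.predict_patients(test_pat, test_slides)
    return _score_predictions(test_pat, preds, condition={"protocol": "cross_cohort"})


def compare_groups(
    errors_a: Sequence[float],
    errors_b: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-tailed permutation test for a difference in mean error.

    Returns ``(mean(a) - mean(b), p)`` where p is the fraction of label
    permutations whose absolute mean difference is at least the observed
    one (with the observed arrangement counted, so p is never 0).
    """
    a = np.asarray(errors_a, dtype=np.float64)
    b = np.asarray(errors_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = perm[: a.size].mean() - perm[a.size :].mean()
        if abs(stat) >= abs(observed) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return observed, float(p)
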