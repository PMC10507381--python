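"""Metrics, operating-point analysis, subgroup evaluation, and the
data-efficiency experiment harness.

AUROC is the headline metric; because positives are rare (~13%
prevalence for the emulated biomarker), AUPRC (average precision, i.e.
step-wise integration of the precision-recall curve) is reported
alongside. Cross-validated results are summarized as mean +/- std over
the five folds, with pooled per-patient scores also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (average_precision_score,
                             precision_recall_curve, roc_auc_score,
                             roc_curve)

__all__ = [
    "EvalResult",
    "DataEfficiencyCurve",
    "auroc",
    "auprc",
    "fix_threshold",
    "operating_point",
    "subgroup_eval",
    "summarize_folds",
    "data_efficiency",
]


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if not np.isfinite(scores).all():
        raise ValueError("scores contain non-finite values")
    return scores, labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve.

    Equal to the Mann-Whitney statistic P(s+ > s-) + 0.5 P(s+ = s-);
    tied scores contribute half a concordant pair.
    """
    scores, labels = _validate(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC requires both classes present")
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve via average precision
    (step-wise integration; equals prevalence for uninformative scores)."""
    scores, labels = _validate(scores, labels)
    if labels.sum() == 0:
        raise ValueError("AUPRC requires at least one positive")
    return float(average_precision_score(labels, scores))


def fix_threshold(scores, labels, target_sensitivity: float = 0.95) -> float:
    """Largest threshold whose sensitivity (classifying score >= t as
    positive) reaches `target_sensitivity` on the given set.

    The threshold is chosen once on an in-domain test set and then
    applied unchanged to external or biopsy sets.
    """
    scores, labels = _validate(scores, labels)
    if not 0.0 < target_sensitivity <= 1.0:
        raise ValueError("target_sensitivity must be in (0, 1]")
    pos = np.sort(scores[labels == 1])[::-1]
    if pos.size == 0:
        raise ValueError("no positives in the threshold-fixing set")
    k = int(np.ceil(target_sensitivity * pos.size))  # positives to capture
    t = float(pos[k - 1])
    achieved = float((scores[labels == 1] >= t).mean())
    if achieved < target_sensitivity:
        raise ValueError(
            f"target sensitivity {target_sensitivity} unreachable; "
            f"max achievable at this threshold is {achieved:.3f}")
    return t


def operating_point(scores, labels, threshold: float) -> dict[str, float]:
    """Confusion-matrix metrics at a fixed threshold (score >= t positive)."""
    scores, labels = _validate(scores, labels)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fp = int((pred & (labels == 0)).sum())
    return {
        "threshold": float(threshold),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


@dataclass
class EvalResult:
    """Per-fold and aggregated discrimination metrics."""

    fold_auroc: list[float]
    fold_auprc: list[float]
    auroc_mean: float
    auroc_std: float
    auprc_mean: float
    auprc_std: float
    pooled_auroc: float
    pooled_auprc: float
    roc_curve: pd.DataFrame
    pr_curve: pd.DataFrame
    operating_point: dict[str, float] | None = None


def summarize_folds(scores_df: pd.DataFrame,
                    target_sensitivity: float | None = None) -> EvalResult:
    """Aggregate a long (patient_id, score, label, fold) score table.

    Per-fold AUROC/AUPRC give the headline mean +/- std; pooled scores
    give the overall ROC/PR curves and optionally an operating point at
    the requested sensitivity.
    """
    fold_au, fold_ap = [], []
    for _, grp in scores_df.groupby("fold"):
        fold_au.append(auroc(grp["score"], grp["label"]))
        fold_ap.append(auprc(grp["score"], grp["label"]))
    pooled = scores_df.drop_duplicates(subset=["patient_id", "fold"])
    s = pooled["score"].to_numpy()
    y = pooled["label"].to_numpy().astype(int)
    fpr, tpr, roc_t = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    op = None
    if target_sensitivity is not None:
        t = fix_threshold(s, y, target_sensitivity)
        op = operating_point(s, y, t)
    return EvalResult(
        fold_auroc=fold_au, fold_auprc=fold_ap,
        auroc_mean=float(np.mean(fold_au)),
        auroc_std=float(np.std(fold_au)),
        auprc_mean=float(np.mean(fold_ap)),
        auprc_std=float(np.std(fold_ap)),
        pooled_auroc=auroc(s, y), pooled_auprc=auprc(s, y),
        roc_curve=pd.DataFrame({"fpr": fpr, "tpr": tpr,
                                "threshold": roc_t}),
        pr_curve=pd.DataFrame({"recall": rec, "precision": prec}),
        operating_point=op,
    )


def subgroup_eval(scores_df: pd.DataFrame,
                  grouping_column: str) -> pd.DataFrame:
    """AUROC per clinicopathological subgroup.

    Groups containing a single class are skipped with a warning rather
    than failing the whole analysis.
    """
    rows = []
    for name, grp in scores_df.groupby(grouping_column):
        y = grp["label"].to_numpy().astype(int)
        if len(np.unique(y)) < 2:
            warnings.warn(f"subgroup {name!r} has a single class; skipped",
                          stacklevel=2)
            continue
        rows.append({
            grouping_column: name,
            "n": len(grp),
            "n_positive": int(y.sum()),
            "auroc": auroc(grp["score"], y),
            "auprc": auprc(grp["score"], y),
        })
    return pd.DataFrame(rows)


@dataclass
class DataEfficiencyCurve:
    sizes: list[int]
    aurocs: dict[int, list[float]]   # size -> one AUROC per repetition

    def mean(self, size: int) -> float:
        return float(np.mean(self.aurocs[size]))

    def std(self, size: int) -> float:
        return float(np.std(self.aurocs[size]))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"size": s, "auroc_mean": self.mean(s), "auroc_std": self.std(s),
             "n_reps": len(self.aurocs[s])}
            for s in self.sizes])


def data_efficiency(bags: Mapping[str, object], manifest,
                    eval_bags: Mapping[str, object], eval_manifest,
                    sizes: Sequence[int], cfg, reps: int = 5,
                    val_frac: float = 0.2) -> DataEfficiencyCurve:
    """Test AUROC as a function of training-set size.

    For each size, `reps` independent stratified patient subsamples are
    drawn from the training pool, a model is trained for the configured
    (fixed) number of epochs with a stratified validation split carved
    from the subsample, and the best checkpoint is scored on the fixed
    held-out evaluation cohort. Means and standard deviations over the
    repetitions form the curve.
    """
    from .training import build_model, train_fold, SplitPlan

    sizes = sorted(int(s) for s in sizes)
    usable = manifest.usable_for_training()
    pool = np.array(usable.patient_ids)
    pool_labels = usable.labels.loc[pool].to_numpy().astype(int)
    if sizes[-1] > len(pool):
        raise ValueError(
            f"requested size {sizes[-1]} exceeds the {len(pool)}-patient "
            "training pool")
    eval_pids = [p for p in eval_manifest.usable_for_training().patient_ids
                 if p in eval_bags]
    y_eval = eval_manifest.labels.loc[eval_pids].to_numpy().astype(int)

    aurocs: dict[int, list[float]] = {s: [] for s in sizes}
    for size in sizes:
        for rep in range(reps):
            seed = int(np.random.SeedSequence(
                [cfg.seed, size, rep]).generate_state(1)[0] % (2 ** 31))
            rng = np.random.default_rng(seed)
            # stratified subsample of the pool
            idx = []
            for cls in (1, 0):
                cls_idx = np.where(pool_labels == cls)[0]
                n_cls = max(2, int(round(size * cls_idx.size / len(pool))))
                n_cls = min(n_cls, cls_idx.size)
                idx.extend(rng.choice(cls_idx, size=n_cls, replace=False))
            sub_pids = [str(p) for p in pool[np.array(idx)]]
            sub_labels = usable.labels.loc[sub_pids].to_numpy().astype(int)
            # carve a stratified validation split out of the subsample:
            # fold 0 = validation, fold 1 = training (train_fold's test
            # fold 2 is left empty; evaluation uses the external cohort)
            fold_of: dict[str, int] = {}
            for cls in (0, 1):
                cls_pids = [p for p, y in zip(sub_pids, sub_labels)
                            if y == cls]
                cls_pids = list(rng.permutation(cls_pids))
                n_val = max(1, int(round(val_frac * len(cls_pids))))
                for p in cls_pids[:n_val]:
                    fold_of[p] = 1
                for p in cls_pids[n_val:]:
                    fold_of[p] = 2
            plan = SplitPlan(k=3, fold_of=fold_of)
            run_cfg = type(cfg)(**{**cfg.__dict__, "seed": seed})
            res = train_fold(bags, manifest, plan, fold=0, cfg=run_cfg)
            model = build_model(run_cfg, seed=0)
            model.load_state_dict(res.best_state)
            scores = np.array([
                float(model.predict(
                    eval_bags[p].embeddings if hasattr(eval_bags[p],
                                                       "embeddings")
                    else np.asarray(eval_bags[p])).probabilities[0])
                for p in eval_pids])
            aurocs[size].append(auroc(scores, y_eval))
    return DataEfficiencyCurve(sizes=sizes, aurocs=aurocs)
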