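"""Optimization loops and the patient-level cross-validation protocol.

Experiments run 5-fold cross-validation with in-domain validation and
testing: folds are stratified by label at the patient level; for fold f
the test set is fold f, the validation set fold (f+1) mod k, and the
remaining k-2 folds train. Cycling the test fold through the data gives
pooled, representative in-domain test scores. The validation set selects
the best checkpoint (highest validation AUROC, earlier iteration on
ties); test patients are never touched during training.

Training recipes follow the full-scale defaults: the transformer trains
with AdamW (learning rate and weight decay both 2e-5) for 8 epochs at
batch size one (bags have variable length and are not stacked);
AttentionMIL trains with Adam, weight decay 1e-2, a fit-one-cycle
schedule with max learning rate 1e-4 and a 25% warm-up, for 32 epochs.
`TrainConfig.synthetic_profile` is the scaled-down recipe used for the
small synthetic models in the test suite.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .aggregator import (AggregatorConfig, AttentionMILConfig,
                         AttentionMILModel, MeanPoolModel,
                         TransformerAggregator)
from .bagio import CohortManifest, TileBag
from .evaluation import auroc
from .nn import Adam, AdamW, one_cycle_lr

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "FoldResult",
    "make_splits",
    "train_fold",
    "cross_validate",
    "external_test",
    "build_model",
]


@dataclass
class TrainConfig:
    model: str = "transformer"       # transformer | attention_mil | mean_pool
    d_in: int = 768
    lr: float = 2e-5
    weight_decay: float = 2e-5
    epochs: int = 8
    batch_size: int = 1
    eval_every: int = 500            # iterations between validation passes
    scheduler: str = "constant"      # constant | one_cycle
    warmup_frac: float = 0.25
    clip_grad_norm: float | None = None
    n_runs: int = 1                  # independent inits per fold; scores
    #                                  are averaged over the runs
    selection_burnin_frac: float = 0.0   # ignore checkpoints before this
    seed: int = 0
    arch: AggregatorConfig | AttentionMILConfig | None = None

    def __post_init__(self) -> None:
        if self.model not in ("transformer", "attention_mil", "mean_pool"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("lr must be > 0 and weight_decay >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size != 1:
            raise ValueError("bags have variable length; batch_size must be 1")

    @classmethod
    def transformer_default(cls, **kw) -> "TrainConfig":
        return cls(model="transformer", lr=2e-5, weight_decay=2e-5,
                   epochs=8, **kw)

    @classmethod
    def attention_mil_default(cls, **kw) -> "TrainConfig":
        return cls(model="attention_mil", lr=1e-4, weight_decay=1e-2,
                   epochs=32, scheduler="one_cycle", **kw)

    @classmethod
    def synthetic_profile(cls, model: str = "transformer", d_in: int = 64,
                          seed: int = 0, **kw) -> "TrainConfig":
        """Scaled-down recipe for the small synthetic models (d_model 64)."""
        if model == "transformer":
            arch = AggregatorConfig(d_in=d_in, d_model=64, n_layers=2,
                                    n_heads=8, mlp_hidden=128, head_hidden=64)
            return cls(model=model, d_in=d_in, lr=2e-3, weight_decay=1e-4,
                       epochs=16, scheduler="one_cycle", eval_every=250,
                       clip_grad_norm=1.0, n_runs=2,
                       selection_burnin_frac=0.3, seed=seed, arch=arch,
                       **kw)
        if model == "attention_mil":
            arch = AttentionMILConfig(d_in=d_in, d_hidden=64, d_attn=32)
            return cls(model=model, d_in=d_in, lr=1e-3, weight_decay=1e-2,
                       epochs=16, scheduler="one_cycle", eval_every=500,
                       seed=seed, arch=arch, **kw)
        return cls(model="mean_pool", d_in=d_in, lr=1e-2, weight_decay=1e-4,
                   epochs=16, eval_every=500, seed=seed, **kw)


@dataclass
class SplitPlan:
    """Patient-level fold assignment for k-fold cross-validation."""

    k: int
    fold_of: dict[str, int]          # patient_id -> fold index 0..k-1

    def patients_in_fold(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.fold_of.items() if f == fold)

    def test_patients(self, fold: int) -> list[str]:
        return self.patients_in_fold(fold)

    def val_patients(self, fold: int) -> list[str]:
        return self.patients_in_fold((fold + 1) % self.k)

    def train_patients(self, fold: int) -> list[str]:
        excluded = {fold, (fold + 1) % self.k}
        return sorted(p for p, f in self.fold_of.items()
                      if f not in excluded)


@dataclass
class FoldResult:
    fold: int
    model_name: str
    best_state: dict[str, np.ndarray]    # representative (best-val) run
    best_val_auroc: float
    best_iteration: int
    curve: pd.DataFrame                  # iteration, train_loss, val_auroc
    test_scores: pd.DataFrame            # patient_id, score, label, fold
    config: TrainConfig
    run_states: list[dict[str, np.ndarray]] = None  # all ensemble members


def make_splits(manifest: CohortManifest, k: int = 5,
                seed: int = 0) -> SplitPlan:
    """Stratified patient-level k-fold assignment, deterministic in seed."""
    usable = manifest.usable_for_training()
    pids = np.array(usable.patient_ids)
    labels = usable.labels.loc[pids].to_numpy().astype(int)
    for cls_val in (0, 1):
        n_cls = int((labels == cls_val).sum())
        if n_cls < k:
            raise ValueError(
                f"class {cls_val} has only {n_cls} patients; need >= {k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(pids, labels)):
        for i in test_idx:
            fold_of[str(pids[i])] = fold
    return SplitPlan(k=k, fold_of=fold_of)


def build_model(cfg: TrainConfig, seed: int):
    if cfg.model == "transformer":
        arch = cfg.arch or AggregatorConfig(d_in=cfg.d_in)
        return TransformerAggregator(arch, seed=seed)
    if cfg.model == "attention_mil":
        arch = cfg.arch or AttentionMILConfig(d_in=cfg.d_in)
        return AttentionMILModel(arch, seed=seed)
    return MeanPoolModel(d_in=cfg.d_in, seed=seed)


def _bag_matrix(bag) -> np.ndarray:
    return bag.embeddings if isinstance(bag, TileBag) else np.asarray(bag)


def _score_patients(model, bags: Mapping[str, TileBag],
                    pids: Sequence[str]) -> np.ndarray:
    return np.array([float(model.predict(_bag_matrix(bags[p]))
                           .probabilities[0]) for p in pids])


def train_fold(bags: Mapping[str, TileBag], manifest: CohortManifest,
               plan: SplitPlan, fold: int, cfg: TrainConfig) -> FoldResult:
    """Train one fold's model and score its in-domain test patients."""
    labels = manifest.labels
    train_pids = [p for p in plan.train_patients(fold) if p in bags]
    val_pids = [p for p in plan.val_patients(fold) if p in bags]
    test_pids = [p for p in plan.test_patients(fold) if p in bags]
    if not val_pids:
        raise ValueError(f"fold {fold}: empty validation set")
    missing = [p for p in plan.train_patients(fold) + plan.val_patients(fold)
               if p not in bags]
    if missing:
        raise ValueError(f"fold {fold}: bags missing for patients {missing}")
    y_val = labels.loc[val_pids].to_numpy().astype(int)
    if len(np.unique(y_val)) < 2:
        raise ValueError(f"fold {fold}: validation set has a single class")

    def run_once(restart: int):
        seed = int(np.random.SeedSequence(
            [cfg.seed, fold, restart]).generate_state(1)[0] % (2 ** 31))
        model = build_model(cfg, seed=seed)
        opt_cls = AdamW if cfg.model == "transformer" else Adam
        opt = opt_cls(model.parameters(), lr=cfg.lr,
                      weight_decay=cfg.weight_decay)
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(seed + 7919)
        total_steps = cfg.epochs * len(train_pids)
        # checkpoints from the schedule's burn-in (the model is still
        # near its initialization there) are excluded from selection
        burnin_iter = int(cfg.selection_burnin_frac * total_steps)

        best_state = model.state_dict()
        best_key = (-np.inf, -np.inf)
        best_iter = 0
        log_rows: list[dict] = []
        iteration = 0

        def evaluate(train_loss: float) -> None:
            nonlocal best_state, best_key, best_iter
            scores = _score_patients(model, bags, val_pids)
            val_auroc = auroc(scores, y_val)
            eps = 1e-12
            p = np.clip(scores, eps, 1 - eps)
            val_loss = float(-np.mean(y_val * np.log(p)
                                      + (1 - y_val) * np.log(1 - p)))
            log_rows.append({"restart": restart, "iteration": iteration,
                             "train_loss": train_loss,
                             "val_auroc": val_auroc,
                             "val_loss": val_loss})
            # model selection: highest validation AUROC; equal AUROC
            # (which saturates quickly on small validation sets) broken
            # by lower validation loss, exact ties by earlier checkpoint
            key = (val_auroc, -val_loss)
            if iteration < burnin_iter:
                return
            if key > best_key:
                best_key = key
                best_iter = iteration
                best_state = model.state_dict()

        for _epoch in range(cfg.epochs):
            order = rng.permutation(len(train_pids))
            for idx in order:
                pid = train_pids[idx]
                if cfg.scheduler == "one_cycle":
                    opt.lr = one_cycle_lr(iteration, total_steps, cfg.lr,
                                          warmup_frac=cfg.warmup_frac)
                opt.zero_grad()
                loss = model.loss(_bag_matrix(bags[pid]),
                                  float(labels.loc[pid]), rng=drop_rng)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"fold {fold}: non-finite loss at iteration "
                        f"{iteration} (patient {pid})")
                loss.backward()
                if cfg.clip_grad_norm is not None:
                    total = np.sqrt(sum(float((p.grad ** 2).sum())
                                        for p in model.parameters()
                                        if p.grad is not None))
                    if total > cfg.clip_grad_norm:
                        scale = cfg.clip_grad_norm / total
                        for p in model.parameters():
                            if p.grad is not None:
                                p.grad *= scale
                opt.step()
                iteration += 1
                if iteration % cfg.eval_every == 0:
                    evaluate(float(loss.data))
        if iteration % cfg.eval_every != 0 or iteration == 0:
            evaluate(float("nan") if iteration == 0 else float(loss.data))
        return best_state, best_key, best_iter, log_rows

    # a single run occasionally lands in a bad optimization basin; the
    # fold's scores average an ensemble of n_runs independent
    # initializations, which is robust to one failed member
    run_states: list[dict[str, np.ndarray]] = []
    log_rows: list[dict] = []
    best_key = (-np.inf, -np.inf)
    best_state = None
    best_iter = 0
    for r in range(cfg.n_runs):
        state_r, key_r, iter_r, rows_r = run_once(r)
        run_states.append(state_r)
        log_rows.extend(rows_r)
        if key_r > best_key:
            best_state, best_key, best_iter = state_r, key_r, iter_r
    best_val = float(best_key[0])

    member_scores = []
    for state in run_states:
        model = build_model(cfg, seed=0)
        model.load_state_dict(state)
        member_scores.append(_score_patients(model, bags, test_pids))
    test_df = pd.DataFrame({
        "patient_id": test_pids,
        "score": np.mean(member_scores, axis=0),
        "label": labels.loc[test_pids].to_numpy().astype(int),
        "fold": fold,
    })
    return FoldResult(
        fold=fold, model_name=cfg.model, best_state=best_state,
        best_val_auroc=float(best_val), best_iteration=best_iter,
        curve=pd.DataFrame(log_rows), test_scores=test_df, config=cfg,
        run_states=run_states,
    )


def cross_validate(bags: Mapping[str, TileBag], manifest: CohortManifest,
                   cfg: TrainConfig, k: int = 5) -> list[FoldResult]:
    """Run full k-fold cross-validation; each patient is tested exactly
    once across the k folds."""
    plan = make_splits(manifest, k=k, seed=cfg.seed)
    return [train_fold(bags, manifest, plan, f, cfg) for f in range(k)]


def external_test(fold_results: Sequence[FoldResult],
                  external_bags: Mapping[str, TileBag],
                  external_manifest: CohortManifest) -> pd.DataFrame:
    """Score an external cohort with every fold's best checkpoint.

    Returns a long table (fold, patient_id, score, label); summarize
    per-fold AUROC with :func:`histomil.evaluation.summarize_folds`.
    """
    labels = external_manifest.labels
    pids = [p for p in external_manifest.patient_ids if p in external_bags]
    rows = []
    for res in fold_results:
        states = res.run_states or [res.best_state]
        member = []
        for state in states:
            model = build_model(res.config, seed=0)
            model.load_state_dict(state)
            member.append(_score_patients(model, external_bags, pids))
        scores = np.mean(member, axis=0)
        for pid, s in zip(pids, scores):
            rows.append({"fold": res.fold, "patient_id": pid,
                         "score": float(s),
                         "label": int(labels.loc[pid])})
    return pd.DataFrame(rows)
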