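"""Nested cross-validation and the flattened-voxel SVM baseline.

Ten rotating folds realize the 80/10/10 train/validation/test split:
subjects are shuffled once, cut into 10 near-equal blocks, and fold i
tests on block i, validates on block (i+1) mod 10 and trains on the
remaining eight.  Test blocks are pairwise disjoint and jointly cover
the cohort, so the mean over folds is a leakage-free generalization
estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import model as pcnn
from . import nn
from .errors import DomainError
from .prep import PreparedDataset

N_FOLDS = 10


@dataclass
class FoldPlan:
    folds: list  # [{"train": [...], "val": [...], "test": [...]}]
    n_total: int
    seed: int

    def to_json(self) -> str:
        return json.dumps({"folds": self.folds, "n_total": self.n_total, "seed": self.seed})

    @classmethod
    def from_json(cls, s: str) -> "FoldPlan":
        d = json.loads(s)
        return cls(folds=d["folds"], n_total=d["n_total"], seed=d["seed"])


def make_fold_plan(subject_ids, seed: int) -> FoldPlan:
    ids = [str(s) for s in subject_ids]
    if len(ids) < N_FOLDS:
        raise DomainError(f"need at least {N_FOLDS} subjects; got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise DomainError("subject ids must be unique")
    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(len(ids))]
    blocks = [list(b) for b in np.array_split(shuffled, N_FOLDS)]
    folds = []
    for i in range(N_FOLDS):
        test = blocks[i]
        val = blocks[(i + 1) % N_FOLDS]
        train = [s for j, b in enumerate(blocks) if j not in (i, (i + 1) % N_FOLDS) for s in b]
        folds.append({"train": train, "val": val, "test": test})
    return FoldPlan(folds=folds, n_total=len(ids), seed=seed)


def accuracy(predictions, truth) -> float:
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) == 0:
        raise DomainError("empty prediction list")
    if predictions.shape != truth.shape:
        raise DomainError("predictions and truth differ in length")
    return float((predictions == truth).mean())


@dataclass
class CVResult:
    fold_accuracies: list
    mean_accuracy: float
    sd_accuracy: float
    histories: list = field(default_factory=list)
    best_model: object = None  # fold model with highest validation accuracy
    best_fold: int = -1

    def summary(self) -> dict:
        return {
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
        }


def _fold_arrays(store: PreparedDataset, fold):
    parts = {}
    for part in ("train", "val", "test"):
        sub = store.subset(fold[part])
        parts[part] = (sub.volumes, sub.labels.astype(np.float32))
    return parts


def _check_plan(store: PreparedDataset, plan: FoldPlan):
    all_ids = set(store.subject_ids)
    for k, fold in enumerate(plan.folds):
        union = set(fold["train"]) | set(fold["val"]) | set(fold["test"])
        if union != all_ids:
            raise DomainError(f"fold {k} does not cover the dataset")


def run_nested_cv(
    store: PreparedDataset,
    config: pcnn.TrainingConfig,
    plan: FoldPlan,
    n_pools: int = 3,
    keep_best_model: bool = True,
) -> CVResult:
    """Train a fresh model per fold; report test accuracy per fold.

    The per-fold model seed is derived from (config.seed, fold index) so
    folds are independent but the whole run is reproducible.
    """
    nn.configure_malloc()
    _check_plan(store, plan)
    accs, histories = [], []
    best_val, best_model, best_fold = -1.0, None, -1
    for k, fold in enumerate(plan.folds):
        parts = _fold_arrays(store, fold)
        fold_seed = int(np.random.SeedSequence((config.seed, k)).generate_state(1)[0])
        fold_config = pcnn.TrainingConfig(**{**vars(config), "seed": fold_seed})
        model = pcnn.build_model(store.target_shape, fold_config, n_pools=n_pools)
        try:
            model, history = pcnn.train(
                model, *parts["train"], *parts["val"], fold_config
            )
        except Exception as exc:
            raise type(exc)(f"fold {k}: {exc}") from exc
        test_x, test_y = parts["test"]
        acc = accuracy(pcnn.predict(model, test_x, config.batch_size), test_y.argmax(axis=1))
        accs.append(acc)
        histories.append(history)
        fold_best_val = max(history.val_accuracy)
        if keep_best_model and fold_best_val > best_val:
            best_val, best_model, best_fold = fold_best_val, model, k
    return CVResult(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs, ddof=1)),
        histories=histories,
        best_model=best_model,
        best_fold=best_fold,
    )


def svm_baseline(store: PreparedDataset, plan: FoldPlan, C: float = 1.0) -> CVResult:
    """Linear SVM on flattened, per-voxel-standardized volumes.

    Trained on train+validation of each fold (no tuning step to spend
    the validation block on), tested on the same test blocks as the
    network for a paired comparison.
    """
    _check_plan(store, plan)
    accs = []
    for fold in plan.folds:
        parts = _fold_arrays(store, fold)
        x_tr = np.concatenate([parts["train"][0], parts["val"][0]]).reshape(
            len(parts["train"][0]) + len(parts["val"][0]), -1
        )
        y_tr = np.concatenate([parts["train"][1], parts["val"][1]]).argmax(axis=1)
        x_te = parts["test"][0].reshape(len(parts["test"][0]), -1)
        y_te = parts["test"][1].argmax(axis=1)
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
        clf.fit(x_tr, y_tr)
        accs.append(accuracy(clf.predict(x_te), y_te))
    return CVResult(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs, ddof=1)),
    )
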