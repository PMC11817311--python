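"""Cross-validated SVM comparison of the representations.

Every representation (functionals, GMM supervectors, CNN embeddings,
early fusion) is classified with an SVM under one shared, stratified
5-fold partition of the subjects.  Per outer fold, features are
standardized on the training portion and the SVM hyperparameters
(C, γ ∈ {1e−3 … 1e3}, kernel ∈ {linear, rbf}) are grid-searched --
by nested 3-fold cross-validation on the training portion by default,
which avoids selection leakage.  Reports carry per-fold and aggregate
accuracy / specificity / sensitivity / F1 (PD is the positive class),
pooled out-of-fold decision scores, the ROC curve and its AUC, and a
hash of the fold plan so that pipeline comparisons can verify they
used identical partitions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from scribepd.io_formats import Condition, DatasetManifest

POSITIVE = Condition.PD  # clinical convention: PD is the positive class


@dataclass
class FoldPlan:
    """Stratified k-fold partition of subjects, reused across pipelines."""

    subject_ids: list[str]
    labels: np.ndarray          # 1 = PD, 0 = HC
    assignments: np.ndarray     # fold index per subject
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.assignments = np.asarray(self.assignments, dtype=int)
        if not (len(self.subject_ids) == len(self.labels) == len(self.assignments)):
            raise ValueError("subject_ids, labels and assignments must align")
        if set(np.unique(self.assignments)) != set(range(self.k)):
            raise ValueError("assignments must cover folds 0..k-1")

    def folds(self):
        """Yield (train_idx, test_idx) per fold."""
        for f in range(self.k):
            test = np.flatnonzero(self.assignments == f)
            train = np.flatnonzero(self.assignments != f)
            yield train, test

    @property
    def hash(self) -> str:
        h = hashlib.sha256()
        h.update("|".join(self.subject_ids).encode())
        h.update(self.labels.tobytes())
        h.update(self.assignments.tobytes())
        return h.hexdigest()[:16]


@dataclass
class SVMGrid:
    """Hyperparameter grid of the SVM classifier."""

    c_values: tuple = tuple(10.0 ** k for k in range(-3, 4))
    gamma_values: tuple = tuple(10.0 ** k for k in range(-3, 4))
    kernels: tuple = ("linear", "rbf")

    def param_grid(self) -> list[dict]:
        """γ applies only to the rbf kernel (deduplicated for linear)."""
        grid = []
        if "linear" in self.kernels:
            grid.append({"svc__kernel": ["linear"],
                         "svc__C": list(self.c_values)})
        if "rbf" in self.kernels:
            grid.append({"svc__kernel": ["rbf"],
                         "svc__C": list(self.c_values),
                         "svc__gamma": list(self.gamma_values)})
        return grid


def binary_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and F1 with PD positive."""
    total = tp + fp + tn + fn
    acc = (tp + tn) / total if total else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec, "f1": f1}


@dataclass
class CVReport:
    """Per-fold and aggregate results of one cross-validated pipeline."""

    name: str
    fold_metrics: list[dict[str, float]]
    best_params: list[dict]
    scores: np.ndarray          # pooled out-of-fold decision scores
    true_labels: np.ndarray
    plan_hash: str
    chosen_M: "int | None" = None
    extras: dict = field(default_factory=dict)

    def aggregate(self) -> dict[str, dict[str, float]]:
        out = {}
        for metric in ("accuracy", "sensitivity", "specificity", "f1"):
            vals = np.array([m[metric] for m in self.fold_metrics])
            out[metric] = {"mean": float(vals.mean()),
                           "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
        return out

    @property
    def accuracy(self) -> float:
        return self.aggregate()["accuracy"]["mean"]

    @property
    def auc(self) -> float:
        return float(roc_auc_score(self.true_labels, self.scores))

    def roc(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return roc_curve(self.true_labels, self.scores)

    def to_dict(self) -> dict:
        fpr, tpr, thr = self.roc()
        return {
            "name": self.name,
            "plan_hash": self.plan_hash,
            "chosen_M": self.chosen_M,
            "fold_metrics": self.fold_metrics,
            "aggregate": self.aggregate(),
            "best_params": [
                {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                 for k, v in p.items()} for p in self.best_params],
            "auc": self.auc,
            "scores": [float(s) for s in self.scores],
            "true_labels": [int(t) for t in self.true_labels],
            "roc": {"fpr": [float(v) for v in fpr],
                    "tpr": [float(v) for v in tpr]},
            "extras": self.extras,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def make_folds(manifest: "DatasetManifest | tuple", seed: int = 0,
               k: int = 5) -> FoldPlan:
    """Stratified k-fold plan over a manifest (or (ids, labels) pair).

    Labels are 1 for PD and 0 for HC; each class must have at least k
    subjects so that every fold sees both classes.
    """
    if isinstance(manifest, DatasetManifest):
        ids = manifest.subject_ids
        labels = np.array([int(c is Condition.PD) for c in manifest.conditions])
    else:
        ids, labels = manifest
        ids = list(ids)
        labels = np.asarray(labels, dtype=int)
    for cls, cname in ((1, "PD"), (0, "HC")):
        n_cls = int(np.sum(labels == cls))
        if n_cls < k:
            raise ValueError(
                f"class {cname} has {n_cls} subjects; at least {k} are "
                f"required for {k}-fold stratification")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(ids), dtype=int)
    for f, (_tr, te) in enumerate(skf.split(np.zeros(len(ids)), labels)):
        assignments[te] = f
    return FoldPlan(ids, labels, assignments, k=k, seed=seed)


def _pipe() -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("svc", SVC())])


def _grid_search(grid: SVMGrid, seed: int) -> GridSearchCV:
    inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    return GridSearchCV(_pipe(), grid.param_grid(), cv=inner,
                        scoring="accuracy", n_jobs=1)


def run_svm_cv(
    X: "np.ndarray | None",
    y: np.ndarray,
    plan: FoldPlan,
    grid: "SVMGrid | None" = None,
    nested: bool = True,
    seed: int = 0,
    name: str = "pipeline",
    fold_embedder=None,
) -> CVReport:
    """Cross-validate an SVM over a shared fold plan.

    ``X`` holds one feature row per subject; alternatively
    ``fold_embedder(train_idx, test_idx) -> (X_train, X_test)`` computes
    fold-specific features (used by the fine-tuned image branch, where
    representations legitimately depend on the training portion).
    """
    grid = grid or SVMGrid()
    y = np.asarray(y, dtype=int)
    if X is not None:
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            i, j = np.argwhere(~np.isfinite(X))[0]
            raise ValueError(
                f"non-finite feature value for subject {plan.subject_ids[i]!r} "
                f"at dimension {j}")

    # Non-nested model selection tunes once on the shared outer folds
    # (a deliberately simpler, leak-prone protocol kept behind a flag);
    # the default is nested selection inside each training portion.
    global_params = None
    if not nested:
        if fold_embedder is not None:
            raise ValueError("non-nested selection requires a fixed X")
        gs = GridSearchCV(_pipe(), grid.param_grid(),
                          cv=list(plan.folds()), scoring="accuracy", n_jobs=1)
        gs.fit(X, y)
        global_params = dict(gs.best_params_)

    fold_metrics, best_params = [], []
    scores = np.empty(len(y))
    for train_idx, test_idx in plan.folds():
        if fold_embedder is not None:
            xtr, xte = fold_embedder(train_idx, test_idx)
        else:
            xtr, xte = X[train_idx], X[test_idx]
        ytr, yte = y[train_idx], y[test_idx]
        if nested:
            gs = _grid_search(grid, seed)
            gs.fit(xtr, ytr)
            best_params.append(dict(gs.best_params_))
            fitted = gs.best_estimator_
        else:
            fitted = _pipe().set_params(**global_params)
            fitted.fit(xtr, ytr)
            best_params.append(dict(global_params))
        s = fitted.decision_function(xte)
        scores[test_idx] = s
        pred = (s > 0).astype(int)
        tp = int(np.sum((pred == 1) & (yte == 1)))
        fp = int(np.sum((pred == 1) & (yte == 0)))
        tn = int(np.sum((pred == 0) & (yte == 0)))
        fn = int(np.sum((pred == 0) & (yte == 1)))
        fold_metrics.append(binary_metrics(tp, fp, tn, fn))
    return CVReport(name=name, fold_metrics=fold_metrics,
                    best_params=best_params, scores=scores, true_labels=y,
                    plan_hash=plan.hash)


def training_accuracy(X: np.ndarray, y: np.ndarray, plan: FoldPlan,
                      grid: "SVMGrid | None" = None, seed: int = 0) -> float:
    """Mean grid-search CV accuracy over the outer training portions."""
    grid = grid or SVMGrid()
    y = np.asarray(y, dtype=int)
    accs = []
    for train_idx, _ in plan.folds():
        gs = _grid_search(grid, seed)
        gs.fit(X[train_idx], y[train_idx])
        accs.append(float(gs.best_score_))
    return float(np.mean(accs))


def select_gmm_M(
    vectors_by_M: dict[int, np.ndarray],
    y: np.ndarray,
    plan: FoldPlan,
    grid: "SVMGrid | None" = None,
    seed: int = 0,
    name: str = "gmm",
) -> tuple[int, CVReport, pd.DataFrame]:
    """Pick the mixture size by training accuracy, then evaluate it.

    For every candidate M the training-portion CV accuracy is computed;
    the argmax wins (ties go to the smaller M) and the final report is
    produced on the held-out folds at that M.  The accuracy-vs-M table
    is returned for inspection.
    """
    if not vectors_by_M:
        raise ValueError("vectors_by_M is empty")
    allowed = {1} | set(range(2, 31, 2))
    bad = set(vectors_by_M) - allowed
    if bad:
        raise ValueError(f"invalid M values: {sorted(bad)}")
    rows = []
    for M in sorted(vectors_by_M):
        acc = training_accuracy(np.asarray(vectors_by_M[M], dtype=float), y,
                                plan, grid, seed)
        rows.append({"M": M, "train_accuracy": acc})
    table = pd.DataFrame(rows)
    best_idx = int(table["train_accuracy"].idxmax())  # idxmax -> first max, smaller M
    chosen = int(table.loc[best_idx, "M"])
    report = run_svm_cv(np.asarray(vectors_by_M[chosen], dtype=float), y, plan,
                        grid, seed=seed, name=name)
    report.chosen_M = chosen
    return chosen, report, table


def compare_pipelines(reports: dict[str, CVReport]) -> dict:
    """Tabulate pipelines that share one fold plan.

    Returns a dict with a metric table (percent scale, mean ± sd), AUCs,
    pairwise accuracy differences, and per-pipeline ROC / score exports.
    """
    if not reports:
        raise ValueError("no reports to compare")
    hashes = {r.plan_hash for r in reports.values()}
    if len(hashes) != 1:
        raise ValueError(f"reports use different fold plans: {sorted(hashes)}")
    rows = []
    for name, rep in reports.items():
        agg = rep.aggregate()
        row = {"pipeline": name, "auc": rep.auc}
        for metric in ("accuracy", "specificity", "sensitivity", "f1"):
            row[f"{metric}_pct"] = 100.0 * agg[metric]["mean"]
            row[f"{metric}_sd_pct"] = 100.0 * agg[metric]["sd"]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("pipeline")
    names = list(reports)
    diffs = {
        f"{a} - {b}": 100.0 * (reports[a].accuracy - reports[b].accuracy)
        for i, a in enumerate(names) for b in names[i + 1:]
    }
    roc_data = {}
    for name, rep in reports.items():
        fpr, tpr, _ = rep.roc()
        roc_data[name] = {
            "fpr": fpr, "tpr": tpr,
            "scores": rep.scores, "true_labels": rep.true_labels,
        }
    return {"table": table, "accuracy_differences_pct": diffs, "roc": roc_data}
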