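"""Repeated stratified k-fold cross-validation with per-fold refitting.

Everything that looks at the class labels — the differential-expression
statistics, seed ranking, module discovery and classifier fitting — is
recomputed from each fold's training complement only, so the reported error
rate is free of feature-selection leakage.  The error rate is the fraction of
misclassified samples per repeat, averaged over repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import dlda_fit, dlda_predict, dqda_fit, dqda_predict, one_nn_predict
from .data import ExpressionDataset
from .mlda import mlda_fit, mlda_predict
from .modules import DEFAULT_R_GRID, build_module_set, correlation_matrix
from .mpclr import mpclr_fit, mpclr_predict
from .scoring import SamConfig, sam_statistic, select_seeds, t_statistic

__all__ = ["CVConfig", "CVResult", "FoldFit", "make_folds", "fit_fold", "run_cv"]

METHODS = ("mlda", "mpclr", "dlda", "dqda", "1nn")


@dataclass(frozen=True)
class CVConfig:
    method: str = "mlda"
    m: int = 5
    statistic: str = "t"
    k: int = 10
    repeats: int = 10
    seed: int = 0
    r_grid: tuple = DEFAULT_R_GRID
    stratified: bool = True
    shrinkage: bool = True
    corr_mode: str = "pooled_centered"
    sam: SamConfig = field(default_factory=SamConfig)
    rel_tol: float = 1e-8

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.statistic not in {"t", "sam"}:
            raise ValueError("statistic must be 't' or 'sam'")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")


def make_folds(labels, k: int, rng: np.random.Generator, stratified: bool = True) -> np.ndarray:
    """Assign each sample a fold in 0..k-1, stratified by class by default.

    Within each class the fold sizes differ by at most one.  The assignment
    is a deterministic function of the generator state.
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    folds = np.empty(n, dtype=int)
    if not stratified:
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % k
        return folds
    offset = 0  # continues across classes so total fold sizes stay balanced
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            warnings.warn(
                f"class {cls!r} has {len(idx)} samples for {k} folds; some folds "
                "will lack this class in their test split",
                UserWarning,
                stacklevel=2,
            )
        perm = rng.permutation(len(idx))
        folds[idx[perm]] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)
    return folds


@dataclass(frozen=True)
class FoldFit:
    """Training-side artifacts of one fold: scores, seeds, modules, model."""

    method: str
    scores: object
    seeds: np.ndarray
    module_set: object  # None for the diagonal/1NN baselines
    model: object

    def predict(self, test: ExpressionDataset) -> np.ndarray:
        if self.method == "mlda":
            return mlda_predict(self.model, test)[0]
        if self.method == "mpclr":
            return mpclr_predict(self.model, test)[0]
        if self.method == "dlda":
            return dlda_predict(self.model, test)[0]
        if self.method == "dqda":
            return dqda_predict(self.model, test)[0]
        return one_nn_predict(self.model, test)


def fit_fold(train: ExpressionDataset, cfg: CVConfig) -> FoldFit:
    """Run the full training pipeline (statistic -> seeds -> modules -> model)
    on a training split, never touching held-out samples."""
    scores = (
        t_statistic(train) if cfg.statistic == "t" else sam_statistic(train, cfg.sam)
    )
    seeds = select_seeds(scores, cfg.m)
    if cfg.method in {"mlda", "mpclr"}:
        corr = correlation_matrix(train, cfg.corr_mode)
        module_set = build_module_set(seeds, corr, scores, cfg.r_grid)
        if cfg.method == "mlda":
            model = mlda_fit(train, module_set, shrinkage=cfg.shrinkage, rel_tol=cfg.rel_tol)
        else:
            model = mpclr_fit(train, module_set)
        return FoldFit(cfg.method, scores, seeds, module_set, model)
    subset = train.subset_genes(seeds)
    if cfg.method == "dlda":
        model = dlda_fit(subset)
    elif cfg.method == "dqda":
        model = dqda_fit(subset)
    else:  # 1nn keeps the gene-selected training set itself
        model = subset
    return FoldFit(cfg.method, scores, seeds, None, model)


@dataclass(frozen=True)
class CVResult:
    per_repeat_errors: np.ndarray
    predictions: pd.DataFrame  # repeat, fold, sample_id, truth, predicted
    fold_assignments: np.ndarray  # repeats x n
    config: CVConfig

    @property
    def mean_error(self) -> float:
        return float(self.per_repeat_errors.mean())


def run_cv(data: ExpressionDataset, cfg: CVConfig) -> CVResult:
    """Repeated k-fold cross-validation; every sample is predicted exactly
    once per repeat.  A classifier failure inside a fold aborts the run with
    the repeat/fold context attached."""
    data.require_both_classes()
    rng = np.random.default_rng(cfg.seed)
    n = data.n_samples
    errors = np.empty(cfg.repeats)
    assignments = np.empty((cfg.repeats, n), dtype=int)
    rows = []
    for rep in range(cfg.repeats):
        folds = make_folds(data.labels, cfg.k, rng, cfg.stratified)
        assignments[rep] = folds
        wrong = 0
        for f in range(cfg.k):
            test_idx = np.flatnonzero(folds == f)
            train_idx = np.flatnonzero(folds != f)
            try:
                fold_fit = fit_fold(data.subset_samples(train_idx), cfg)
                predicted = fold_fit.predict(data.subset_samples(test_idx))
            except Exception as exc:
                raise RuntimeError(
                    f"classifier {cfg.method!r} failed in repeat {rep}, fold {f}: {exc}"
                ) from exc
            for j, pred in zip(test_idx, predicted):
                truth = data.labels[j]
                wrong += int(pred != truth)
                rows.append(
                    {
                        "repeat": rep,
                        "fold": f,
                        "sample_id": data.sample_ids[j],
                        "truth": truth,
                        "predicted": pred,
                    }
                )
        errors[rep] = wrong / n
    return CVResult(errors, pd.DataFrame(rows), assignments, cfg)


def cv_error_table(data: ExpressionDataset, cfg: CVConfig, methods, seed_counts):
    """Mean CV error for each (seed count, method) pair, as a table with one
    row per seed count — the layout used for benchmark comparisons.  The same
    base seed is used for every cell so all methods see the same fold splits.
    """
    table = {}
    for m in seed_counts:
        row = {}
        for method in methods:
            result = run_cv(data, replace(cfg, method=method, m=int(m)))
            row[method] = result.mean_error
        table[int(m)] = row
    frame = pd.DataFrame(table).T
    frame.index.name = "n_genes"
    return frame
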