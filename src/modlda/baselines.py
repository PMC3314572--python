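"""Diagonal discriminant baselines (DLDA, DQDA) and one-nearest-neighbour.

DLDA is the C = p limiting case of the modular discriminant: every gene is its
own covariance block, so gene-gene correlation is ignored and the pooled
per-gene variance scales each contribution.  DQDA additionally allows the two
classes their own variances, adding a variance-penalty term to the score.
Both share the modular classifier's class-size handling (DLDA the
log(n_B/n_A) threshold, DQDA a log(n_k/n) prior in each class score).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset
from .scoring import ZeroVarianceWarning

__all__ = [
    "DiagonalModel",
    "dlda_fit",
    "dlda_predict",
    "dqda_fit",
    "dqda_predict",
    "one_nn_predict",
]


@dataclass(frozen=True)
class DiagonalModel:
    kind: str  # "dlda" | "dqda"
    gene_ids: tuple
    mu_a: np.ndarray
    mu_b: np.ndarray
    var_pooled: np.ndarray | None
    var_a: np.ndarray | None
    var_b: np.ndarray | None
    n_a: int
    n_b: int
    class_names: dict = field(default_factory=lambda: {"A": "A", "B": "B"})

    @property
    def threshold(self) -> float:
        return float(np.log(self.n_b / self.n_a))


def _class_moments(data: ExpressionDataset):
    data.require_both_classes()
    if data.n_a < 2 or data.n_b < 2:
        raise ValueError("need at least two samples per class")
    xa = data.values[:, data.class_mask("A")]
    xb = data.values[:, data.class_mask("B")]
    return xa, xb


def _keep(data: ExpressionDataset, good: np.ndarray, what: str) -> np.ndarray:
    if not good.all():
        names = [data.gene_ids[i] for i in np.flatnonzero(~good)]
        warnings.warn(
            f"{len(names)} gene(s) with zero {what} variance excluded: {names[:10]}",
            ZeroVarianceWarning,
            stacklevel=3,
        )
    if not good.any():
        raise ValueError("no gene with positive variance remains")
    return np.flatnonzero(good)


def dlda_fit(data: ExpressionDataset) -> DiagonalModel:
    """Per-gene class means and pooled variances; zero-variance genes dropped."""
    xa, xb = _class_moments(data)
    var_pooled = (
        (data.n_a - 1) * xa.var(axis=1, ddof=1) + (data.n_b - 1) * xb.var(axis=1, ddof=1)
    ) / (data.n_a + data.n_b - 2)
    keep = _keep(data, var_pooled > 0, "pooled")
    return DiagonalModel(
        "dlda",
        tuple(data.gene_ids[i] for i in keep),
        xa.mean(axis=1)[keep],
        xb.mean(axis=1)[keep],
        var_pooled[keep],
        None,
        None,
        data.n_a,
        data.n_b,
        dict(data.class_names),
    )


def _model_rows(model: DiagonalModel, data: ExpressionDataset) -> np.ndarray:
    index = data.gene_index()
    try:
        rows = [index[g] for g in model.gene_ids]
    except KeyError as exc:
        raise KeyError(f"gene {exc.args[0]!r} required by the model is missing") from None
    return data.values[rows]


def dlda_predict(model: DiagonalModel, data: ExpressionDataset):
    """DLDA linear predictor; class A when LP >= log(n_B/n_A)."""
    x = _model_rows(model, data)
    direction = (model.mu_a - model.mu_b) / model.var_pooled
    lp = (x - 0.5 * (model.mu_a + model.mu_b)[:, None]).T @ direction
    labels = np.where(lp >= model.threshold, "A", "B").astype(object)
    return labels, lp


def dqda_fit(data: ExpressionDataset) -> DiagonalModel:
    """Per-gene, per-class means and variances; genes with a zero class
    variance are dropped."""
    xa, xb = _class_moments(data)
    var_a = xa.var(axis=1, ddof=1)
    var_b = xb.var(axis=1, ddof=1)
    keep = _keep(data, (var_a > 0) & (var_b > 0), "per-class")
    return DiagonalModel(
        "dqda",
        tuple(data.gene_ids[i] for i in keep),
        xa.mean(axis=1)[keep],
        xb.mean(axis=1)[keep],
        None,
        var_a[keep],
        var_b[keep],
        data.n_a,
        data.n_b,
        dict(data.class_names),
    )


def dqda_predict(model: DiagonalModel, data: ExpressionDataset):
    """Quadratic class scores with a log(n_k/n) prior; ties go to class A."""
    x = _model_rows(model, data)
    n = model.n_a + model.n_b

    def score(mu, var, n_k):
        quad = -0.5 * np.sum((x - mu[:, None]) ** 2 / var[:, None], axis=0)
        return quad - 0.5 * np.sum(np.log(var)) + np.log(n_k / n)

    d_a = score(model.mu_a, model.var_a, model.n_a)
    d_b = score(model.mu_b, model.var_b, model.n_b)
    labels = np.where(d_a >= d_b, "A", "B").astype(object)
    return labels, d_a - d_b


def one_nn_predict(train: ExpressionDataset, data: ExpressionDataset):
    """Label of the Euclidean-nearest training sample (over the genes of the
    training set); distance ties go to the lowest training-sample index."""
    if train.n_samples < 1:
        raise ValueError("training set is empty")
    index = data.gene_index()
    try:
        rows = [index[g] for g in train.gene_ids]
    except KeyError as exc:
        raise KeyError(f"gene {exc.args[0]!r} required by the model is missing") from None
    x = data.values[rows]  # p x n_new
    t = train.values  # p x n_train
    d2 = (
        np.sum(x**2, axis=0)[:, None]
        - 2.0 * x.T @ t
        + np.sum(t**2, axis=0)[None, :]
    )
    nearest = np.argmin(d2, axis=1)  # argmin takes the first (lowest) index on ties
    return train.labels[nearest].copy()
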