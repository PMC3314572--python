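"""Module first-principal-component logistic regression (super-gene model).

Each module is summarised by one "super-gene": the first principal component
of its z-scored member genes, computed by SVD on the training data with a
deterministic sign convention (the largest-magnitude loading is positive).
A plain logistic regression of the class indicator (Y = 1 for class A) on the
module scores then yields the classifier

    logit p_j = beta_0 + sum_c beta_c * PC1_cj .

The fit is maximum likelihood via IRLS with a capped iteration count; complete
separation is detected and flagged, with the coefficients at the stopping
point returned unpenalised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from .data import ExpressionDataset
from .modules import GeneModule, ModuleSet

__all__ = ["ModulePC", "MPCLRModel", "first_pc", "mpclr_fit", "mpclr_predict"]


@dataclass(frozen=True)
class ModulePC:
    """First-PC summary of one module: training normalisation + loadings."""

    gene_ids: tuple
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray

    def scores(self, data: ExpressionDataset) -> np.ndarray:
        index = data.gene_index()
        try:
            rows = [index[g] for g in self.gene_ids]
        except KeyError as exc:
            raise KeyError(
                f"gene {exc.args[0]!r} required by the model is missing"
            ) from None
        z = (data.values[rows].T - self.center) / self.scale
        return z @ self.loadings

    def to_dict(self) -> dict:
        return {
            "gene_ids": list(self.gene_ids),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModulePC":
        return cls(
            tuple(d["gene_ids"]),
            np.asarray(d["center"], dtype=float),
            np.asarray(d["scale"], dtype=float),
            np.asarray(d["loadings"], dtype=float),
        )


@dataclass(frozen=True)
class MPCLRModel:
    """Per-module PC summaries plus logistic coefficients (intercept first)."""

    module_pcs: tuple
    beta: np.ndarray
    diagnostics: dict = field(default_factory=dict, compare=False)
    class_names: dict = field(default_factory=lambda: {"A": "A", "B": "B"})

    def __post_init__(self):
        if len(self.beta) != len(self.module_pcs) + 1:
            raise ValueError("need one coefficient per module plus an intercept")

    def predict(self, data: ExpressionDataset):
        return mpclr_predict(self, data)

    def to_dict(self) -> dict:
        return {
            "module_pcs": [m.to_dict() for m in self.module_pcs],
            "beta": self.beta.tolist(),
            "diagnostics": {
                k: (bool(v) if isinstance(v, (bool, np.bool_)) else v)
                for k, v in self.diagnostics.items()
            },
            "class_names": dict(self.class_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MPCLRModel":
        return cls(
            tuple(ModulePC.from_dict(m) for m in d["module_pcs"]),
            np.asarray(d["beta"], dtype=float),
            dict(d.get("diagnostics", {})),
            dict(d.get("class_names", {"A": "A", "B": "B"})),
        )


def first_pc(data: ExpressionDataset, module: GeneModule):
    """First principal component of a module's z-scored expression.

    Returns the fitted :class:`ModulePC` and the training scores.  The sign is
    fixed so the largest-|loading| coordinate is positive, making repeated
    fits on identical data bit-reproducible.
    """
    if data.n_samples < 2:
        raise ValueError("first_pc needs at least 2 samples")
    members = list(module.members)
    x = data.values[members].T  # n x p_c
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    if np.any(scale == 0):
        bad = data.gene_ids[members[int(np.argmax(scale == 0))]]
        raise ValueError(f"zero-variance gene {bad!r} inside a module")
    z = (x - center) / scale
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e1 = vt[0]
    if e1[int(np.argmax(np.abs(e1)))] < 0:
        e1 = -e1
    pc = ModulePC(tuple(data.gene_ids[g] for g in members), center, scale, e1)
    return pc, z @ e1


def mpclr_fit(
    data: ExpressionDataset,
    modules: ModuleSet,
    max_iter: int = 100,
) -> MPCLRModel:
    """Logistic regression of the class indicator on per-module PC1 scores."""
    data.require_both_classes()
    if len(modules) == 0:
        raise ValueError("at least one module is required")
    if len(modules) >= data.n_samples:
        warnings.warn(
            f"{len(modules)} modules for {data.n_samples} samples: the logistic "
            "fit is overparameterised",
            UserWarning,
            stacklevel=2,
        )
    pcs, score_cols = [], []
    for mod in modules.modules:
        pc, s = first_pc(data, mod)
        pcs.append(pc)
        score_cols.append(s)
    design = np.column_stack([np.ones(data.n_samples)] + score_cols)
    y = (data.labels == "A").astype(float)

    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=max_iter)
    for w in caught:
        if issubclass(w.category, PerfectSeparationWarning):
            separated = True
        elif not issubclass(w.category, ConvergenceWarning):
            warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
    diagnostics = {
        "converged": bool(result.converged),
        "separated": separated,
        "n_iter": int(result.fit_history["iteration"]),
    }
    return MPCLRModel(tuple(pcs), np.asarray(result.params), diagnostics, dict(data.class_names))


def mpclr_predict(model: MPCLRModel, data: ExpressionDataset):
    """Class labels and P(class A) for new samples.

    Scores use the stored training normalisation and loadings; the decision
    threshold is p >= 0.5 (the boundary goes to class A).
    """
    scores = np.column_stack([pc.scores(data) for pc in model.module_pcs])
    eta = model.beta[0] + scores @ model.beta[1:]
    prob = expit(eta)
    labels = np.where(prob >= 0.5, "A", "B").astype(object)
    return labels, prob
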