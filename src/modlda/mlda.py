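"""Modular linear discriminant analysis with a block-diagonal covariance.

Each gene module contributes one covariance block.  Within a block the pooled
within-class covariance is estimated and then shrunk toward a single-
correlation structure: the diagonal keeps the pooled per-gene variances while
every off-diagonal entry is replaced by sigma_i * sigma_i' * r_c, where r_c is
the median of the block's pairwise pooled correlations.  Blocks are inverted
by SVD, falling back to the Moore-Penrose pseudo-inverse when a block is
singular (possible when a module holds more genes than there are samples).
The linear predictor is the sum of per-block LDA scores and a sample is
assigned to class A when it reaches log(n_B / n_A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset
from .modules import GeneModule, ModuleSet

__all__ = [
    "ModuleBlock",
    "MLDAModel",
    "estimate_block_covariance",
    "invert_block",
    "mlda_fit",
    "mlda_predict",
]


@dataclass(frozen=True)
class ModuleBlock:
    """Fitted per-module quantities: class means, shrunken covariance, inverse."""

    gene_ids: tuple
    mu_a: np.ndarray
    mu_b: np.ndarray
    sigma: np.ndarray
    sigma_inv: np.ndarray
    gene_sd: np.ndarray
    median_corr: float | None

    @property
    def p_c(self) -> int:
        return len(self.gene_ids)

    def to_dict(self) -> dict:
        return {
            "gene_ids": list(self.gene_ids),
            "mu_a": self.mu_a.tolist(),
            "mu_b": self.mu_b.tolist(),
            "sigma": self.sigma.tolist(),
            "sigma_inv": self.sigma_inv.tolist(),
            "gene_sd": self.gene_sd.tolist(),
            "median_corr": self.median_corr,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModuleBlock":
        return cls(
            tuple(d["gene_ids"]),
            np.asarray(d["mu_a"], dtype=float),
            np.asarray(d["mu_b"], dtype=float),
            np.asarray(d["sigma"], dtype=float),
            np.asarray(d["sigma_inv"], dtype=float),
            np.asarray(d["gene_sd"], dtype=float),
            d["median_corr"],
        )


@dataclass(frozen=True)
class MLDAModel:
    """Block-diagonal discriminant model; threshold is log(n_B / n_A)."""

    blocks: tuple
    n_a: int
    n_b: int
    class_names: dict = field(default_factory=lambda: {"A": "A", "B": "B"})
    provenance: dict = field(default_factory=dict, compare=False)

    @property
    def threshold(self) -> float:
        return float(np.log(self.n_b / self.n_a))

    def predict(self, data: ExpressionDataset):
        return mlda_predict(self, data)

    def to_dict(self) -> dict:
        return {
            "blocks": [b.to_dict() for b in self.blocks],
            "n_a": self.n_a,
            "n_b": self.n_b,
            "class_names": dict(self.class_names),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLDAModel":
        return cls(
            tuple(ModuleBlock.from_dict(b) for b in d["blocks"]),
            int(d["n_a"]),
            int(d["n_b"]),
            dict(d.get("class_names", {"A": "A", "B": "B"})),
            dict(d.get("provenance", {})),
        )


def invert_block(sigma: np.ndarray, rel_tol: float = 1e-8) -> np.ndarray:
    """SVD-based inverse of a symmetric covariance block.

    Singular values below ``rel_tol`` times the largest are zeroed and their
    reciprocals set to zero, yielding the Moore-Penrose pseudo-inverse for
    rank-deficient blocks; for well-conditioned blocks this equals the exact
    inverse to numerical precision.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("covariance block must be a square matrix")
    if not np.allclose(sigma, sigma.T, rtol=1e-8, atol=1e-12):
        raise ValueError("covariance block is not symmetric")
    u, s, vt = np.linalg.svd(sigma)
    if s[0] <= 0:
        raise np.linalg.LinAlgError("covariance block has rank 0")
    keep = s > rel_tol * s[0]
    if not keep.any():
        raise np.linalg.LinAlgError("covariance block has rank 0 at this tolerance")
    inv_s = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    return (vt.T * inv_s) @ u.T


def estimate_block_covariance(
    data: ExpressionDataset,
    module: GeneModule,
    shrinkage: bool = True,
    rel_tol: float = 1e-8,
) -> ModuleBlock:
    """Pooled within-class covariance of one module, with median-correlation
    shrinkage of the off-diagonal entries (optional), plus its (pseudo-)inverse.
    """
    data.require_both_classes()
    n_a, n_b = data.n_a, data.n_b
    if n_a + n_b < 3:
        raise ValueError("pooled covariance needs at least 3 samples")
    members = list(module.members)
    sub = data.values[members]
    xa = sub[:, data.class_mask("A")]
    xb = sub[:, data.class_mask("B")]
    mu_a = xa.mean(axis=1)
    mu_b = xb.mean(axis=1)
    ca = xa - mu_a[:, None]
    cb = xb - mu_b[:, None]
    pooled = (ca @ ca.T + cb @ cb.T) / (n_a + n_b - 2)

    var = np.diagonal(pooled)
    if np.any(var <= 0):
        bad = data.gene_ids[members[int(np.argmax(var <= 0))]]
        raise ValueError(f"zero pooled variance for gene {bad!r} inside a module")
    sd = np.sqrt(var)

    median_corr = None
    if shrinkage and len(members) > 1:
        corr = pooled / np.outer(sd, sd)
        iu = np.triu_indices(len(members), k=1)
        median_corr = float(np.median(corr[iu]))
        sigma = np.outer(sd, sd) * median_corr
        np.fill_diagonal(sigma, var)
    else:
        sigma = pooled.copy()

    return ModuleBlock(
        tuple(data.gene_ids[g] for g in members),
        mu_a,
        mu_b,
        sigma,
        invert_block(sigma, rel_tol),
        sd,
        median_corr,
    )


def mlda_fit(
    data: ExpressionDataset,
    modules: ModuleSet,
    shrinkage: bool = True,
    rel_tol: float = 1e-8,
    provenance: dict | None = None,
) -> MLDAModel:
    """Fit one covariance block per module and record the class counts."""
    data.require_both_classes()
    blocks = tuple(
        estimate_block_covariance(data, mod, shrinkage=shrinkage, rel_tol=rel_tol)
        for mod in modules.modules
    )
    return MLDAModel(
        blocks,
        data.n_a,
        data.n_b,
        dict(data.class_names),
        provenance or {"shrinkage": shrinkage, "rel_tol": rel_tol},
    )


def _block_columns(block: ModuleBlock, data: ExpressionDataset) -> np.ndarray:
    index = data.gene_index()
    try:
        rows = [index[g] for g in block.gene_ids]
    except KeyError as exc:
        raise KeyError(f"gene {exc.args[0]!r} required by the model is missing") from None
    return data.values[rows]


def mlda_predict(model: MLDAModel, data: ExpressionDataset):
    """Linear predictor and class labels for new samples.

    LP(x) = sum_c (x_c - (mu_Ac + mu_Bc)/2)' Sigma_c^-1 (mu_Ac - mu_Bc);
    class A when LP >= log(n_B / n_A) (the boundary goes to A), else B.
    """
    lp = np.zeros(data.n_samples)
    for block in model.blocks:
        x = _block_columns(block, data)  # p_c x n
        centered = x - 0.5 * (block.mu_a + block.mu_b)[:, None]
        direction = block.sigma_inv @ (block.mu_a - block.mu_b)
        lp += centered.T @ direction
    labels = np.where(lp >= model.threshold, "A", "B").astype(object)
    return labels, lp
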