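"""Per-gene two-sample differential-expression statistics and seed ranking.

Two statistics are provided: the pooled-variance two-sample t statistic and a
SAM-style moderated t in which a small positive constant ``s0`` is added to
every gene's standard error, stabilising genes with near-zero variance.  Genes
are ranked by decreasing absolute statistic and the top ``m`` become the seed
genes for module discovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import ExpressionDataset

__all__ = [
    "GeneScoreTable",
    "SamConfig",
    "t_statistic",
    "sam_statistic",
    "select_seeds",
]


class ZeroVarianceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class SamConfig:
    """How the SAM fudge constant ``s0`` is chosen.

    ``rule`` is one of ``"median_se"`` (median of the gene-wise standard
    errors, the default), ``"percentile"`` (the ``q``-th percentile of the
    standard errors) or ``"fixed"`` (use ``value`` directly).
    """

    rule: str = "median_se"
    q: float = 50.0
    value: float = 0.0

    def __post_init__(self):
        if self.rule not in {"median_se", "percentile", "fixed"}:
            raise ValueError(f"unknown s0 rule {self.rule!r}")
        if self.rule == "percentile" and not 0.0 <= self.q <= 100.0:
            raise ValueError("percentile q must be in [0, 100]")
        if self.rule == "fixed" and self.value < 0:
            raise ValueError("fixed s0 must be >= 0")

    def s0(self, se: np.ndarray) -> float:
        if self.rule == "median_se":
            return float(np.median(se))
        if self.rule == "percentile":
            return float(np.percentile(se, self.q))
        return float(self.value)


@dataclass(frozen=True)
class GeneScoreTable:
    """Per-gene statistics T_i with a deterministic |T| ranking.

    ``statistic`` holds one value per gene (NaN for genes excluded because
    their pooled variance is zero).  ``ranking`` lists the indices of the
    finite-statistic genes by decreasing |T|, ties broken by ascending gene
    index; it is a full permutation of ``0..p-1`` when no gene is excluded.
    """

    statistic: np.ndarray
    method: str
    ranking: np.ndarray

    def to_frame(self, gene_ids):
        import pandas as pd

        rank_of = {int(g): r for r, g in enumerate(self.ranking)}
        return pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "statistic": self.statistic,
                "rank": [rank_of.get(i, -1) for i in range(len(gene_ids))],
            }
        )


def _rank_by_abs(statistic: np.ndarray) -> np.ndarray:
    finite = np.flatnonzero(np.isfinite(statistic))
    order = np.argsort(-np.abs(statistic[finite]), kind="stable")
    return finite[order]


def _group_stats(data: ExpressionDataset):
    data.require_both_classes()
    if data.n_a < 2 or data.n_b < 2:
        raise ValueError(
            f"need at least two samples per class, got n_A={data.n_a}, n_B={data.n_b}"
        )
    xa = data.values[:, data.class_mask("A")]
    xb = data.values[:, data.class_mask("B")]
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    s2_pool = (
        (data.n_a - 1) * xa.var(axis=1, ddof=1)
        + (data.n_b - 1) * xb.var(axis=1, ddof=1)
    ) / (data.n_a + data.n_b - 2)
    se = np.sqrt(s2_pool * (1.0 / data.n_a + 1.0 / data.n_b))
    return diff, se


def _warn_zero_variance(data: ExpressionDataset, zero: np.ndarray) -> None:
    names = [data.gene_ids[i] for i in np.flatnonzero(zero)]
    warnings.warn(
        f"{len(names)} gene(s) with zero pooled variance excluded from "
        f"ranking: {names[:10]}",
        ZeroVarianceWarning,
        stacklevel=3,
    )


def t_statistic(data: ExpressionDataset) -> GeneScoreTable:
    """Pooled-variance two-sample t statistic per gene (A minus B).

    Genes whose pooled variance is exactly zero get a NaN statistic, are
    excluded from the ranking, and trigger a :class:`ZeroVarianceWarning`.
    """
    diff, se = _group_stats(data)
    statistic = np.full(data.n_genes, np.nan)
    ok = se > 0
    statistic[ok] = diff[ok] / se[ok]
    if not ok.all():
        _warn_zero_variance(data, ~ok)
    return GeneScoreTable(statistic, "t", _rank_by_abs(statistic))


def sam_statistic(data: ExpressionDataset, cfg: SamConfig = SamConfig()) -> GeneScoreTable:
    """SAM-style moderated t: T_i = (mean_A - mean_B) / (se_i + s0).

    With ``s0 = 0`` this reduces exactly to :func:`t_statistic`.
    """
    diff, se = _group_stats(data)
    if np.all(se == 0):
        raise ValueError("all genes have zero standard error; dataset is degenerate")
    s0 = cfg.s0(se)
    denom = se + s0
    statistic = np.full(data.n_genes, np.nan)
    ok = denom > 0
    statistic[ok] = diff[ok] / denom[ok]
    if not ok.all():
        _warn_zero_variance(data, ~ok)
    return GeneScoreTable(statistic, "sam", _rank_by_abs(statistic))


def select_seeds(scores: GeneScoreTable, m: int) -> np.ndarray:
    """Indices of the top ``m`` genes by |T|, in rank order."""
    if not 1 <= m <= len(scores.ranking):
        raise ValueError(
            f"m={m} out of range: {len(scores.ranking)} genes have a finite statistic"
        )
    return scores.ranking[:m].copy()
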