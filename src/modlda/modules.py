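"""Correlation-sharing module discovery on a Pearson co-expression network.

For each seed gene the search scans a grid of correlation cutoffs r and forms
the neighbourhood C_r(seed) = {s : |corr(seed, s)| >= r}; the module kept is
the neighbourhood whose average absolute differential-expression statistic is
maximal (ties broken toward the largest r, i.e. the smallest module).  Seeds
are processed in rank order and genes already claimed by an earlier module are
withheld from later searches, so the resulting modules are pairwise disjoint —
the property required for a block-diagonal covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset
from .scoring import GeneScoreTable, ZeroVarianceWarning

__all__ = [
    "DEFAULT_R_GRID",
    "CorrelationMatrix",
    "GeneModule",
    "ModuleSet",
    "correlation_matrix",
    "find_module",
    "build_module_set",
]

# ten cutoffs from 0.50 to 0.95 in steps of 0.05
DEFAULT_R_GRID = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


def _validate_grid(grid):
    grid = tuple(float(r) for r in grid)
    if len(grid) == 0:
        raise ValueError("the cutoff grid is empty")
    if any(not 0.0 <= r <= 1.0 for r in grid):
        raise ValueError("correlation cutoffs must lie in [0, 1]")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("correlation cutoffs must be strictly increasing")
    return grid


@dataclass(frozen=True)
class CorrelationMatrix:
    """p x p Pearson correlations; NaN rows mark zero-variance genes."""

    values: np.ndarray
    mode: str

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(np.diagonal(self.values))


@dataclass(frozen=True)
class GeneModule:
    """A seed gene plus its correlation-sharing members (seed included)."""

    seed: int
    members: tuple
    chosen_r: float
    score: float

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(sorted(int(m) for m in self.members)))
        if self.seed not in self.members:
            raise ValueError("the seed gene must be a member of its own module")


@dataclass(frozen=True)
class ModuleSet:
    """Disjoint, rank-ordered collection of gene modules."""

    modules: tuple
    assignment: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "modules", tuple(self.modules))
        assignment = {}
        for c, mod in enumerate(self.modules):
            for g in mod.members:
                if g in assignment:
                    raise ValueError(
                        f"gene index {g} belongs to modules {assignment[g]} and {c}; "
                        "modules must be disjoint"
                    )
                assignment[g] = c
        object.__setattr__(self, "assignment", assignment)

    def __len__(self) -> int:
        return len(self.modules)

    def to_frame(self, gene_ids):
        import pandas as pd

        rows = []
        for c, mod in enumerate(self.modules):
            rows.append(
                {
                    "module_index": c,
                    "seed_gene_id": gene_ids[mod.seed],
                    "chosen_r": mod.chosen_r,
                    "score": mod.score,
                    "n_genes": len(mod.members),
                    "member_gene_ids": ",".join(gene_ids[g] for g in mod.members),
                }
            )
        return pd.DataFrame(rows)


def correlation_matrix(
    data: ExpressionDataset, mode: str = "pooled_centered"
) -> CorrelationMatrix:
    """Gene-gene Pearson correlations over the samples.

    ``pooled_centered`` (default) centres each gene within its class before
    correlating, so class-mean separation does not masquerade as
    co-expression; ``overall`` is the plain Pearson correlation over all
    samples.  Zero-variance genes get NaN correlations and a warning.
    """
    if mode not in {"pooled_centered", "overall"}:
        raise ValueError(f"unknown correlation mode {mode!r}")
    if data.n_samples < 3:
        raise ValueError("correlation_matrix needs at least 3 samples")
    x = data.values.astype(float).copy()
    if mode == "pooled_centered":
        for k in ("A", "B"):
            mask = data.class_mask(k)
            if mask.any():
                x[:, mask] -= x[:, mask].mean(axis=1, keepdims=True)
    else:
        x -= x.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", x, x))
    ok = norms > 0
    if not ok.all():
        names = [data.gene_ids[i] for i in np.flatnonzero(~ok)]
        warnings.warn(
            f"{len(names)} zero-variance gene(s) excluded from the "
            f"co-expression network: {names[:10]}",
            ZeroVarianceWarning,
            stacklevel=2,
        )
    safe = np.where(ok, norms, 1.0)
    r = (x / safe[:, None]) @ (x / safe[:, None]).T
    r = np.clip(r, -1.0, 1.0)
    r[~ok, :] = np.nan
    r[:, ~ok] = np.nan
    np.fill_diagonal(r, np.where(ok, 1.0, np.nan))
    return CorrelationMatrix(r, mode)


def find_module(
    seed: int,
    corr: CorrelationMatrix,
    scores: GeneScoreTable,
    grid=DEFAULT_R_GRID,
    allowed: np.ndarray | None = None,
) -> GeneModule:
    """Correlation-sharing search around one seed gene.

    Scans the cutoff grid and returns the neighbourhood of the seed whose
    average |T| is largest; on ties the largest cutoff (smallest module) wins.
    ``allowed`` optionally restricts candidate members (the seed itself is
    always eligible).
    """
    grid = _validate_grid(grid)
    if not np.isfinite(scores.statistic[seed]):
        raise ValueError(f"seed gene index {seed} has no finite statistic")
    r_row = np.abs(corr.values[seed])
    abs_t = np.abs(scores.statistic)
    eligible = np.isfinite(r_row) & np.isfinite(abs_t)
    if allowed is not None:
        eligible &= np.asarray(allowed, dtype=bool)
    eligible[seed] = True
    r_row = np.where(eligible, r_row, -np.inf)
    r_row[seed] = 1.0

    best = None
    for r in sorted(grid, reverse=True):
        members = np.flatnonzero(r_row >= r)
        score = float(abs_t[members].mean())
        if best is None or score > best[0]:
            best = (score, r, members)
    score, chosen_r, members = best
    return GeneModule(int(seed), tuple(int(m) for m in members), chosen_r, score)


def build_module_set(
    seeds,
    corr: CorrelationMatrix,
    scores: GeneScoreTable,
    grid=DEFAULT_R_GRID,
) -> ModuleSet:
    """Run the module search for ranked seeds, claiming genes greedily.

    Higher-ranked seeds claim genes first; a seed absorbed by an earlier
    module yields no module of its own, so the result has at most as many
    modules as seeds and the modules are disjoint by construction.
    """
    seeds = [int(s) for s in seeds]
    if len(seeds) == 0:
        raise ValueError("seed list is empty")
    p = corr.values.shape[0]
    available = np.ones(p, dtype=bool)
    modules = []
    for seed in seeds:
        if not available[seed]:
            continue
        mod = find_module(seed, corr, scores, grid, allowed=available)
        modules.append(mod)
        available[list(mod.members)] = False
    return ModuleSet(tuple(modules))
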