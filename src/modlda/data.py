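"""Expression-matrix data model and delimited-text I/O.

The central container is :class:`ExpressionDataset`, a genes x samples matrix
of real-valued (log-scale) expression measurements with unique gene and sample
identifiers and a binary class label per sample.  Class labels are normalised
internally to ``"A"``/``"B"``; the original label names are retained so that
reports can use them.  Input matrices must be complete — missing or
non-numeric cells are rejected at load time rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "LoadError", "read_expression", "write_expression"]


class LoadError(ValueError):
    """Raised when an input file fails validation; names the offending record."""


def _unique_or_raise(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise LoadError(f"duplicate {what} {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class ExpressionDataset:
    """Genes x samples expression matrix with two-class sample labels.

    Parameters
    ----------
    values : (p, n) float array
        Expression measurements, genes as rows.
    gene_ids, sample_ids : sequences of unique strings.
    labels : length-n array of ``"A"``/``"B"``.
    class_names : mapping from internal ``"A"``/``"B"`` to the original label
        names (identity by default).
    """

    values: np.ndarray
    gene_ids: tuple
    sample_ids: tuple
    labels: np.ndarray
    class_names: dict = field(default_factory=lambda: {"A": "A", "B": "B"})

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))
        if values.ndim != 2:
            raise LoadError("expression values must be a 2-D matrix")
        p, n = values.shape
        if p < 1 or n < 2:
            raise LoadError(f"need at least 1 gene and 2 samples, got {p} x {n}")
        if len(self.gene_ids) != p:
            raise LoadError("gene_ids length does not match the matrix")
        if len(self.sample_ids) != n:
            raise LoadError("sample_ids length does not match the matrix")
        if len(self.labels) != n:
            raise LoadError("labels length does not match the number of samples")
        _unique_or_raise(self.gene_ids, "gene ID")
        _unique_or_raise(self.sample_ids, "sample ID")
        bad = set(self.labels) - {"A", "B"}
        if bad:
            raise LoadError(f"labels must be 'A' or 'B', got {sorted(bad)}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise LoadError(
                f"non-finite value for gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_a(self) -> int:
        return int(np.sum(self.labels == "A"))

    @property
    def n_b(self) -> int:
        return int(np.sum(self.labels == "B"))

    def class_mask(self, k: str) -> np.ndarray:
        return self.labels == k

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def require_both_classes(self) -> None:
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("both classes A and B must be present for fitting")

    # -- subsetting -----------------------------------------------------
    def subset_genes(self, indices) -> "ExpressionDataset":
        indices = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            self.values[indices],
            tuple(self.gene_ids[i] for i in indices),
            self.sample_ids,
            self.labels,
            dict(self.class_names),
        )

    def subset_samples(self, indices) -> "ExpressionDataset":
        indices = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            self.values[:, indices],
            self.gene_ids,
            tuple(self.sample_ids[i] for i in indices),
            self.labels[indices],
            dict(self.class_names),
        )


def _read_table(path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"{what} file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        return pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise LoadError(f"could not parse {what} file {path}: {exc}") from exc


def read_expression(
    matrix_path,
    labels_path,
    class_a: str | None = None,
    transpose: bool = False,
) -> ExpressionDataset:
    """Load a genes x samples matrix (TSV/CSV, gene IDs in the first column,
    sample IDs in the header) together with a two-column sample/class file.

    The class mapped to the internal label ``"A"`` is, by default, the one
    whose name sorts lexicographically first; ``class_a`` overrides this.
    ``transpose=True`` accepts a samples x genes matrix instead.
    """
    frame = _read_table(matrix_path, "expression matrix")
    if transpose:
        frame = frame.T
    gene_ids = [str(g) for g in frame.index]
    sample_ids = [str(s) for s in frame.columns]
    _unique_or_raise(gene_ids, "gene ID")
    _unique_or_raise(sample_ids, "sample ID")

    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise LoadError(
                    f"non-numeric cell {raw[i, j]!r} for gene {gene_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None

    label_path = Path(labels_path)
    if not label_path.exists():
        raise LoadError(f"labels file not found: {label_path}")
    sep = "," if label_path.suffix.lower() == ".csv" else "\t"
    lab = pd.read_csv(label_path, sep=sep, header=None, dtype=str, comment="#")
    if lab.shape[1] < 2:
        raise LoadError(f"labels file {label_path} must have two columns")
    if str(lab.iloc[0, 0]).lower() in {"sample_id", "sample"}:
        lab = lab.iloc[1:]
    mapping = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1].astype(str)))

    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise LoadError(f"samples missing from the label file: {missing}")
    raw_labels = [mapping[s] for s in sample_ids]
    classes = sorted(set(raw_labels))
    if len(classes) != 2:
        raise LoadError(f"expected exactly two classes, found {classes}")
    if class_a is None:
        class_a = classes[0]
    elif class_a not in classes:
        raise LoadError(f"class_a={class_a!r} not among the observed classes {classes}")
    class_b = [c for c in classes if c != class_a][0]
    labels = np.array(["A" if c == class_a else "B" for c in raw_labels], dtype=object)
    return ExpressionDataset(
        values, gene_ids, sample_ids, labels, {"A": class_a, "B": class_b}
    )


def write_expression(data: ExpressionDataset, matrix_path, labels_path) -> None:
    """Write a dataset back to a TSV matrix + two-column label file."""
    frame = pd.DataFrame(data.values, index=list(data.gene_ids), columns=list(data.sample_ids))
    frame.to_csv(matrix_path, sep="\t")
    with open(labels_path, "w") as fh:
        for s, lab in zip(data.sample_ids, data.labels):
            fh.write(f"{s}\t{data.class_names[lab]}\n")
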