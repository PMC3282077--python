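"""Log2 transform, replicate averaging, expression masking and gene collapse."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DesignTable, ExpressionMatrix, ProbeAnnotation

__all__ = [
    "AveragedData",
    "GeneMatrix",
    "to_log2",
    "average_replicates",
    "expression_mask",
    "collapse_to_genes",
]


@dataclass
class AveragedData:
    """Per-condition mean log2 intensities ('averaged data')."""

    probe_ids: list[str]
    condition_labels: list[str]
    values: np.ndarray  # probes x conditions, log2
    replicate_counts: dict[str, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.condition_labels)):
            raise ValueError("averaged grid does not match probe/condition lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite averaged value")

    def condition_index(self, label: str) -> int:
        try:
            return self.condition_labels.index(label)
        except ValueError:
            raise KeyError(f"condition {label!r} not present") from None


@dataclass
class GeneMatrix:
    """Gene-symbol x condition mean log2 intensities (unique-gene view)."""

    gene_symbols: list[str]
    condition_labels: list[str]
    values: np.ndarray
    probes_per_gene: dict[str, int]

    def condition_index(self, label: str) -> int:
        try:
            return self.condition_labels.index(label)
        except ValueError:
            raise KeyError(f"condition {label!r} not present") from None

    def gene_index(self, symbol: str) -> int:
        try:
            return self.gene_symbols.index(symbol)
        except ValueError:
            raise KeyError(f"gene {symbol!r} not present") from None


def to_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise base-2 logarithm of a linear-scale matrix."""
    if matrix.scale != "linear":
        raise ValueError("matrix is already on the log2 scale")
    if np.any(matrix.values <= 0):
        i, j = np.argwhere(matrix.values <= 0)[0]
        raise ValueError(
            f"non-positive intensity at probe {matrix.probe_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}: cannot log-transform"
        )
    return ExpressionMatrix(
        list(matrix.probe_ids), list(matrix.sample_ids), np.log2(matrix.values), scale="log2"
    )


def average_replicates(matrix: ExpressionMatrix, design: DesignTable) -> AveragedData:
    """Arithmetic mean of each probe over the replicates of each condition."""
    if matrix.scale != "log2":
        raise ValueError("replicate averaging expects log2-scale data")
    design.check_against(matrix)
    labels = design.conditions
    cols = np.empty((matrix.values.shape[0], len(labels)))
    counts: dict[str, int] = {}
    for k, cond in enumerate(labels):
        idx = [matrix.sample_index(s) for s in design.samples_for(cond)]
        counts[cond] = len(idx)
        cols[:, k] = matrix.values[:, idx].mean(axis=1)
    return AveragedData(list(matrix.probe_ids), labels, cols, counts)


def expression_mask(
    matrix: ExpressionMatrix,
    design: DesignTable,
    cond_a: str,
    cond_b: str,
    t: float = 4.0,
) -> np.ndarray:
    """Probes expressed above threshold ``t`` in ALL replicates of >= 1 condition.

    ``t`` is on the post-normalization log2 intensity scale. A probe passes
    when its minimum over the replicates of ``cond_a`` exceeds ``t``, or its
    minimum over the replicates of ``cond_b`` does.
    """
    if matrix.scale != "log2":
        raise ValueError("expression mask expects log2-scale data")
    masks = []
    for cond in (cond_a, cond_b):
        idx = [matrix.sample_index(s) for s in design.samples_for(cond)]
        masks.append(matrix.values[:, idx].min(axis=1) > t)
    return masks[0] | masks[1]


def collapse_to_genes(data: AveragedData, annotation: ProbeAnnotation) -> GeneMatrix:
    """Average the probes of each annotated gene symbol; drop unannotated probes."""
    by_gene: dict[str, list[int]] = {}
    for i, probe in enumerate(data.probe_ids):
        sym = annotation.symbol(probe)
        if sym is not None:
            by_gene.setdefault(sym, []).append(i)
    if not by_gene:
        raise ValueError("no annotated probes: gene collapse would be empty")
    symbols = sorted(by_gene)
    values = np.empty((len(symbols), len(data.condition_labels)))
    for g, sym in enumerate(symbols):
        values[g] = data.values[by_gene[sym]].mean(axis=0)
    return GeneMatrix(
        symbols,
        list(data.condition_labels),
        values,
        {s: len(by_gene[s]) for s in symbols},
    )
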