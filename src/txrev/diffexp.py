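"""Differential-expression calls for condition-vs-condition contrasts.

With duplicate arrays per condition a per-probe t-test has essentially no
power, so the test statistic borrows strength across probes: the null SD of
a probe's mean difference comes from the intensity-dependent noise model
(:mod:`txrev.noise`), giving a z statistic with a standard-normal reference.
Probes first pass an expression mask (above threshold ``t`` in all
replicates of at least one condition), p-values are adjusted by
Benjamini-Hochberg over the masked probes only, and a call additionally
requires the signed linear fold change to exceed ``fc_min`` in magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .io import DesignTable, ExpressionMatrix, ProbeAnnotation, signed_fold_change
from .noise import IntensityNoiseModel
from .preprocess import GeneMatrix, expression_mask

__all__ = [
    "ComparisonResult",
    "DEGeneSets",
    "DEFAULT_CONTRASTS",
    "benjamini_hochberg",
    "compare_conditions",
    "to_gene_sets",
]

log = logging.getLogger(__name__)

DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("A", "0"),
    ("Z", "0"),
    ("C", "0"),
    ("AZ", "0"),
    ("AC", "0"),
    ("ZC", "0"),
    ("AZC", "0"),
    ("AC", "A"),
    ("ZC", "C"),
    ("AZC", "AC"),
    ("AZ", "A"),
)
"""Canonical contrasts: each treatment vs untreated plus the rescue contrasts."""


@dataclass
class ComparisonResult:
    """Per-probe statistics for one contrast, as a tidy DataFrame.

    Columns: feature_id, mean_log2_a, mean_log2_b, log2_diff, signed_fc,
    z, p, q, passed_mask, called ({'up','down','none'}). Probes failing the
    expression mask carry NaN statistics and called='none'.
    """

    label: str
    table: pd.DataFrame
    alpha: float
    fc_min: float

    @property
    def up_probes(self) -> list[str]:
        return list(self.table.loc[self.table["called"] == "up", "feature_id"])

    @property
    def down_probes(self) -> list[str]:
        return list(self.table.loc[self.table["called"] == "down", "feature_id"])

    @property
    def n_called(self) -> int:
        return int((self.table["called"] != "none").sum())


@dataclass
class DEGeneSets:
    """Direction-resolved differentially expressed gene symbols."""

    label: str
    up: set[str]
    down: set[str]

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"genes called in both directions: {sorted(overlap)}")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_conditions(
    matrix: ExpressionMatrix,
    design: DesignTable,
    cond_a: str,
    cond_b: str,
    noise: IntensityNoiseModel,
    t: float = 4.0,
    alpha: float = 0.05,
    fc_min: float = 1.5,
) -> ComparisonResult:
    """Call probes differentially expressed between ``cond_a`` and ``cond_b``.

    Fold changes are signed ``cond_a`` relative to ``cond_b`` (positive =
    higher in ``cond_a``). The fold-change filter is strict: |FC| must
    exceed ``fc_min``.
    """
    if cond_a == cond_b:
        raise ValueError("contrast requires two distinct condition labels")
    if matrix.scale != "log2":
        raise ValueError("comparisons expect log2-scale data")
    idx_a = [matrix.sample_index(s) for s in design.samples_for(cond_a)]
    idx_b = [matrix.sample_index(s) for s in design.samples_for(cond_b)]
    n_a, n_b = len(idx_a), len(idx_b)

    mean_a = matrix.values[:, idx_a].mean(axis=1)
    mean_b = matrix.values[:, idx_b].mean(axis=1)
    diff = mean_a - mean_b
    fc = signed_fold_change(diff)
    mask = expression_mask(matrix, design, cond_a, cond_b, t=t)

    z = np.full(len(diff), np.nan)
    p = np.full(len(diff), np.nan)
    q = np.full(len(diff), np.nan)
    called = np.array(["none"] * len(diff), dtype=object)
    if mask.any():
        intensity = (mean_a + mean_b) / 2.0
        se = noise.sd_at(intensity[mask]) * np.sqrt(1.0 / n_a + 1.0 / n_b)
        z[mask] = diff[mask] / se
        p[mask] = 2.0 * norm.sf(np.abs(z[mask]))
        q[mask] = benjamini_hochberg(p[mask])
        sig = mask & (q <= alpha) & (np.abs(fc) > fc_min)
        called[sig & (diff > 0)] = "up"
        called[sig & (diff < 0)] = "down"
    else:
        log.warning("contrast %s-%s: expression mask is empty, no calls", cond_a, cond_b)

    table = pd.DataFrame(
        {
            "feature_id": matrix.probe_ids,
            "mean_log2_a": mean_a,
            "mean_log2_b": mean_b,
            "log2_diff": diff,
            "signed_fc": fc,
            "z": z,
            "p": p,
            "q": q,
            "passed_mask": mask,
            "called": called,
        }
    )
    return ComparisonResult(f"{cond_a}-{cond_b}", table, alpha, fc_min)


def to_gene_sets(
    result: ComparisonResult,
    annotation: ProbeAnnotation,
    gene_matrix: GeneMatrix,
    cond_a: str | None = None,
    cond_b: str | None = None,
    fc_min: float | None = None,
) -> DEGeneSets:
    """Lift probe-level calls to unique gene symbols.

    A gene enters the up (down) set when at least one of its probes is
    called in that direction AND the gene-level fold change (from the
    averaged, collapsed matrix) exceeds ``fc_min`` in the same direction.
    Genes whose probes disagree in direction are dropped with a warning.
    """
    if cond_a is None or cond_b is None:
        cond_a, cond_b = result.label.split("-", 1)
    if fc_min is None:
        fc_min = result.fc_min
    ja = gene_matrix.condition_index(cond_a)
    jb = gene_matrix.condition_index(cond_b)
    gene_fc = signed_fold_change(gene_matrix.values[:, ja] - gene_matrix.values[:, jb])
    fc_of = dict(zip(gene_matrix.gene_symbols, gene_fc))

    votes: dict[str, set[str]] = {}
    for direction, probes in (("up", result.up_probes), ("down", result.down_probes)):
        for probe in probes:
            sym = annotation.symbol(probe)
            if sym is not None:
                votes.setdefault(sym, set()).add(direction)

    up: set[str] = set()
    down: set[str] = set()
    for sym, dirs in votes.items():
        if len(dirs) > 1:
            log.warning("gene %s has probes called in both directions; dropped", sym)
            continue
        fc = fc_of.get(sym)
        if fc is None:
            continue
        if "up" in dirs and fc > fc_min:
            up.add(sym)
        elif "down" in dirs and fc < -fc_min:
            down.add(sym)
    return DEGeneSets(result.label, up, down)
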