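"""Hypergeometric gene-set over-representation with FDR and overlap filters.

Given a query gene list, a universe of testable symbols and a gene-set
collection, each set is scored by the upper-tail hypergeometric probability
of its observed overlap with the query. Sets are restricted to a size range
(measured after intersection with the universe), p-values are adjusted by
Benjamini-Hochberg across the tested sets, and a set is significant when
its q-value passes the FDR cut AND the overlap reaches a minimum gene
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .diffexp import benjamini_hochberg
from .io import GeneSetCollection

__all__ = ["EnrichmentResult", "hypergeom_tail", "enrich"]

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """One row per tested set, sorted by q-value."""

    table: pd.DataFrame
    universe_size: int
    query_size: int
    fdr: float
    min_overlap: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def hypergeom_tail(overlap: int, query: int, set_size: int, universe: int) -> float:
    """P[X >= overlap] for X ~ Hypergeometric(universe, set_size, query)."""
    if not (0 <= overlap <= min(query, set_size) and max(query, set_size) <= universe):
        raise ValueError(
            f"invalid hypergeometric configuration: k={overlap}, n={query}, "
            f"K={set_size}, N={universe}"
        )
    if overlap == 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, universe, set_size, query))


def enrich(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    fdr: float = 0.10,
    min_overlap: int = 5,
    min_size: int = 8,
    max_size: int = 500,
) -> EnrichmentResult:
    """Test every eligible set in the collection for query over-representation."""
    if not universe:
        raise ValueError("empty universe")
    universe = set(universe)
    outside = set(query) - universe
    if outside:
        log.warning("%d query genes outside the universe dropped", len(outside))
    query = set(query) & universe

    rows = []
    for name, members in collection:
        in_universe = members & universe
        size = len(in_universe)
        if not min_size <= size <= max_size:
            continue
        overlap = in_universe & query
        p = hypergeom_tail(len(overlap), len(query), size, len(universe))
        rows.append((name, size, len(overlap), ",".join(sorted(overlap)), p))

    table = pd.DataFrame(
        rows, columns=["set_name", "set_size", "overlap_size", "overlap_symbols", "p"]
    )
    if len(table):
        table["q"] = benjamini_hochberg(table["p"].to_numpy())
        table["significant"] = (table["q"] <= fdr) & (table["overlap_size"] >= min_overlap)
        table = table.sort_values(["q", "p", "set_name"], kind="stable").reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return EnrichmentResult(table, len(universe), len(query), fdr, min_overlap)
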