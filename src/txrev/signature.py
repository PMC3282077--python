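"""Consensus gene signatures by voting across independent study gene sets.

A gene belongs to the consensus "up" (or "down") signature when it appears
in the up-sets (down-sets) of at least ``min_votes`` of the contributing
studies. Symbols are upper-cased before voting since public gene-set
collections mix capitalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .diffexp import DEGeneSets

__all__ = ["ConsensusSignature", "build_consensus", "intersect_with_de"]

log = logging.getLogger(__name__)


@dataclass
class ConsensusSignature:
    up: set[str]
    down: set[str]
    votes_up: dict[str, int]
    votes_down: dict[str, int]
    n_studies: int
    min_votes: int
    conflicting: set[str] = field(default_factory=set)  # members of both lists


def _count_votes(sets: Sequence[Iterable[str]]) -> dict[str, int]:
    votes: dict[str, int] = {}
    for s in sets:
        for sym in {str(g).upper() for g in s}:
            votes[sym] = votes.get(sym, 0) + 1
    return votes


def build_consensus(
    up_sets: Sequence[Iterable[str]],
    down_sets: Sequence[Iterable[str]],
    min_votes: int = 2,
) -> ConsensusSignature:
    """Vote over per-study up/down gene sets; keep symbols with enough votes.

    A symbol supported in both directions by different studies is kept in
    both lists and flagged in ``conflicting``; downstream intersections are
    direction-matched so nothing is double counted.
    """
    if min_votes < 1:
        raise ValueError("min_votes must be >= 1")
    n_studies = max(len(up_sets), len(down_sets))
    if min_votes > n_studies:
        log.warning(
            "min_votes=%d exceeds the %d contributing studies; signature is empty",
            min_votes, n_studies,
        )
    votes_up = _count_votes(up_sets)
    votes_down = _count_votes(down_sets)
    up = {g for g, v in votes_up.items() if v >= min_votes}
    down = {g for g, v in votes_down.items() if v >= min_votes}
    conflicting = up & down
    if conflicting:
        log.warning("%d symbols supported in both directions", len(conflicting))
    return ConsensusSignature(up, down, votes_up, votes_down, n_studies, min_votes, conflicting)


def intersect_with_de(
    signature: ConsensusSignature, de: DEGeneSets
) -> tuple[set[str], set[str]]:
    """Direction-matched intersection of a consensus signature with DE calls."""
    de_up = {g.upper() for g in de.up}
    de_down = {g.upper() for g in de.down}
    return signature.up & de_up, signature.down & de_down
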