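"""Reversal scoring: does a counter-treatment undo a primary effect?

For each gene, the primary contrast (e.g. cobalt vs untreated, C-0) gives a
signed fold change, and the counter contrast (zinc+cobalt vs cobalt, ZC-C)
gives a second one. A gene is

* ``reversed`` when the counter fold change has the opposite sign and its
  magnitude strictly exceeds the threshold (default 1.5-fold),
* ``partial`` when the sign is opposite but the magnitude does not exceed
  the threshold,
* ``none`` when the counter change has the same sign (or no change).

The headline statistic is the count of reversed genes per primary
direction. :func:`band_fraction` quantifies the companion scatter-plot
view: after the counter-treatment, what fraction of the originally
modulated genes lies back inside the |FC| <= 1.5 band around baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import SharedGeneRecord

__all__ = ["ReversalReport", "classify_reversal", "summarize_reversal", "band_fraction"]

STATUSES = ("reversed", "partial", "none")


@dataclass
class ReversalReport:
    """Per-gene reversal classifications plus per-direction summary counts."""

    table: pd.DataFrame  # columns: gene, direction, fc_primary, fc_counter, status
    counts: dict[str, dict[str, int]]  # direction -> status -> count
    fc_threshold: float

    def n_reversed(self, direction: str) -> int:
        return self.counts[direction]["reversed"]

    def n_total(self, direction: str) -> int:
        return sum(self.counts[direction].values())

    def summary_dict(self) -> dict:
        return {"fc_threshold": self.fc_threshold, "counts": self.counts}


def _check_fc(fc: float, name: str) -> None:
    if -1.0 < fc < 1.0:
        raise ValueError(
            f"{name}={fc} violates the signed fold-change convention (|FC| >= 1)"
        )


def classify_reversal(
    fc_primary: float, fc_counter: float, fc_threshold: float = 1.5
) -> str:
    """Classify one gene as 'reversed', 'partial' or 'none' (strict threshold)."""
    _check_fc(fc_primary, "fc_primary")
    _check_fc(fc_counter, "fc_counter")
    opposite = (fc_primary > 0) != (fc_counter > 0)
    if not opposite:
        return "none"
    return "reversed" if abs(fc_counter) > fc_threshold else "partial"


def summarize_reversal(
    records: Sequence[SharedGeneRecord], fc_threshold: float = 1.5
) -> ReversalReport:
    """Classify every record and tally statuses per primary direction."""
    rows = []
    counts = {d: {s: 0 for s in STATUSES} for d in ("up", "down")}
    for rec in records:
        status = classify_reversal(rec.fc_primary, rec.fc_counter, fc_threshold)
        direction = rec.direction
        if direction not in counts:
            counts[direction] = {s: 0 for s in STATUSES}
        counts[direction][status] += 1
        rows.append((rec.gene, direction, rec.fc_primary, rec.fc_counter, status))
    table = pd.DataFrame(
        rows, columns=["gene", "direction", "fc_primary", "fc_counter", "status"]
    )
    return ReversalReport(table, counts, fc_threshold)


def band_fraction(fc_net: Iterable[float], band: float = 1.5) -> float:
    """Fraction of net fold changes (vs baseline) inside the |FC| <= band strip."""
    values = [float(f) for f in fc_net]
    if not values:
        raise ValueError("band_fraction needs at least one fold change")
    for fc in values:
        _check_fc(fc, "fc_net")
    inside = sum(1 for fc in values if abs(fc) <= band)
    return inside / len(values)
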