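"""Three-set Venn partition of DE gene lists and the named response clusters.

The three contrasts of interest are the zinc rescue atop drug+cobalt
(AZC-AC), the zinc rescue atop cobalt alone (ZC-C), and the drug effect
itself (A-0). Genes shared by the rescue-with-drug and drug contrasts but
not the rescue-alone contrast (clusters ``pink`` for up, ``green`` for
down) are candidate drug-response genes restored by zinc; genes shared by
the two rescue contrasts (``light_blue`` up, ``violet`` down) respond to
zinc irrespective of the drug. The triple intersection is reported as its
own region and excluded from both cluster pairs by default.
"""

from __future__ import annotations

from dataclasses import dataclass

from .diffexp import DEGeneSets

__all__ = ["VennPartition", "venn3", "assign_clusters"]

REGIONS = ("a_only", "b_only", "c_only", "ab", "ac", "bc", "abc")


@dataclass
class VennPartition:
    """The 7 disjoint membership regions of three labelled sets."""

    labels: tuple[str, str, str]
    regions: dict[str, frozenset[str]]

    def size(self, region: str) -> int:
        return len(self.regions[region])

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.regions.values():
            out |= members
        return frozenset(out)


def venn3(
    a: set[str],
    b: set[str],
    c: set[str],
    labels: tuple[str, str, str] = ("a", "b", "c"),
) -> VennPartition:
    a, b, c = set(a), set(b), set(c)
    regions = {
        "a_only": frozenset(a - b - c),
        "b_only": frozenset(b - a - c),
        "c_only": frozenset(c - a - b),
        "ab": frozenset((a & b) - c),
        "ac": frozenset((a & c) - b),
        "bc": frozenset((b & c) - a),
        "abc": frozenset(a & b & c),
    }
    return VennPartition(tuple(labels), regions)


def assign_clusters(
    up_partition: VennPartition,
    down_partition: VennPartition,
    include_triple_in_shared: bool = False,
) -> dict[str, frozenset[str]]:
    """Name the response clusters from directional Venn partitions.

    Both partitions must be built with role order (rescue-with-drug,
    rescue-alone, drug), i.e. (AZC-AC, ZC-C, A-0). ``pink``/``green`` are
    the up/down genes in rescue-with-drug AND drug but NOT rescue-alone
    (region ``ac``); ``light_blue``/``violet`` are the up/down genes shared
    by the two rescue contrasts (region ``ab``, with the triple region
    optionally folded in); the triple intersections are returned separately.
    """
    if up_partition.labels != down_partition.labels:
        raise ValueError("up and down partitions use different set labels")
    if len(up_partition.labels) != 3:
        raise ValueError("cluster assignment needs exactly three labelled sets")

    def shared(p: VennPartition) -> frozenset[str]:
        if include_triple_in_shared:
            return p.regions["ab"] | p.regions["abc"]
        return p.regions["ab"]

    return {
        "pink": up_partition.regions["ac"],
        "green": down_partition.regions["ac"],
        "light_blue": shared(up_partition),
        "violet": shared(down_partition),
        "triple_up": up_partition.regions["abc"],
        "triple_down": down_partition.regions["abc"],
    }


def partition_de_results(
    rescue_drug: DEGeneSets, rescue_alone: DEGeneSets, drug: DEGeneSets,
    include_triple_in_shared: bool = False,
) -> dict[str, frozenset[str]]:
    """Convenience wrapper: build both partitions from DE results and cluster."""
    labels = (rescue_drug.label, rescue_alone.label, drug.label)
    up = venn3(rescue_drug.up, rescue_alone.up, drug.up, labels)
    down = venn3(rescue_drug.down, rescue_alone.down, drug.down, labels)
    return assign_clusters(up, down, include_triple_in_shared)
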