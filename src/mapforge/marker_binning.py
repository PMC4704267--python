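"""Collapse markers with identical segregation patterns before ordering.

Markers whose call vectors are byte-for-byte identical (missing counts as a
distinct symbol, so binning is order-independent) are clustered; only the
first member in input order enters linkage analysis and the rest are
re-inserted at its map position afterwards.
"""
from __future__ import annotations

from dataclasses import dataclass

from .model import CALL_SYMBOLS, GenotypeMatrix, LinkageGroup, LinkageMap, MapforgeError


@dataclass
class Bin:
    representative: str
    members: list[str]  # includes the representative, in input order
    pattern_key: str


@dataclass
class BinSet:
    bins: list[Bin]

    def member_map(self) -> dict[str, str]:
        """marker_id -> representative marker_id."""
        return {m: b.representative for b in self.bins for m in b.members}


def bin_markers(g: GenotypeMatrix) -> BinSet:
    """Exact-equality clustering of call vectors; the representative is the
    first member in input order, and bins are listed in that order too."""
    seen: dict[bytes, Bin] = {}
    order: list[Bin] = []
    for i, mid in enumerate(g.marker_ids):
        key = g.calls[i].tobytes()
        b = seen.get(key)
        if b is None:
            b = Bin(mid, [mid], "".join(CALL_SYMBOLS[g.calls[i]]))
            seen[key] = b
            order.append(b)
        else:
            b.members.append(mid)
    return BinSet(order)


def representatives_matrix(g: GenotypeMatrix, bins: BinSet) -> GenotypeMatrix:
    reps = {b.representative for b in bins.bins}
    mask = [m in reps for m in g.marker_ids]
    return g.subset(marker_mask=mask)


def expand_bins(linkage_map: LinkageMap, bins: BinSet) -> LinkageMap:
    """Insert every bin member at its representative's cM position. Co-located
    loci are ordered by marker_id for determinism."""
    by_rep = {b.representative: b for b in bins.bins}
    groups = []
    for g in linkage_map.groups:
        loci: list[tuple[str, float]] = []
        for mid, cm in g.loci:
            b = by_rep.get(mid)
            if b is None:
                raise MapforgeError(
                    f"map locus {mid!r} is not a bin representative"
                )
            loci.extend((m, cm) for m in sorted(b.members))
        groups.append(LinkageGroup(g.group_id, loci))
    return LinkageMap(linkage_map.population_id, groups, dict(linkage_map.metadata))
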