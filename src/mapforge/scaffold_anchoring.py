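"""Anchor unplaced scaffolds onto chromosomes via their mapped markers.

A scaffold is anchored to the chromosome assigned to the linkage group of
its markers; its genetic position is the median cM of its markers, kept
separately per population (maps have different scales, so no cross-
population averaging). Orientation is the sign of the (offset, cM) rank
correlation and is only called when at least two markers have distinct cM
and distinct offsets.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import spearmanr

from .model import LinkageMap, MapforgeError, MareyMap, Scaffold, ScaffoldSet


@dataclass
class ScaffoldAnchor:
    scaffold_id: str
    length: int
    chromosome: Optional[str]
    cm_position: dict[str, float]  # population_id -> median cM
    orientation: str  # '+', '-', 'UNKNOWN'
    support: list[str]  # populations whose maps place this scaffold
    status: str  # 'anchored', 'skipped', 'conflicting'
    reason: str = ""


@dataclass
class AnchorSummary:
    n_anchored: int
    total_anchored_length: int
    n_skipped: int
    n_conflicting: int


def _scaffold_evidence(
    scaffold: Scaffold, linkage_map: LinkageMap, assignment: dict[str, str]
):
    """(chromosome | None, median cM, [(offset, cM)]) for one population, or
    None when the map places none of the scaffold's markers. A chromosome of
    None with markers present signals an intra-population group conflict."""
    group_of = linkage_map.group_of()
    cm_of = linkage_map.cm_of()
    hits = [(off, cm_of[mid], group_of[mid]) for mid, off in scaffold.markers if mid in group_of]
    if not hits:
        return None
    groups = {h[2] for h in hits}
    if len(groups) > 1:
        return (None, np.nan, [])
    chrom = assignment.get(next(iter(groups)))
    pairs = [(off, cm) for off, cm, _ in hits]
    return (chrom, float(np.median([c for _, c in pairs])), pairs)


def anchor_scaffolds(
    scaffolds: ScaffoldSet,
    maps: Union[LinkageMap, Sequence[LinkageMap]],
    assignment: Union[dict[str, str], Sequence[dict[str, str]]],
) -> tuple[list[ScaffoldAnchor], AnchorSummary]:
    """Anchor every scaffold with mapped markers; scaffolds with no mapped
    marker are skipped with a reason, and scaffolds whose markers disagree on
    the group/chromosome are flagged as conflicting, not anchored."""
    if isinstance(maps, LinkageMap):
        maps = [maps]
    if isinstance(assignment, dict):
        assignments = [assignment] * len(maps)
    else:
        assignments = list(assignment)
    if len(assignments) != len(maps):
        raise MapforgeError("one group->chromosome assignment required per map")

    anchors: list[ScaffoldAnchor] = []
    for s in scaffolds.entries:
        per_pop = {}
        for lm, asg in zip(maps, assignments):
            ev = _scaffold_evidence(s, lm, asg)
            if ev is not None:
                per_pop[lm.population_id] = ev
        if not per_pop:
            anchors.append(
                ScaffoldAnchor(s.scaffold_id, s.length, None, {}, "UNKNOWN", [],
                               "skipped", "no mapped marker")
            )
            continue
        chroms = {ev[0] for ev in per_pop.values()}
        if None in chroms or len(chroms - {None}) > 1:
            anchors.append(
                ScaffoldAnchor(s.scaffold_id, s.length, None, {}, "UNKNOWN",
                               sorted(per_pop), "conflicting", "conflicting anchor")
            )
            continue
        chrom = next(iter(chroms))
        pairs_all = [p for ev in per_pop.values() for p in ev[2]]
        orientation = _orientation(pairs_all)
        anchors.append(
            ScaffoldAnchor(
                s.scaffold_id, s.length, chrom,
                {pop: ev[1] for pop, ev in per_pop.items()},
                orientation, sorted(per_pop), "anchored",
            )
        )

    anchored = [a for a in anchors if a.status == "anchored"]
    summary = AnchorSummary(
        n_anchored=len(anchored),
        total_anchored_length=sum(a.length for a in anchored),
        n_skipped=sum(a.status == "skipped" for a in anchors),
        n_conflicting=sum(a.status == "conflicting" for a in anchors),
    )
    return anchors, summary


def _orientation(pairs: list[tuple[int, float]]) -> str:
    offs = [p[0] for p in pairs]
    cms = [p[1] for p in pairs]
    if len(pairs) < 2 or len(set(offs)) < 2 or len(set(np.round(cms, 9))) < 2:
        return "UNKNOWN"
    rho = spearmanr(offs, cms).statistic
    if rho is None or np.isnan(rho) or rho == 0:
        return "UNKNOWN"
    return "+" if rho > 0 else "-"


def insertion_bp(marey: MareyMap, cm: float) -> int:
    """Physical insertion coordinate for an anchored scaffold: linear
    interpolation of the local Marey segment at its genetic position."""
    pts = marey.points
    return int(round(float(np.interp(cm, pts[:, 1], pts[:, 0]))))
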