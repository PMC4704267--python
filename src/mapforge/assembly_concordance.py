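"""Genetic-vs-physical order concordance: detect and apply assembly fixes.

The detector walks each assembly chromosome in physical order and compares
it with the linkage map assigned to that chromosome. Markers belonging to a
foreign linkage group form MOVE candidates; the remaining markers are
segmented into maximal runs monotone in genetic position — a strictly
decreasing run is an inverted block (REORIENT), a monotone run whose cM
interval is displaced relative to the backbone is a REPOSITION_WITHIN, and
lone out-of-place markers are reported as singletons rather than
corrections. A whole chromosome whose map runs backwards is flagged as a
chromosome-orientation issue, not emitted as per-segment noise.

Greedy left-to-right segmentation systematically leaves the apex marker of
an inverted block in the preceding ascending run; a peak-reassignment pass
moves it into the descending run whenever reversing the extended run
restores local sorted order, which makes planted inversions recoverable
with exact marker boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .data_io import AgpPiece
from .model import (
    Action,
    CorrectionEntry,
    CorrectionLedger,
    LinkageMap,
    MapforgeError,
    PhysicalPlacement,
    Support,
)


@dataclass
class GroupAssignment:
    """Partial bijection between linkage groups and assembly chromosomes."""

    assignment: dict[str, str]  # group_id -> chromosome
    unresolved: list[str] = field(default_factory=list)  # ties
    conflicts: list[tuple[str, str, str]] = field(default_factory=list)  # (chrom, winner, loser)

    def chromosome_to_group(self) -> dict[str, str]:
        return {c: g for g, c in self.assignment.items()}


def assign_groups_to_chromosomes(
    linkage_map: LinkageMap, placement: PhysicalPlacement
) -> GroupAssignment:
    """Assign each linkage group to the chromosome holding the majority of its
    placed markers. Majority ties are left unresolved; when two groups claim
    one chromosome, the group with more markers there wins and the loss is
    reported as a conflict."""
    chrom_of = dict(
        placement.records[["marker_id", "chromosome"]].itertuples(index=False, name=None)
    )
    votes: dict[str, tuple[str, int]] = {}
    unresolved: list[str] = []
    for g in linkage_map.groups:
        counts: dict[str, int] = {}
        for m in g.marker_ids():
            c = chrom_of.get(m)
            if c is not None:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            unresolved.append(g.group_id)
            continue
        best = max(counts.values())
        winners = [c for c, n in counts.items() if n == best]
        if len(winners) > 1:
            unresolved.append(g.group_id)
        else:
            votes[g.group_id] = (winners[0], best)

    assignment: dict[str, str] = {}
    conflicts: list[tuple[str, str, str]] = []
    claimed: dict[str, str] = {}
    for gid in sorted(votes, key=lambda g: -votes[g][1]):
        chrom, _ = votes[gid]
        if chrom in claimed:
            conflicts.append((chrom, claimed[chrom], gid))
        else:
            claimed[chrom] = gid
            assignment[gid] = chrom
    return GroupAssignment(assignment, unresolved, conflicts)


# ---------------------------------------------------------------- detection

def _monotone_runs(cm: np.ndarray) -> list[tuple[int, int, int]]:
    """Greedy maximal monotone runs over ``cm``; returns (start, end inclusive,
    direction) with direction +1 ascending/flat, -1 strictly descending, after
    the peak-reassignment fix."""
    n = len(cm)
    runs: list[list[int]] = []  # [start, end, dir]
    i = 0
    while i < n:
        j = i
        direction = 0
        while j + 1 < n:
            step = cm[j + 1] - cm[j]
            if step > 0:
                if direction < 0:
                    break
                direction = 1
            elif step < 0:
                if direction > 0:
                    break
                direction = -1
            j += 1
        runs.append([i, j, direction if direction != 0 else 1])
        i = j + 1

    # peak reassignment: move the apex of ascending->descending transitions
    # into the descending run when reversal there restores sorted order
    for k in range(1, len(runs)):
        prev, cur = runs[k - 1], runs[k]
        if cur[2] != -1 or prev[2] != 1 or prev[1] != cur[0] - 1:
            continue
        while prev[1] >= prev[0]:
            x = prev[1]
            nxt_first = runs[k + 1][0] if k + 1 < len(runs) else None
            fits_desc = cm[x] >= cm[cur[0]]  # continues the decreasing run
            fits_next = nxt_first is None or cm[x] <= cm[nxt_first]
            prev_ok = prev[1] - 1 < prev[0] or cm[prev[1] - 1] <= cm[cur[1]]
            if fits_desc and fits_next and prev_ok:
                cur[0] = x
                prev[1] = x - 1
            else:
                break
        if prev[1] < prev[0]:
            runs[k - 1] = None  # emptied
    runs = [r for r in runs if r is not None]

    # lone-outlier split: a single spike (or dip) at the junction of two
    # ascending runs is its own unit, not part of either run
    out: list[list[int]] = []
    for r in runs:
        out.append(r)
        while True:
            if len(out) < 2:
                break
            r1, r2 = out[-2], out[-1]
            if r1[2] != 1 or r2[2] != 1 or cm[r1[1]] <= cm[r2[0]]:
                break
            if r1[1] > r1[0] and cm[r1[1] - 1] <= cm[r2[0]]:
                spike = r1[1]
                r1[1] -= 1
                out.insert(-1, [spike, spike, 1])
                break
            if r2[1] > r2[0] and cm[r1[1]] <= cm[r2[0] + 1]:
                dip = r2[0]
                r2[0] += 1
                out.insert(-1, [dip, dip, 1])
                break
            break
    return [(r[0], r[1], r[2]) for r in out]


def _backbone_runs(runs: list[tuple[int, int, int]], cm: np.ndarray) -> set[int]:
    """Indices of ascending runs on the maximum-weight chain of runs whose cM
    intervals are in non-decreasing order (weight = run length)."""
    asc = [k for k, r in enumerate(runs) if r[2] == 1]
    if not asc:
        return set()
    weight = {k: runs[k][1] - runs[k][0] + 1 for k in asc}
    best: dict[int, float] = {}
    parent: dict[int, Optional[int]] = {}
    for idx, k in enumerate(asc):
        best[k] = weight[k]
        parent[k] = None
        for kp in asc[:idx]:
            if cm[runs[kp][1]] <= cm[runs[k][0]] + 1e-9 and best[kp] + weight[k] > best[k]:
                best[k] = best[kp] + weight[k]
                parent[k] = kp
    end = max(best, key=lambda k: best[k])
    chain = set()
    node: Optional[int] = end
    while node is not None:
        chain.add(node)
        node = parent[node]
    return chain


def detect_corrections(
    linkage_map: LinkageMap,
    placement: PhysicalPlacement,
    min_run: int = 2,
    complex_threshold: int = 5,
    assignment: Optional[GroupAssignment] = None,
    support: Support = Support.POP1_ONLY,
) -> CorrectionLedger:
    """Produce a correction ledger for ``placement`` against one linkage map."""
    group_of = linkage_map.group_of()
    cm_of = linkage_map.cm_of()
    shared = set(group_of) & set(placement.records["marker_id"])
    if not shared:
        raise MapforgeError("placement and linkage map share no markers")
    if assignment is None:
        assignment = assign_groups_to_chromosomes(linkage_map, placement)
    group_chrom = assignment.assignment

    entries: list[CorrectionEntry] = []
    singletons: list[str] = []
    flipped_chromosomes: list[str] = []

    for chrom in placement.chromosomes():
        own_group = assignment.chromosome_to_group().get(chrom)
        table = placement.chromosome_table(chrom)
        table = table[table["marker_id"].isin(shared)].reset_index(drop=True)
        if table.empty:
            continue
        groups = np.array([group_of[m] for m in table["marker_id"]])
        chrom_entries: list[CorrectionEntry] = []

        # (a) foreign-group runs -> MOVE / MOVE_AND_REORIENT
        native_idx: list[int] = []
        i = 0
        while i < len(table):
            if groups[i] == own_group:
                native_idx.append(i)
                i += 1
                continue
            j = i
            while j + 1 < len(table) and groups[j + 1] == groups[i]:
                j += 1
            sub = table.iloc[i : j + 1]
            cms = np.array([cm_of[m] for m in sub["marker_id"]])
            reversed_inside = len(cms) >= 2 and np.all(np.diff(cms) < 0)
            chrom_entries.append(
                CorrectionEntry(
                    chromosome=chrom,
                    first_marker=sub["marker_id"].iloc[0],
                    last_marker=sub["marker_id"].iloc[-1],
                    span=(int(sub["position"].iloc[0]), int(sub["position"].iloc[-1])),
                    action=Action.MOVE_AND_REORIENT if reversed_inside else Action.MOVE,
                    target=group_chrom.get(groups[i]),
                    support=support,
                )
            )
            i = j + 1

        # (b) native markers: monotone-run segmentation
        nat = table.iloc[native_idx].reset_index(drop=True)
        if len(nat) >= 2:
            cm = np.array([cm_of[m] for m in nat["marker_id"]])
            rho = spearmanr(nat["position"], cm).statistic if len(nat) > 2 else np.sign(cm[-1] - cm[0])
            if rho is not None and rho < 0:
                flipped_chromosomes.append(chrom)
                cm = -cm  # analyze in the map's own orientation
            runs = _monotone_runs(cm)
            backbone = _backbone_runs(runs, cm)
            for k, (a, b, direction) in enumerate(runs):
                length = b - a + 1
                sub = nat.iloc[a : b + 1]
                if direction == -1 and cm[a] > cm[b]:
                    if length >= min_run:
                        chrom_entries.append(
                            CorrectionEntry(
                                chromosome=chrom,
                                first_marker=sub["marker_id"].iloc[0],
                                last_marker=sub["marker_id"].iloc[-1],
                                span=(int(sub["position"].iloc[0]), int(sub["position"].iloc[-1])),
                                action=Action.REORIENT,
                                support=support,
                            )
                        )
                    else:
                        singletons.extend(sub["marker_id"])
                elif k not in backbone:
                    if length >= min_run:
                        chrom_entries.append(
                            CorrectionEntry(
                                chromosome=chrom,
                                first_marker=sub["marker_id"].iloc[0],
                                last_marker=sub["marker_id"].iloc[-1],
                                span=(int(sub["position"].iloc[0]), int(sub["position"].iloc[-1])),
                                action=Action.REPOSITION_WITHIN,
                                support=support,
                            )
                        )
                    else:
                        singletons.extend(sub["marker_id"])

        if len(chrom_entries) > complex_threshold:
            lo = min(e.span[0] for e in chrom_entries)
            hi = max(e.span[1] for e in chrom_entries)
            by_lo = min(chrom_entries, key=lambda e: e.span[0])
            by_hi = max(chrom_entries, key=lambda e: e.span[1])
            chrom_entries = [
                CorrectionEntry(
                    chromosome=chrom,
                    first_marker=by_lo.first_marker,
                    last_marker=by_hi.last_marker,
                    span=(lo, hi),
                    action=Action.COMPLEX,
                    support=support,
                )
            ]
        entries.extend(chrom_entries)

    _fill_move_destinations(entries, placement, group_of, cm_of, assignment)
    return CorrectionLedger(
        entries,
        metadata={
            "singletons": singletons,
            "chromosome_orientation_flipped": flipped_chromosomes,
            "unresolved_groups": assignment.unresolved,
            "assignment_conflicts": assignment.conflicts,
            "min_run": min_run,
            "complex_threshold": complex_threshold,
        },
    )


def _fill_move_destinations(
    entries: list[CorrectionEntry],
    placement: PhysicalPlacement,
    group_of: dict[str, str],
    cm_of: dict[str, float],
    assignment: GroupAssignment,
) -> None:
    """Give MOVE entries a destination on the target chromosome interpolated
    from the genetic positions of the target's own markers, so that applying
    the ledger interleaves the moved block where the map says it belongs
    (making apply-then-detect idempotent) instead of appending it at the end."""
    chrom_group = assignment.chromosome_to_group()
    for e in entries:
        if e.action not in (Action.MOVE, Action.MOVE_AND_REORIENT) or e.target is None:
            continue
        tab = placement.chromosome_table(e.target)
        own = chrom_group.get(e.target)
        native = tab[[group_of.get(m) == own for m in tab["marker_id"]]]
        if native.empty:
            continue
        bp = native["position"].to_numpy(float)
        cm = np.array([cm_of[m] for m in native["marker_id"]])
        if len(cm) > 2 and cm[-1] < cm[0]:
            cm = -cm
        src = placement.chromosome_table(e.chromosome)
        block = src[src["position"].between(*e.span)]
        block_cm = np.array([cm_of[m] for m in block["marker_id"] if m in cm_of])
        if block_cm.size == 0:
            continue
        span_len = e.span[1] - e.span[0]
        prev_bp = bp[cm <= block_cm.min()]
        next_bp = bp[cm >= block_cm.max()]
        if prev_bp.size and next_bp.size:
            gap_lo, gap_hi = prev_bp.max(), next_bp.min()
            e.dest_start = int(gap_lo + max(1, (gap_hi - gap_lo - span_len) // 2))
        elif next_bp.size:
            e.dest_start = int(max(1, next_bp.min() - span_len - 1000))
        elif prev_bp.size:
            e.dest_start = int(prev_bp.max() + 1000)


# ------------------------------------------------------------------ merging

def merge_support(l1: CorrectionLedger, l2: CorrectionLedger) -> CorrectionLedger:
    """Combine ledgers from two populations over the same placement. Entries
    with the same action and overlapping spans merge into one BOTH entry over
    the intersection; the rest keep their single-population support."""
    used2: set[int] = set()
    merged: list[CorrectionEntry] = []
    for e1 in l1.entries:
        match = None
        for j, e2 in enumerate(l2.entries):
            if j in used2:
                continue
            if e1.chromosome == e2.chromosome and e1.action == e2.action and e1.overlaps(e2):
                match = (j, e2)
                break
        if match is None:
            merged.append(
                CorrectionEntry(e1.chromosome, e1.first_marker, e1.last_marker,
                                e1.span, e1.action, e1.target, Support.POP1_ONLY, e1.dest_start)
            )
        else:
            j, e2 = match
            used2.add(j)
            lo = max(e1.span[0], e2.span[0])
            hi = min(e1.span[1], e2.span[1])
            first = e1.first_marker if e1.span[0] >= e2.span[0] else e2.first_marker
            last = e1.last_marker if e1.span[1] <= e2.span[1] else e2.last_marker
            merged.append(
                CorrectionEntry(e1.chromosome, first, last, (lo, hi), e1.action,
                                e1.target or e2.target, Support.BOTH, e1.dest_start)
            )
    for j, e2 in enumerate(l2.entries):
        if j not in used2:
            merged.append(
                CorrectionEntry(e2.chromosome, e2.first_marker, e2.last_marker,
                                e2.span, e2.action, e2.target, Support.POP2_ONLY, e2.dest_start)
            )
    return CorrectionLedger(merged, metadata={"merged_from": [l1.metadata, l2.metadata]})


# ----------------------------------------------------------------- applying

def apply_corrections(
    placement: PhysicalPlacement, ledger: CorrectionLedger
) -> tuple[PhysicalPlacement, list[AgpPiece]]:
    """Apply a ledger to a placement, returning the corrected placement and
    the matching AGP layout.

    REORIENT reflects marker positions within the span. MOVE re-homes the
    span's markers on the target chromosome: at ``dest_start`` when the entry
    carries one, else appended past the target's current end, preserving
    internal order (reversed first for MOVE_AND_REORIENT). REPOSITION_WITHIN
    with a known destination moves within the chromosome; COMPLEX entries and
    destination-less repositions are recorded as skipped. Overlapping entries
    are rejected before any mutation.
    """
    es = sorted(ledger.entries, key=lambda e: (e.chromosome, e.span))
    for a, b in zip(es, es[1:]):
        if a.overlaps(b):
            raise MapforgeError(
                f"conflicting ledger entries on {a.chromosome}: {a.span} vs {b.span}"
            )

    df = placement.records.copy()
    pieces: list[AgpPiece] = []
    skipped: list[CorrectionEntry] = []
    # residual (untouched) chromosome segments become identity AGP pieces
    source_span: dict[str, int] = {
        c: int(df.loc[df["chromosome"] == c, "position"].max())
        for c in placement.chromosomes()
    }
    cuts: dict[str, list[tuple[int, int]]] = {c: [] for c in source_span}

    for e in es:
        lo, hi = e.span
        in_span = (df["chromosome"] == e.chromosome) & df["position"].between(lo, hi)
        if e.action == Action.REORIENT:
            df.loc[in_span, "position"] = lo + hi - df.loc[in_span, "position"]
            cuts[e.chromosome].append((lo, hi))
            pieces.append(AgpPiece(e.chromosome, lo, hi, e.chromosome, lo, hi, "-"))
        elif e.action in (Action.MOVE, Action.MOVE_AND_REORIENT):
            if e.target is None:
                skipped.append(e)
                continue
            pos = df.loc[in_span, "position"]
            if e.action == Action.MOVE_AND_REORIENT:
                pos = lo + hi - pos
            if e.dest_start is not None:
                new_pos = e.dest_start + (pos - lo)
            else:
                t_max = df.loc[df["chromosome"] == e.target, "position"]
                base = int(t_max.max()) if len(t_max) else 0
                new_pos = base + 1 + (pos - lo)
            df.loc[in_span, "position"] = new_pos
            df.loc[in_span, "chromosome"] = e.target
            cuts[e.chromosome].append((lo, hi))
            obj_lo = int(new_pos.min()) if len(new_pos) else (e.dest_start or 1)
            obj_hi = obj_lo + (hi - lo)
            if e.target in cuts and obj_lo <= source_span.get(e.target, 0):
                # block inserted inside the target: split the target there too
                cuts[e.target].append((obj_lo, obj_hi))
            pieces.append(
                AgpPiece(
                    e.target, obj_lo, obj_hi, e.chromosome, lo, hi,
                    "-" if e.action == Action.MOVE_AND_REORIENT else "+",
                )
            )
        elif e.action == Action.REPOSITION_WITHIN and e.dest_start is not None:
            df.loc[in_span, "position"] = e.dest_start + (df.loc[in_span, "position"] - lo)
            cuts[e.chromosome].append((lo, hi))
            pieces.append(
                AgpPiece(e.chromosome, e.dest_start, e.dest_start + (hi - lo),
                         e.chromosome, lo, hi, "+")
            )
        else:
            skipped.append(e)

    for chrom, spans in cuts.items():
        prev = 1
        for lo, hi in sorted(spans):
            if lo > prev:
                pieces.append(AgpPiece(chrom, prev, lo - 1, chrom, prev, lo - 1, "+"))
            prev = hi + 1
        if prev <= source_span[chrom]:
            pieces.append(AgpPiece(chrom, prev, source_span[chrom], chrom, prev, source_span[chrom], "+"))

    corrected = PhysicalPlacement(placement.assembly_id + "_corrected", df)
    if skipped:
        corrected.records.attrs["skipped_entries"] = [
            (e.chromosome, e.span, e.action.value) for e in skipped
        ]
    return corrected, pieces
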