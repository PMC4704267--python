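"""Delimit heterochromatic regions from Marey maps.

The cumulative genetic distance of mapped loci is regressed on their
physical position with a continuous piecewise-linear model. The pericentric
heterochromatin appears as a long low-slope middle segment: its two
breakpoints ("inflection points") delimit the heterochromatic interval.
Degenerate two-segment fits are evaluated as well so a heterochromatic
block abutting a chromosome end is recoverable. Model order (1, 2 or 3
segments) is chosen by BIC among candidates whose low segment passes the
slope-ratio criterion; if nothing passes, the chromosome is reported
all-euchromatic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import spearmanr

from .model import (
    ChromatinPartition,
    ChromosomeChromatin,
    LinkageMap,
    MapforgeError,
    MareyMap,
    PhysicalPlacement,
)


# -------------------------------------------------------------- Marey build

def build_marey(
    linkage_map: LinkageMap, placement: PhysicalPlacement, chromosome: str,
    min_markers: int = 10,
) -> MareyMap:
    """Marey map of one chromosome from the markers shared between a linkage
    map and a placement. A map stored in reverse orientation is auto-flipped
    (negative rank correlation with bp); residual non-monotone points are
    dropped (largest monotone subset kept) and counted."""
    cm_of = linkage_map.cm_of()
    table = placement.chromosome_table(chromosome)
    table = table[table["marker_id"].isin(cm_of)]
    if len(table) < min_markers:
        raise MapforgeError(
            f"insufficient density: {len(table)} shared markers on {chromosome}"
        )
    bp = table["position"].to_numpy(dtype=float)
    cm = np.array([cm_of[m] for m in table["marker_id"]], dtype=float)
    rho = spearmanr(bp, cm).statistic
    if rho is not None and rho < 0:
        cm = cm.max() - cm
    keep = _longest_nondecreasing(cm)
    n_dropped = len(cm) - len(keep)
    bp, cm = bp[keep], cm[keep]
    uniq = np.concatenate([[True], np.diff(bp) > 0])
    return MareyMap(chromosome, np.column_stack([bp[uniq], cm[uniq]]), n_dropped)


def _longest_nondecreasing(x: np.ndarray) -> np.ndarray:
    """Indices of a longest non-decreasing subsequence (patience sorting)."""
    import bisect

    n = len(x)
    tails: list[float] = []
    tail_idx: list[int] = []
    parent = np.full(n, -1)
    for i, v in enumerate(x):
        j = bisect.bisect_right(tails, v)
        if j == len(tails):
            tails.append(v)
            tail_idx.append(i)
        else:
            tails[j] = v
            tail_idx[j] = i
        parent[i] = tail_idx[j - 1] if j > 0 else -1
    out = []
    i = tail_idx[-1]
    while i >= 0:
        out.append(i)
        i = parent[i]
    return np.array(out[::-1])


# ------------------------------------------------------------ breakpoint fit

def _fit(bp: np.ndarray, cm: np.ndarray, breaks: tuple[float, ...]) -> tuple[float, np.ndarray]:
    cols = [np.ones_like(bp), bp] + [np.maximum(bp - b, 0.0) for b in breaks]
    coef, *_ = np.linalg.lstsq(np.column_stack(cols), cm, rcond=None)
    resid = cm - np.column_stack(cols) @ coef
    return float(resid @ resid), coef


def _slopes(coef: np.ndarray) -> list[float]:
    return list(np.cumsum(coef[1:]))


def _bic(sse: float, n: int, k: int) -> float:
    return n * np.log(max(sse, 1e-12) / n) + k * np.log(n)


def _candidate_grid(bp: np.ndarray, max_coarse: int = 40) -> np.ndarray:
    if len(bp) <= max_coarse:
        return bp
    idx = np.unique(np.linspace(0, len(bp) - 1, max_coarse).astype(int))
    return bp[idx]


def _best_pair(bp, cm, grid, min_segment, lo_bound, hi_bound):
    best = (np.inf, None, None)
    for i, b1 in enumerate(grid):
        if b1 - lo_bound < min_segment:
            continue
        for b2 in grid[i + 1 :]:
            if b2 - b1 < min_segment or hi_bound - b2 < min_segment:
                continue
            sse, coef = _fit(bp, cm, (b1, b2))
            if sse < best[0]:
                best = (sse, (b1, b2), coef)
    return best


def _low_block(slopes: list[float], bounds: tuple[int, ...], ratio: float):
    """Heterochromatic interval of a fitted piecewise model: the contiguous
    block of low-slope segments (slope <= ratio x the steepest segment).
    Adjacent low segments merge, so a low region reaching a chromosome end is
    reported in full. None when no segment is low (uniform recombination)."""
    smax = max(slopes)
    if smax <= 0:
        return None
    low = [s <= ratio * smax for s in slopes]
    blocks = []
    i = 0
    while i < len(low):
        if low[i]:
            j = i
            while j + 1 < len(low) and low[j + 1]:
                j += 1
            blocks.append((i, j))
            i = j + 1
        else:
            i += 1
    if not blocks:
        return None
    # one het interval per chromosome: take the physically longest low block
    i, j = max(blocks, key=lambda b: bounds[b[1] + 1] - bounds[b[0]])
    return (bounds[i], bounds[j + 1])


def delimit_heterochromatin(
    marey: MareyMap,
    slope_ratio_max: float = 0.25,
    min_segment: float = 2_000_000.0,
    chromosome_length: Optional[int] = None,
) -> ChromosomeChromatin:
    """Estimate the heterochromatic interval of one chromosome.

    The breakpoint pair is searched coarse-to-fine over marker positions
    (coarse grid of <= 40 positions, then every marker position within one
    coarse step of the optimum); all segments must span ``min_segment`` and
    the low segment's slope must be at most ``slope_ratio_max`` times the
    mean flanking slope. Reported bounds are rounded to 0.1 Mb.
    """
    bp = marey.points[:, 0]
    cm = marey.points[:, 1]
    length = int(chromosome_length if chromosome_length is not None else bp[-1])
    n = len(bp)
    lo_bound, hi_bound = 1.0, float(length)

    sse1, _ = _fit(bp, cm, ())
    candidates: list[tuple[float, Optional[tuple[int, int]]]] = [(_bic(sse1, n, 2), None)]

    grid = _candidate_grid(bp)
    step = (grid[-1] - grid[0]) / max(len(grid) - 1, 1)

    # 3-segment: coarse search then local refinement on the full marker grid
    sse, brks, coef = _best_pair(bp, cm, grid, min_segment, lo_bound, hi_bound)
    if brks is not None:
        fine1 = bp[np.abs(bp - brks[0]) <= step]
        fine2 = bp[np.abs(bp - brks[1]) <= step]
        fine = np.unique(np.concatenate([fine1, fine2]))
        sse_f, brks_f, coef_f = _best_pair(bp, cm, fine, min_segment, lo_bound, hi_bound)
        if brks_f is not None and sse_f <= sse:
            sse, brks, coef = sse_f, brks_f, coef_f
        het3 = _low_block(_slopes(coef), (1, int(brks[0]), int(brks[1]), length),
                          slope_ratio_max)
        if het3 is not None:
            candidates.append((_bic(sse, n, 6), het3))

    # 2-segment: heterochromatin abutting either chromosome end
    best2 = (np.inf, None, None)
    for b in np.unique(np.concatenate([grid, bp[np.abs(bp[None, :] - grid[:, None]).min(0) <= step]])):
        if b - lo_bound < min_segment or hi_bound - b < min_segment:
            continue
        sse_b, coef_b = _fit(bp, cm, (b,))
        if sse_b < best2[0]:
            best2 = (sse_b, b, coef_b)
    if best2[1] is not None:
        het2 = _low_block(_slopes(best2[2]), (1, int(best2[1]), length), slope_ratio_max)
        if het2 is not None:
            candidates.append((_bic(best2[0], n, 4), het2))

    candidates.sort(key=lambda c: c[0])
    het = candidates[0][1]
    if het is not None:
        lo = max(1, int(round(het[0] / 1e5) * 1e5))
        hi = min(length, int(round(het[1] / 1e5) * 1e5))
        het = (lo, hi)
    return ChromosomeChromatin(marey.chromosome, length, het)


def partition_genome(
    linkage_map: LinkageMap,
    placement: PhysicalPlacement,
    chromosome_lengths: dict[str, int],
    slope_ratio_max: float = 0.25,
    min_segment: float = 2_000_000.0,
) -> ChromatinPartition:
    entries = []
    for chrom in sorted(chromosome_lengths):
        marey = build_marey(linkage_map, placement, chrom)
        entries.append(
            delimit_heterochromatin(
                marey, slope_ratio_max, min_segment, chromosome_lengths[chrom]
            )
        )
    return ChromatinPartition(entries)


# ------------------------------------------------------------------- totals

@dataclass
class PartitionTotals:
    total_bp: int
    het_bp: int
    euch_bp: int
    het_mb: float
    euch_mb: float
    het_pct: int
    euch_pct: int


def summarize_against_total(
    partition: ChromatinPartition, total_bp: int
) -> PartitionTotals:
    """Totals when only the genome-wide chromosome total is declared (the
    usual case when working from a published per-chromosome table):
    euchromatin is the complement of the summed het intervals within it."""
    het_bp = sum(e.het_length() for e in partition.entries)
    if het_bp > total_bp:
        raise MapforgeError("het total exceeds the declared genome total")
    euch_bp = total_bp - het_bp
    return PartitionTotals(
        total_bp=total_bp,
        het_bp=het_bp,
        euch_bp=euch_bp,
        het_mb=round(het_bp / 1e6, 1),
        euch_mb=round(euch_bp / 1e6, 1),
        het_pct=round(100.0 * het_bp / total_bp),
        euch_pct=round(100.0 * euch_bp / total_bp),
    )


def summarize_partition(
    partition: ChromatinPartition, chromosome_lengths: dict[str, int]
) -> PartitionTotals:
    """Genome-wide totals: heterochromatin is the sum of the per-chromosome
    intervals, euchromatin the complement within the declared chromosome
    lengths; fractions are rounded to whole percent, Mb totals to 0.1."""
    het_bp = 0
    for e in partition.entries:
        if e.chromosome not in chromosome_lengths:
            raise MapforgeError(f"no declared length for {e.chromosome}")
        if e.het is not None and e.het[1] > chromosome_lengths[e.chromosome]:
            raise MapforgeError(
                f"het interval {e.het} exceeds declared length of {e.chromosome}"
            )
        het_bp += e.het_length()
    total_bp = int(sum(chromosome_lengths.values()))
    euch_bp = total_bp - het_bp
    return PartitionTotals(
        total_bp=total_bp,
        het_bp=het_bp,
        euch_bp=euch_bp,
        het_mb=round(het_bp / 1e6, 1),
        euch_mb=round(euch_bp / 1e6, 1),
        het_pct=round(100.0 * het_bp / total_bp),
        euch_pct=round(100.0 * euch_bp / total_bp),
    )
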