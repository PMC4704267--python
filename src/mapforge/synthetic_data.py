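"""Synthetic F5-derived RIL populations and assemblies with planted errors.

The generator emulates the structure of two large biparental selfing-series
mapping populations genotyped at thousands of biallelic markers: each line
descends from an F1 by ``k`` rounds of selfing, with crossovers sampled as a
Poisson process on the true genetic scale (no interference, i.e. a Haldane
world, chosen because closed-form RIL expectations then exist and give sharp
test oracles). Residual heterozygosity is simulated faithfully — an F5-derived
line retains (1/2)^4 ≈ 6 % H per locus — and its handling is left to QC.

A model genome carries a monotone piecewise-linear true Marey map per
chromosome with a low-recombination middle block (heterochromatin mimic), and
``corrupt_assembly`` plants inversions, inter-chromosome translocations and
detached scaffolds with a truth ledger whose application provably restores
the true placement.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    A,
    B,
    H,
    MISSING,
    Action,
    ChromatinPartition,
    ChromosomeChromatin,
    CorrectionEntry,
    CorrectionLedger,
    GenotypeMatrix,
    MapforgeError,
    PhysicalPlacement,
    Scaffold,
    ScaffoldSet,
)


# ------------------------------------------------------------- genome model

@dataclass
class ChromosomeModel:
    name: str
    physical_length: int  # bp
    marey_knots: list[tuple[int, float]]  # (bp, cM), monotone, first (1, 0)
    marker_positions: np.ndarray  # sorted bp

    def __post_init__(self) -> None:
        bps = [k[0] for k in self.marey_knots]
        cms = [k[1] for k in self.marey_knots]
        if self.marey_knots[0] != (1, 0.0):
            raise MapforgeError(f"{self.name}: first Marey knot must be (1, 0)")
        if any(b2 < b1 for b1, b2 in zip(bps, bps[1:])) or any(
            c2 < c1 for c1, c2 in zip(cms, cms[1:])
        ):
            raise MapforgeError(f"{self.name}: Marey knots must be monotone")
        self.marker_positions = np.asarray(self.marker_positions, dtype=np.int64)

    @property
    def genetic_length(self) -> float:
        return self.marey_knots[-1][1]

    def cm_at(self, bp: np.ndarray) -> np.ndarray:
        """True genetic position of physical coordinates (linear interpolation
        between Marey knots)."""
        xs = np.array([k[0] for k in self.marey_knots], dtype=float)
        ys = np.array([k[1] for k in self.marey_knots], dtype=float)
        return np.interp(np.asarray(bp, dtype=float), xs, ys)

    def marker_ids(self) -> list[str]:
        return [f"M{self.name}_{int(bp)}" for bp in self.marker_positions]


@dataclass
class GenomeModel:
    chromosomes: list[ChromosomeModel]

    def n_markers(self) -> int:
        return sum(len(c.marker_positions) for c in self.chromosomes)


def _het_block_knots(
    length: int, genetic_length: float, het_lo: int, het_hi: int, slope_ratio: float
) -> list[tuple[int, float]]:
    """Knots of a 3-segment Marey map with a low-recombination middle block
    whose slope is ``slope_ratio`` times the flanking slope."""
    het_span = het_hi - het_lo
    euch_span = length - 1 - het_span
    s_e = genetic_length / (euch_span + slope_ratio * het_span)
    c1 = s_e * (het_lo - 1)
    c2 = c1 + s_e * slope_ratio * het_span
    return [(1, 0.0), (het_lo, c1), (het_hi, c2), (length, genetic_length)]


def default_genome(
    n_chromosomes: int = 5,
    markers_per_chromosome: int = 500,
    slope_ratio: float = 0.1,
) -> GenomeModel:
    """Deterministic desk-scale genome: chromosome lengths spanning 40–60 Mb,
    genetic lengths 100–130 cM, one low-recombination middle block each (slope
    ratio 1:10), evenly spaced markers."""
    chroms = []
    for i in range(n_chromosomes):
        frac = i / max(1, n_chromosomes - 1)
        length = int(40e6 + 20e6 * frac)
        g_len = 100.0 + 30.0 * frac
        het_lo = int(length * (0.30 + 0.04 * i))
        het_hi = int(length * (0.62 + 0.03 * i))
        knots = _het_block_knots(length, g_len, het_lo, het_hi, slope_ratio)
        positions = np.linspace(5000, length - 5000, markers_per_chromosome).astype(np.int64)
        chroms.append(ChromosomeModel(f"Chr{i + 1:02d}", length, knots, positions))
    return GenomeModel(chroms)


def random_genome(
    seed: int,
    n_chromosomes: int = 5,
    markers_per_chromosome: int = 500,
    slope_ratio: float = 0.1,
) -> GenomeModel:
    """Randomized variant of :func:`default_genome` (lengths, block placement
    and marker positions drawn from a seeded RNG)."""
    rng = np.random.default_rng(seed)
    chroms = []
    for i in range(n_chromosomes):
        length = int(rng.uniform(40e6, 60e6))
        g_len = float(rng.uniform(100.0, 130.0))
        lo_f = rng.uniform(0.15, 0.45)
        hi_f = lo_f + rng.uniform(0.2, 0.4)
        het_lo, het_hi = int(length * lo_f), int(min(0.9, hi_f) * length)
        knots = _het_block_knots(length, g_len, het_lo, het_hi, slope_ratio)
        positions = np.sort(
            rng.choice(
                np.arange(5000, length - 5000, 1000), markers_per_chromosome, replace=False
            )
        ).astype(np.int64)
        chroms.append(ChromosomeModel(f"Chr{i + 1:02d}", length, knots, positions))
    return GenomeModel(chroms)


def genome_placement(genome: GenomeModel, assembly_id: str = "true") -> PhysicalPlacement:
    """True physical placement of every model marker."""
    rows = []
    for c in genome.chromosomes:
        for bp, mid in zip(c.marker_positions, c.marker_ids()):
            rows.append((mid, c.name, int(bp)))
    return PhysicalPlacement(assembly_id, pd.DataFrame(rows, columns=["marker_id", "chromosome", "position"]))


def truth_linkage_map(genome: GenomeModel, population_id: str = "truth"):
    """Noise-free linkage map read directly off the genome's Marey knots."""
    from .model import LinkageGroup, LinkageMap

    groups = []
    for c in genome.chromosomes:
        cms = c.cm_at(c.marker_positions)
        loci = [(mid, float(cm)) for mid, cm in zip(c.marker_ids(), cms)]
        groups.append(LinkageGroup(f"LG_{c.name}", loci))
    return LinkageMap(population_id, groups)


def true_partition(genome: GenomeModel) -> ChromatinPartition:
    """Heterochromatin truth: the low-slope middle block of each chromosome's
    Marey map (interior knots), or all-euchromatic if there is none."""
    entries = []
    for c in genome.chromosomes:
        interior = c.marey_knots[1:-1]
        het = (interior[0][0], interior[1][0]) if len(interior) == 2 else None
        entries.append(ChromosomeChromatin(c.name, c.physical_length, het))
    return ChromatinPartition(entries)


# ------------------------------------------------------- population sampler

def _gamete(h1: np.ndarray, h2: np.ndarray, d_morgan: np.ndarray, rng) -> np.ndarray:
    """One meiotic product per line. Phase parity at each marker follows the
    independent Poisson counts of crossovers in the inter-marker intervals."""
    n, m = h1.shape
    start = rng.integers(0, 2, size=(n, 1))
    if m > 1:
        xo = rng.poisson(d_morgan, size=(n, m - 1))
        parity = (start + np.concatenate([np.zeros((n, 1), int), np.cumsum(xo, axis=1)], axis=1)) % 2
    else:
        parity = start % 2
    return np.where(parity == 0, h1, h2)


def _simulate_lines(genome: GenomeModel, n: int, k: int, rng) -> np.ndarray:
    """Raw genotype codes (markers x lines) for ``n`` F_(1+k)-derived lines."""
    blocks = []
    for c in genome.chromosomes:
        cms = c.cm_at(c.marker_positions)
        d = np.diff(cms) / 100.0  # Morgans between adjacent markers
        m = len(cms)
        h1 = np.zeros((n, m), dtype=np.int8)  # F1: one homolog from each parent
        h2 = np.ones((n, m), dtype=np.int8)
        for _ in range(k):
            g1 = _gamete(h1, h2, d, rng)
            g2 = _gamete(h1, h2, d, rng)
            h1, h2 = g1, g2
        geno = np.full((n, m), H, dtype=np.int8)
        geno[(h1 == 0) & (h2 == 0)] = A
        geno[(h1 == 1) & (h2 == 1)] = B
        blocks.append(geno.T)
    return np.concatenate(blocks, axis=0)


def simulate_population(
    genome: GenomeModel,
    n_lines: int,
    selfing_generations: int = 4,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    distortion: Optional[dict[str, float]] = None,
    seed: int = 0,
    population_id: str = "SIM",
) -> GenotypeMatrix:
    """Simulate an F_(1+k)-derived RIL population over ``genome``.

    ``selfing_generations`` = 4 yields F5-derived lines. Calls are then
    perturbed: with probability ``error_rate`` a call is resampled to another
    symbol, with probability ``missing_rate`` it is set missing. ``distortion``
    maps marker_id -> viability weight w of the B homozygote (sqrt(w) for H);
    lines are rejection-sampled against the product of their weights.
    """
    if n_lines < 1:
        raise MapforgeError("n_lines must be >= 1")
    if selfing_generations < 1:
        raise MapforgeError("selfing_generations must be >= 1")
    for name, rate in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not 0.0 <= rate <= 1.0:
            raise MapforgeError(f"{name} must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    marker_ids = [mid for c in genome.chromosomes for mid in c.marker_ids()]

    if distortion:
        midx = {m: i for i, m in enumerate(marker_ids)}
        for m in distortion:
            if m not in midx:
                raise MapforgeError(f"distortion weight for unknown marker {m!r}")
        kept: list[np.ndarray] = []
        n_kept = 0
        while n_kept < n_lines:
            batch = _simulate_lines(genome, n_lines, selfing_generations, rng)
            w = np.ones(batch.shape[1])
            for m, wt in distortion.items():
                col = batch[midx[m]]
                w *= np.where(col == B, wt, np.where(col == H, np.sqrt(wt), 1.0))
            accept = rng.random(batch.shape[1]) < w / max(w.max(), 1e-12)
            kept.append(batch[:, accept])
            n_kept += int(accept.sum())
        calls = np.concatenate(kept, axis=1)[:, :n_lines]
    else:
        calls = _simulate_lines(genome, n_lines, selfing_generations, rng)

    if error_rate > 0:
        err = rng.random(calls.shape) < error_rate
        # resample to one of the other two genotype symbols
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < missing_rate, MISSING, calls).astype(np.int8)

    line_ids = [f"{population_id}_L{i:05d}" for i in range(n_lines)]
    return GenotypeMatrix(population_id, line_ids, marker_ids, calls)


# ----------------------------------------------------------- assembly noise

@dataclass
class TruthSet:
    """Ground truth emitted alongside a corrupted assembly."""

    true_assembly: PhysicalPlacement
    corrupted_assembly: PhysicalPlacement
    planted_errors: CorrectionLedger
    detached_scaffolds: ScaffoldSet
    # (scaffold_id, chromosome, start bp on chromosome, orientation)
    detached_truth: list[tuple[str, str, int, str]] = field(default_factory=list)
    true_partition: Optional[ChromatinPartition] = None


_MOVE_GAP = 10_000  # bp inserted before a block appended to a chromosome end


def _pick_interval(used: np.ndarray, n_markers: int, size: int, rng, pad: int = 2):
    """Random start index of an unused run of ``size`` markers, keeping ``pad``
    markers clear of chromosome ends and previously chosen intervals."""
    candidates = []
    for i in range(pad, n_markers - size - pad):
        if not used[i - pad : i + size + pad].any():
            candidates.append(i)
    if not candidates:
        return None
    start = int(rng.choice(candidates))
    used[start : start + size] = True
    return start


def corrupt_assembly(
    true_assembly: PhysicalPlacement,
    n_inversions: int = 8,
    n_translocations: int = 4,
    n_detached_scaffolds: int = 10,
    seed: int = 0,
    min_markers: int = 5,
    max_markers: int = 12,
    partition: Optional[ChromatinPartition] = None,
) -> TruthSet:
    """Plant assembly errors into ``true_assembly`` and emit the truth ledger.

    Inversions reverse physical order within a marker interval (positions
    reflected in place). Translocations move an interval to the end of a
    different chromosome, half of them also inverted. Detachments remove an
    interval into a named scaffold. Intervals are disjoint and padded so every
    planted error is recoverable with exact marker boundaries; applying the
    ledger (plus re-attaching scaffolds) restores the truth, which the
    generator verifies before returning.
    """
    rng = np.random.default_rng(seed)
    chrom_tables = {c: true_assembly.chromosome_table(c) for c in true_assembly.chromosomes()}
    chroms = list(chrom_tables)
    if len(chroms) < 2 and n_translocations > 0:
        raise MapforgeError("translocations need at least two chromosomes")
    used = {c: np.zeros(len(t), dtype=bool) for c, t in chrom_tables.items()}

    jobs = (
        ["inv"] * n_inversions + ["trans"] * n_translocations + ["detach"] * n_detached_scaffolds
    )
    picks = []  # (kind, chromosome, start_idx, size)
    ci = 0
    for kind in jobs:
        size = int(rng.integers(min_markers, max_markers + 1))
        placed = False
        for _ in range(len(chroms)):
            c = chroms[ci % len(chroms)]
            ci += 1
            start = _pick_interval(used[c], len(chrom_tables[c]), size, rng)
            if start is not None:
                picks.append((kind, c, start, size))
                placed = True
                break
        if not placed:
            raise MapforgeError("infeasible error counts for this marker density")

    df = true_assembly.records.copy().set_index("marker_id")
    entries: list[CorrectionEntry] = []
    scaffolds: list[Scaffold] = []
    detached_truth: list[tuple[str, str, int, str]] = []

    # inversions first (in place), then removals, then appends
    for kind, c, start, size in picks:
        if kind != "inv":
            continue
        t = chrom_tables[c].iloc[start : start + size]
        lo, hi = int(t["position"].min()), int(t["position"].max())
        for mid, pos in zip(t["marker_id"], t["position"]):
            df.loc[mid, "position"] = lo + hi - int(pos)
        order = t.sort_values("position")  # corrupted bp order = reversed truth
        entries.append(
            CorrectionEntry(
                chromosome=c,
                first_marker=order["marker_id"].iloc[-1],
                last_marker=order["marker_id"].iloc[0],
                span=(lo, hi),
                action=Action.REORIENT,
            )
        )

    n_scaffold = 0
    for kind, c, start, size in picks:
        if kind == "inv":
            continue
        t = chrom_tables[c].iloc[start : start + size]
        lo, hi = int(t["position"].min()), int(t["position"].max())
        inverted = bool(rng.integers(0, 2))
        if kind == "detach":
            n_scaffold += 1
            sid = f"scaffold_{n_scaffold:03d}"
            length = hi - lo + 1
            markers = []
            for mid, pos in zip(t["marker_id"], t["position"]):
                off = (hi - int(pos) + 1) if inverted else (int(pos) - lo + 1)
                markers.append((mid, off))
            scaffolds.append(Scaffold(sid, length, sorted(markers, key=lambda x: x[1])))
            detached_truth.append((sid, c, lo, "-" if inverted else "+"))
            df = df.drop(index=t["marker_id"])
        else:  # translocation
            target = chroms[(chroms.index(c) + 1) % len(chroms)]
            t_max = int(df.loc[df["chromosome"] == target, "position"].max())
            new_lo = t_max + _MOVE_GAP
            for mid, pos in zip(t["marker_id"], t["position"]):
                off = (hi - int(pos)) if inverted else (int(pos) - lo)
                df.loc[mid, "chromosome"] = target
                df.loc[mid, "position"] = new_lo + off
            new_hi = new_lo + (hi - lo)
            sub = df.loc[list(t["marker_id"])].sort_values("position")
            entries.append(
                CorrectionEntry(
                    chromosome=target,
                    first_marker=sub.index[0],
                    last_marker=sub.index[-1],
                    span=(new_lo, new_hi),
                    action=Action.MOVE_AND_REORIENT if inverted else Action.MOVE,
                    target=c,
                    dest_start=lo,
                )
            )

    corrupted = PhysicalPlacement(
        f"{true_assembly.assembly_id}_corrupted",
        df.reset_index()[["marker_id", "chromosome", "position"]],
    )
    truth = TruthSet(
        true_assembly=true_assembly,
        corrupted_assembly=corrupted,
        planted_errors=CorrectionLedger(entries),
        detached_scaffolds=ScaffoldSet(scaffolds),
        detached_truth=detached_truth,
        true_partition=partition,
    )
    _verify_roundtrip(truth)
    return truth


def reattach_scaffolds(
    placement: PhysicalPlacement,
    scaffolds: ScaffoldSet,
    detached_truth: list[tuple[str, str, int, str]],
) -> PhysicalPlacement:
    """Re-insert detached scaffolds at their true chromosome coordinates."""
    by_id = {s.scaffold_id: s for s in scaffolds.entries}
    rows = list(placement.records.itertuples(index=False, name=None))
    for sid, chrom, start, orient in detached_truth:
        s = by_id[sid]
        for mid, off in s.markers:
            pos = start + (s.length - off) if orient == "-" else start + off - 1
            rows.append((mid, chrom, pos))
    return PhysicalPlacement(
        placement.assembly_id + "_restored",
        pd.DataFrame(rows, columns=["marker_id", "chromosome", "position"]),
    )


def _verify_roundtrip(truth: TruthSet) -> None:
    from .assembly_concordance import apply_corrections

    restored, _ = apply_corrections(truth.corrupted_assembly, truth.planted_errors)
    restored = reattach_scaffolds(restored, truth.detached_scaffolds, truth.detached_truth)
    a = truth.true_assembly.records.sort_values("marker_id").reset_index(drop=True)
    b = restored.records.sort_values("marker_id").reset_index(drop=True)
    if not a[["marker_id", "chromosome", "position"]].equals(
        b[["marker_id", "chromosome", "position"]]
    ):
        raise MapforgeError("internal error: planted ledger does not restore the truth")


# RIL-by-selfing closed forms (Haldane world) used as test oracles ----------

def haldane(r: float) -> float:
    """Map distance (cM) under no interference."""
    return -50.0 * np.log(1.0 - 2.0 * r)


def haldane_inverse(d_cm: float) -> float:
    """Recombination fraction at a map distance of ``d_cm`` (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def ril_recombinant_fraction(r: float) -> float:
    """Expected recombinant-line fraction between two loci in selfed RILs at
    fixation (Haldane & Waddington): R = 2r / (1 + 2r)."""
    return 2.0 * r / (1.0 + 2.0 * r)
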