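"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based inclusive base pairs throughout; conversion to
0-based half-open happens only when writing BED. Genotype calls use a fixed
four-symbol dialect: ``A`` (reference-parent homozygote), ``B`` (alternate
parent), ``H`` (heterozygote) and ``-`` (missing).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

# integer codes for genotype calls
A, B, H, MISSING = 0, 1, 2, 3
CALL_SYMBOLS = np.array(["A", "B", "H", "-"])
SYMBOL_TO_CODE = {"A": A, "B": B, "H": H, "-": MISSING, "NA": MISSING, ".": MISSING}


class MapforgeError(ValueError):
    """Raised on any validation failure; the message names the offender."""


@dataclass
class GenotypeMatrix:
    """Markers x lines call table — the raw input of linkage mapping.

    ``calls`` is an int8 array of shape (n_markers, n_lines) over the codes
    {A, B, H, MISSING}.
    """

    population_id: str
    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise MapforgeError("calls must be a 2-D matrix")
        m, n = self.calls.shape
        if m != len(self.marker_ids) or n != len(self.line_ids):
            raise MapforgeError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.line_ids)} lines"
            )
        if len(set(self.marker_ids)) != m:
            dup = _first_duplicate(self.marker_ids)
            raise MapforgeError(f"duplicate marker_id {dup!r}")
        if len(set(self.line_ids)) != n:
            dup = _first_duplicate(self.line_ids)
            raise MapforgeError(f"duplicate line_id {dup!r}")
        if self.calls.size and (self.calls.min() < 0 or self.calls.max() > 3):
            bad = np.argwhere((self.calls < 0) | (self.calls > 3))[0]
            raise MapforgeError(
                f"illegal call code at marker {self.marker_ids[bad[0]]!r}, "
                f"line {self.line_ids[bad[1]]!r}"
            )

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def marker_missing_fraction(self) -> np.ndarray:
        if self.n_lines == 0:
            return np.zeros(self.n_markers)
        return (self.calls == MISSING).mean(axis=1)

    def line_missing_fraction(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.zeros(self.n_lines)
        return (self.calls == MISSING).mean(axis=0)

    def subset(
        self,
        marker_mask: Optional[np.ndarray] = None,
        line_mask: Optional[np.ndarray] = None,
    ) -> "GenotypeMatrix":
        calls = self.calls
        marker_ids = self.marker_ids
        line_ids = self.line_ids
        if marker_mask is not None:
            marker_mask = np.asarray(marker_mask, dtype=bool)
            calls = calls[marker_mask]
            marker_ids = [m for m, k in zip(marker_ids, marker_mask) if k]
        if line_mask is not None:
            line_mask = np.asarray(line_mask, dtype=bool)
            calls = calls[:, line_mask]
            line_ids = [l for l, k in zip(line_ids, line_mask) if k]
        return GenotypeMatrix(self.population_id, list(line_ids), list(marker_ids), calls.copy())

    def marker_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.marker_ids)}

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.population_id == other.population_id
            and self.line_ids == other.line_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PhysicalPlacement:
    """Marker -> (chromosome, bp) table in a named assembly version."""

    assembly_id: str
    records: pd.DataFrame  # columns: marker_id, chromosome, position

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=["marker_id", "chromosome", "position"])
        df["position"] = df["position"].astype(np.int64)
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise MapforgeError(f"duplicate marker_id {dup!r} in placement")
        if len(df) and (df["position"] < 1).any():
            bad = df.loc[df["position"] < 1].iloc[0]
            raise MapforgeError(
                f"position {bad['position']} < 1 for marker {bad['marker_id']!r}"
            )
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def chromosomes(self) -> list[str]:
        return sorted(self.records["chromosome"].unique())

    def chromosome_table(self, chromosome: str) -> pd.DataFrame:
        """Markers on one chromosome, sorted by position."""
        sub = self.records[self.records["chromosome"] == chromosome]
        return sub.sort_values(["position", "marker_id"]).reset_index(drop=True)

    def position_of(self, marker_id: str) -> tuple[str, int]:
        row = self.records[self.records["marker_id"] == marker_id]
        if row.empty:
            raise MapforgeError(f"marker {marker_id!r} not in placement")
        r = row.iloc[0]
        return r["chromosome"], int(r["position"])

    def equals(self, other: "PhysicalPlacement") -> bool:
        a = self.records.sort_values("marker_id").reset_index(drop=True)
        b = other.records.sort_values("marker_id").reset_index(drop=True)
        return self.assembly_id == other.assembly_id and a.equals(b)


@dataclass
class Scaffold:
    scaffold_id: str
    length: int
    markers: list[tuple[str, int]]  # (marker_id, 1-based offset in scaffold)

    def __post_init__(self) -> None:
        for mid, off in self.markers:
            if not (1 <= off <= self.length):
                raise MapforgeError(
                    f"offset {off} of marker {mid!r} outside scaffold "
                    f"{self.scaffold_id!r} (length {self.length})"
                )


@dataclass
class ScaffoldSet:
    entries: list[Scaffold]

    def __post_init__(self) -> None:
        ids = [s.scaffold_id for s in self.entries]
        if len(set(ids)) != len(ids):
            raise MapforgeError(f"duplicate scaffold_id {_first_duplicate(ids)!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def total_length(self) -> int:
        return sum(s.length for s in self.entries)


@dataclass
class LinkageGroup:
    group_id: str
    loci: list[tuple[str, float]]  # (marker_id, cM), cM non-decreasing

    def __post_init__(self) -> None:
        cms = [c for _, c in self.loci]
        if any(b < a - 1e-9 for a, b in zip(cms, cms[1:])):
            raise MapforgeError(f"cM not non-decreasing in group {self.group_id!r}")

    @property
    def length_cm(self) -> float:
        if not self.loci:
            return 0.0
        return self.loci[-1][1] - self.loci[0][1]

    def marker_ids(self) -> list[str]:
        return [m for m, _ in self.loci]


@dataclass
class LinkageMap:
    population_id: str
    groups: list[LinkageGroup]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            for m, _ in g.loci:
                if m in seen:
                    raise MapforgeError(f"marker {m!r} occurs in more than one group")
                seen.add(m)

    @property
    def total_length_cm(self) -> float:
        return sum(g.length_cm for g in self.groups)

    def group_of(self) -> dict[str, str]:
        """marker_id -> group_id lookup."""
        return {m: g.group_id for g in self.groups for m in g.marker_ids()}

    def cm_of(self) -> dict[str, float]:
        return {m: c for g in self.groups for m, c in g.loci}


class Action(enum.Enum):
    REORIENT = "REORIENT"
    MOVE = "MOVE"
    MOVE_AND_REORIENT = "MOVE_AND_REORIENT"
    REPOSITION_WITHIN = "REPOSITION_WITHIN"
    COMPLEX = "COMPLEX"


class Support(enum.Enum):
    BOTH = "BOTH"
    POP1_ONLY = "POP1_ONLY"
    POP2_ONLY = "POP2_ONLY"


@dataclass
class CorrectionEntry:
    """One curation record: an interval of an assembly chromosome and the
    action required to reconcile it with the genetic map."""

    chromosome: str
    first_marker: str
    last_marker: str
    span: tuple[int, int]  # bp interval on `chromosome`, 1-based inclusive
    action: Action
    target: Optional[str] = None  # destination chromosome for MOVE-type actions
    support: Support = Support.POP1_ONLY
    dest_start: Optional[int] = None  # destination bp when known (generator truth)

    def __post_init__(self) -> None:
        lo, hi = self.span
        if hi < lo:
            self.span = (hi, lo)
        if (
            self.action in (Action.MOVE, Action.MOVE_AND_REORIENT)
            and self.target is not None
            and self.target == self.chromosome
        ):
            raise MapforgeError(
                f"MOVE target equals source chromosome {self.chromosome!r}"
            )

    def overlaps(self, other: "CorrectionEntry") -> bool:
        if self.chromosome != other.chromosome:
            return False
        return self.span[0] <= other.span[1] and other.span[0] <= self.span[1]


@dataclass
class CorrectionLedger:
    entries: list[CorrectionEntry]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # entries must not overlap within one chromosome and support class
        # (BOTH vs single-population ledgers may legitimately disagree)
        per_chrom: dict[tuple[str, str], list[CorrectionEntry]] = {}
        for e in self.entries:
            per_chrom.setdefault((e.chromosome, e.support.value), []).append(e)
        for (chrom, _), es in per_chrom.items():
            es = sorted(es, key=lambda e: e.span)
            for a, b in zip(es, es[1:]):
                if a.overlaps(b):
                    raise MapforgeError(
                        f"overlapping ledger entries on {chrom}: "
                        f"{a.span} and {b.span}"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def support_counts(self) -> dict[str, int]:
        counts = {s.value: 0 for s in Support}
        for e in self.entries:
            counts[e.support.value] += 1
        return counts


@dataclass
class ChromosomeChromatin:
    chromosome: str
    length_bp: int
    het: Optional[tuple[int, int]]  # 1-based inclusive, None = all euchromatic

    def __post_init__(self) -> None:
        if self.het is not None:
            lo, hi = self.het
            if hi < lo:
                raise MapforgeError(
                    f"het interval end {hi} < start {lo} on {self.chromosome}"
                )
            if hi > self.length_bp:
                raise MapforgeError(
                    f"het interval {self.het} exceeds length of {self.chromosome}"
                )

    def het_length(self) -> int:
        if self.het is None:
            return 0
        return self.het[1] - self.het[0] + 1

    def euch_intervals(self) -> list[tuple[int, int]]:
        if self.het is None:
            return [(1, self.length_bp)]
        lo, hi = self.het
        out = []
        if lo > 1:
            out.append((1, lo - 1))
        if hi < self.length_bp:
            out.append((hi + 1, self.length_bp))
        return out


@dataclass
class ChromatinPartition:
    entries: list[ChromosomeChromatin]

    def by_chromosome(self) -> dict[str, ChromosomeChromatin]:
        return {e.chromosome: e for e in self.entries}


@dataclass
class MareyMap:
    """Genetic position (cM) against physical position (bp) along one
    chromosome; the slope is the local recombination rate."""

    chromosome: str
    points: np.ndarray  # shape (n, 2): column 0 bp, column 1 cM, sorted by bp
    n_dropped: int = 0  # non-monotone residual points removed

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise MapforgeError("Marey points must be an (n, 2) array")
        if np.any(np.diff(pts[:, 0]) <= 0):
            raise MapforgeError("Marey bp coordinates must be strictly increasing")
        if np.any(np.diff(pts[:, 1]) < -1e-9):
            raise MapforgeError("Marey cM coordinates must be non-decreasing")
        self.points = pts


def _first_duplicate(items: Sequence) -> object:
    seen: set = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
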