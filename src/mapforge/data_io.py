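"""Readers and writers for every on-disk artifact the pipeline touches.

All tabular formats are plain text (CSV/TSV), validated strictly on read:
any failure names the offending row or cell. Writers and readers are exact
inverses on valid in-memory objects.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import (
    CALL_SYMBOLS,
    SYMBOL_TO_CODE,
    ChromatinPartition,
    ChromosomeChromatin,
    GenotypeMatrix,
    MapforgeError,
    PhysicalPlacement,
    Scaffold,
    ScaffoldSet,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------- genotypes

def read_genotypes(path: PathLike, population_id: Optional[str] = None) -> GenotypeMatrix:
    """Read a genotype CSV: first column marker_id, header row of line ids,
    cells in {A, B, H, -, NA, .} ('-', 'NA' and '.' all mean missing)."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise MapforgeError(f"{path}: empty file")
        line_ids = header[1:]
        marker_ids: list[str] = []
        rows: list[list[int]] = []
        for rnum, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise MapforgeError(
                    f"{path}: row {rnum} has {len(row)} fields, expected {len(header)}"
                )
            marker_ids.append(row[0])
            codes = []
            for cnum, cell in enumerate(row[1:]):
                code = SYMBOL_TO_CODE.get(cell.strip())
                if code is None:
                    raise MapforgeError(
                        f"{path}: illegal call {cell!r} at row {rnum} "
                        f"(marker {row[0]!r}), column {line_ids[cnum]!r}"
                    )
                codes.append(code)
            rows.append(codes)
    calls = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(line_ids)), np.int8)
    return GenotypeMatrix(population_id or path.stem, line_ids, marker_ids, calls)


def write_genotypes(g: GenotypeMatrix, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["marker_id", *g.line_ids])
        symbols = CALL_SYMBOLS[g.calls]
        for mid, row in zip(g.marker_ids, symbols):
            writer.writerow([mid, *row])


# ---------------------------------------------------------------- placement

def read_placement(path: PathLike, assembly_id: Optional[str] = None) -> PhysicalPlacement:
    """Read a placement TSV with columns marker_id, chromosome, position."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    expected = ["marker_id", "chromosome", "position"]
    if list(df.columns) != expected:
        raise MapforgeError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return PhysicalPlacement(assembly_id or path.stem, df)


def write_placement(p: PhysicalPlacement, path: PathLike) -> None:
    p.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- scaffolds

def read_scaffolds(path: PathLike) -> ScaffoldSet:
    """Scaffold TSV: scaffold_id, length, marker_id, offset ('.' marker_id for
    a scaffold with no markers). One row per marker."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"scaffold_id": str, "marker_id": str})
    entries: dict[str, Scaffold] = {}
    for _, row in df.iterrows():
        sid = row["scaffold_id"]
        length = int(row["length"])
        if sid not in entries:
            entries[sid] = Scaffold(sid, length, [])
        elif entries[sid].length != length:
            raise MapforgeError(f"{path}: inconsistent length for scaffold {sid!r}")
        if row["marker_id"] != ".":
            entries[sid].markers.append((row["marker_id"], int(row["offset"])))
    out = ScaffoldSet(list(entries.values()))
    for s in out.entries:  # re-run the offset invariant now members are complete
        Scaffold(s.scaffold_id, s.length, s.markers)
    return out


def write_scaffolds(s: ScaffoldSet, path: PathLike) -> None:
    rows = []
    for sc in s.entries:
        if not sc.markers:
            rows.append((sc.scaffold_id, sc.length, ".", 0))
        for mid, off in sc.markers:
            rows.append((sc.scaffold_id, sc.length, mid, off))
    pd.DataFrame(rows, columns=["scaffold_id", "length", "marker_id", "offset"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------- AGP

@dataclass
class AgpPiece:
    """One component line of an AGP object: a source-scaffold interval placed
    on a chromosome, possibly reverse-complemented."""

    object_id: str
    object_beg: int
    object_end: int
    component_id: str
    component_beg: int
    component_end: int
    orientation: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise MapforgeError(f"orientation {self.orientation!r} not in {{+,-}}")
        if self.object_end < self.object_beg or self.component_end < self.component_beg:
            raise MapforgeError(f"inverted interval in AGP piece {self.component_id!r}")
        if (self.object_end - self.object_beg) != (self.component_end - self.component_beg):
            raise MapforgeError(
                f"object span != component span for {self.component_id!r}"
            )


def write_agp(pieces: list[AgpPiece], path: PathLike) -> None:
    """Write an AGP v2.1 file. Pieces are grouped by object, sorted by object
    coordinate; any gap between adjacent pieces is emitted as a U gap line
    (scaffold gap, linkage asserted by map evidence)."""
    by_obj: dict[str, list[AgpPiece]] = {}
    for p in pieces:
        by_obj.setdefault(p.object_id, []).append(p)
    lines = ["##agp-version\t2.1"]
    for obj in sorted(by_obj):
        parts = sorted(by_obj[obj], key=lambda p: p.object_beg)
        for a, b in zip(parts, parts[1:]):
            if b.object_beg <= a.object_end:
                raise MapforgeError(
                    f"overlapping object coordinates on {obj}: "
                    f"{(a.object_beg, a.object_end)} and {(b.object_beg, b.object_end)}"
                )
        part_number = 0
        prev_end = 0
        for p in parts:
            if p.object_beg > prev_end + 1:
                part_number += 1
                gap_len = p.object_beg - prev_end - 1
                lines.append(
                    "\t".join(
                        [obj, str(prev_end + 1), str(p.object_beg - 1), str(part_number),
                         "U", str(gap_len), "scaffold", "yes", "map"]
                    )
                )
            part_number += 1
            lines.append(
                "\t".join(
                    [obj, str(p.object_beg), str(p.object_end), str(part_number),
                     "W", p.component_id, str(p.component_beg), str(p.component_end),
                     p.orientation]
                )
            )
            prev_end = p.object_end
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------- BED

_BED_TRACK = 'track name="chromatin"'


def write_bed(partition: ChromatinPartition, path: PathLike) -> None:
    """Serialize a chromatin partition as BED (0-based half-open); interval
    names are "heterochromatin" / "euchromatin"."""
    lines = [_BED_TRACK]
    for e in partition.entries:
        feats = []
        if e.het is not None:
            feats.append((e.het, "heterochromatin"))
        feats.extend(((iv, "euchromatin") for iv in e.euch_intervals()))
        feats.sort(key=lambda t: t[0])
        for (lo, hi), name in feats:
            lines.append(f"{e.chromosome}\t{lo - 1}\t{hi}\t{name}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed_partition(path: PathLike) -> ChromatinPartition:
    """Inverse of :func:`write_bed`; chromosome lengths are recovered from the
    interval union (the writer always covers [1, length])."""
    het: dict[str, tuple[int, int]] = {}
    length: dict[str, int] = {}
    order: list[str] = []
    for lnum, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith(("track", "#")):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise MapforgeError(f"{path}: line {lnum}: expected 4 BED fields")
        chrom, start0, end, name = fields
        lo, hi = int(start0) + 1, int(end)
        if hi < lo:
            raise MapforgeError(f"{path}: line {lnum}: interval end < start")
        if chrom not in length:
            order.append(chrom)
            length[chrom] = 0
        length[chrom] = max(length[chrom], hi)
        if name == "heterochromatin":
            if chrom in het:
                raise MapforgeError(f"{path}: line {lnum}: second het interval on {chrom}")
            het[chrom] = (lo, hi)
        elif name != "euchromatin":
            raise MapforgeError(f"{path}: line {lnum}: unknown feature {name!r}")
    return ChromatinPartition(
        [ChromosomeChromatin(c, length[c], het.get(c)) for c in order]
    )
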