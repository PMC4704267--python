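"""Loaders for the packaged correction-ledger, scaffold-anchoring and
chromatin-partition reference tables (small TSV transcriptions shipped with
the package, checksum-verified on load)."""
from __future__ import annotations

import hashlib
import re
from importlib import resources

import pandas as pd

from .model import (
    Action,
    ChromatinPartition,
    ChromosomeChromatin,
    CorrectionEntry,
    CorrectionLedger,
    LinkageGroup,
    LinkageMap,
    MapforgeError,
    Scaffold,
    ScaffoldSet,
    Support,
)

_DIGESTS = {
    "table2.tsv": "e7ec1f8cf9cc2a430be4796f637e5afd53a383bdd34e9533206bfec041529572",
    "table3.tsv": "1bc64e5b8c9427fe0f65159f4670da2645eff4b7626e50f73deee28ab2d98cbc",
    "table4.tsv": "14bd0878e508ddc5180050f31cce1758b7e5c09727068444b682e46270736795",
}

_SUPPORT = {"WP and EW": Support.BOTH, "WP": Support.POP1_ONLY, "EW": Support.POP2_ONLY}


def _fixture_text(filename: str) -> str:
    data = resources.files("mapforge").joinpath("data", filename).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _DIGESTS[filename]:
        raise MapforgeError(f"fixture {filename} checksum mismatch: {digest}")
    return data.decode()


def _comment_to_action(comment: str) -> tuple[Action, str | None]:
    m = re.fullmatch(r"Move to (Gm\d+)", comment)
    if m:
        return Action.MOVE, m.group(1)
    m = re.fullmatch(r"Re-orient and move to (Gm\d+)", comment)
    if m:
        return Action.MOVE_AND_REORIENT, m.group(1)
    if comment == "Re-orient":
        return Action.REORIENT, None
    if comment == "Move and Re-orient":
        return Action.MOVE_AND_REORIENT, None
    if comment == "Move to top of chromosome":
        return Action.REPOSITION_WITHIN, None
    if comment == "A number of changes needed":
        return Action.COMPLEX, None
    raise MapforgeError(f"unrecognized correction comment {comment!r}")


def load_table2() -> CorrectionLedger:
    """Correction ledger: 22 BOTH-supported plus 15 single-population
    regions/markers needing re-positioning or reorientation."""
    from io import StringIO

    df = pd.read_csv(StringIO(_fixture_text("table2.tsv")), sep="\t")
    entries = []
    for row in df.itertuples(index=False):
        action, target = _comment_to_action(row.comment)
        entries.append(
            CorrectionEntry(
                chromosome=row.first_chromosome,
                first_marker=row.first_marker,
                last_marker=row.last_marker,
                span=(int(row.first_position), int(row.last_position)),
                action=action,
                target=target,
                support=_SUPPORT[row.support],
            )
        )
    return CorrectionLedger(entries, metadata={"source": "packaged fixture table2"})


def load_table3() -> tuple[ScaffoldSet, dict[str, LinkageMap]]:
    """Previously unanchored scaffolds and the per-population linkage
    positions of their SNPs (28 scaffolds, 32 SNP records)."""
    from io import StringIO

    df = pd.read_csv(
        StringIO(_fixture_text("table3.tsv")), sep="\t",
        dtype={"snp_id": str, "scaffold_id": str}, na_values=["."],
    )
    scaffolds: dict[str, Scaffold] = {}
    loci: dict[str, dict[str, list[tuple[str, float]]]] = {"WP": {}, "EW": {}}
    for row in df.itertuples(index=False):
        sid = row.scaffold_id
        if sid not in scaffolds:
            scaffolds[sid] = Scaffold(sid, int(row.scaffold_length), [])
        elif scaffolds[sid].length != int(row.scaffold_length):
            raise MapforgeError(f"inconsistent length for {sid!r}")
        scaffolds[sid].markers.append((row.snp_id, int(row.offset)))
        for pop, lg_col, cm_col in (("WP", row.wp_lg, row.wp_cm), ("EW", row.ew_lg, row.ew_cm)):
            if pd.notna(lg_col):
                gid = str(int(lg_col))
                loci[pop].setdefault(gid, []).append((row.snp_id, float(cm_col)))
    maps = {
        pop: LinkageMap(
            pop,
            [LinkageGroup(gid, sorted(ls, key=lambda x: (x[1], x[0])))
             for gid, ls in sorted(loci[pop].items(), key=lambda kv: int(kv[0]))],
        )
        for pop in ("WP", "EW")
    }
    return ScaffoldSet(list(scaffolds.values())), maps


def lg_to_chromosome(n_groups: int = 20) -> dict[str, str]:
    """Numbered linkage group -> soybean chromosome name (LG i <-> Gm{i:02d})."""
    return {str(i): f"Gm{i:02d}" for i in range(1, n_groups + 1)}


def load_table4() -> tuple[ChromatinPartition, int]:
    """Per-chromosome heterochromatic intervals plus the printed assembly
    chromosome total (bp). Mb values become bp by x 10^6 rounding; a het
    interval starting at 0 Mb is clamped to position 1."""
    text = _fixture_text("table4.tsv")
    total_mb = None
    for line in text.splitlines():
        m = re.match(r"#\s*assembly_total_mb=([\d.]+)", line)
        if m:
            total_mb = float(m.group(1))
    if total_mb is None:
        raise MapforgeError("table4 fixture lacks the assembly total")
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", comment="#")
    entries = []
    for row in df.itertuples(index=False):
        lo = max(1, int(round(row.het_start_mb * 1e6)))
        hi = int(round(row.het_end_mb * 1e6))
        entries.append(
            ChromosomeChromatin(row.chromosome, int(round(row.length_mb * 1e6)), (lo, hi))
        )
    return ChromatinPartition(entries), int(round(total_mb * 1e6))


def load_table_fixture(name: str):
    if name == "table2":
        return load_table2()
    if name == "table3":
        return load_table3()
    if name == "table4":
        return load_table4()
    raise MapforgeError(f"unknown fixture {name!r}")
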