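"""Position SSR and SNP markers in a target assembly sequence.

Placement uses dual evidence, mirroring electronic-PCR plus source-sequence
alignment: a primer pair must amplify exactly (no gaps, no mismatches), the
marker's source/flanking sequence must align at high identity over nearly
its full length, the amplicon must have the expected length, and for SSRs
the repeat motif must sit between the primers. A marker is UNAMBIGUOUS only
when exactly one genomic region satisfies everything; multiple qualifying
regions make it AMBIGUOUS, none make it UNPLACED, and the per-criterion
diagnostics record which requirement failed.

The source matcher is a seed-and-extend scanner: exact seeds of length 50
are extended ungapped in both directions; hits are kept at >= 99 % identity
over >= 95 % of the source length; seeds occurring more than 1000 times are
discarded as low-complexity. IUPAC ambiguity codes in the genome count as
mismatches.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .model import MapforgeError

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _check_nt(name: str, seq: str, allow_n: bool = False) -> None:
    alphabet = set("ACGTN" if allow_n else "ACGT")
    if not seq or set(seq) - alphabet:
        raise MapforgeError(f"{name} must be nonempty uppercase {''.join(sorted(alphabet))}")


@dataclass
class SsrDescriptor:
    ssr_id: str
    forward_primer: str
    reverse_primer: str
    motif: str
    source_sequence: str
    expected_amplicon_length: int

    def __post_init__(self) -> None:
        _check_nt("forward_primer", self.forward_primer)
        _check_nt("reverse_primer", self.reverse_primer)
        _check_nt("source_sequence", self.source_sequence, allow_n=True)
        if len(self.motif) not in (2, 3, 4):
            raise MapforgeError(
                f"motif {self.motif!r} must be a di-/tri-/tetranucleotide repeat unit"
            )


@dataclass
class SnpDescriptor:
    snp_id: str
    flank_5prime: str
    flank_3prime: str
    alleles: str = ""

    def __post_init__(self) -> None:
        _check_nt("flank_5prime", self.flank_5prime, allow_n=True)
        _check_nt("flank_3prime", self.flank_3prime, allow_n=True)
        if len(self.flank_5prime) + len(self.flank_3prime) < 50:
            raise MapforgeError("combined SNP flanks must be >= 50 bp")


@dataclass
class PlacementResult:
    marker_id: str
    status: str  # UNAMBIGUOUS | AMBIGUOUS | UNPLACED
    position: Optional[tuple[str, int]] = None
    diagnostics: dict = field(default_factory=dict)


def _find_all(hay: str, needle: str) -> list[int]:
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


# ------------------------------------------------------------ in-silico PCR

def insilico_pcr(
    genome: Mapping[str, str],
    forward_primer: str,
    reverse_primer: str,
    max_amplicon: int = 10_000,
) -> list[tuple[str, str, int, int]]:
    """All exact amplification products of a primer pair over all sequences,
    both strands. Coordinates are 1-based inclusive and span the primer outer
    ends. No mismatches or gaps are tolerated; an empty list means no product.
    """
    if len(forward_primer) < 15 or len(reverse_primer) < 15:
        raise MapforgeError("primers must be >= 15 bp")
    products = []
    for chrom, seq in genome.items():
        seq = str(seq).upper()
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            rc_rev = revcomp(reverse_primer)
            for p in _find_all(s, forward_primer):
                stop = min(n, p + max_amplicon)
                q = s.find(rc_rev, p + len(forward_primer))
                while q != -1:
                    end = q + len(reverse_primer)
                    if end - p > max_amplicon:
                        break
                    if strand == "+":
                        products.append((chrom, "+", p + 1, end))
                    else:
                        products.append((chrom, "-", n - end + 1, n - p))
                    q = s.find(rc_rev, q + 1)
                    if q != -1 and q + len(reverse_primer) > stop:
                        break
    return sorted(products)


# ------------------------------------------------------- source-seq matcher

@dataclass
class SourceHit:
    chromosome: str
    strand: str
    start: int  # 1-based inclusive on the plus strand
    end: int
    identity: float


def match_source(
    genome: Mapping[str, str],
    source: str,
    seed: int = 50,
    min_identity: float = 0.99,
    min_coverage: float = 0.95,
    max_seed_hits: int = 1000,
    seed_step: int = 10,
) -> list[SourceHit]:
    """Locate near-exact copies of ``source``. 'N' in the source matches any
    genome base (used for the SNP wildcard position)."""
    if len(source) < seed:
        raise MapforgeError(f"source shorter than the {seed} bp seed requirement")
    source = source.upper()
    hits: dict[tuple[str, str, int], SourceHit] = {}
    seeds = _seed_windows(source, seed, seed_step)
    for chrom, raw in genome.items():
        seq = str(raw).upper()
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for o, kmer in seeds:
                occ = _find_all(s, kmer)
                if len(occ) > max_seed_hits:
                    continue  # low-complexity guard
                for g in occ:
                    a = g - o  # implied source start in s-coordinates
                    lo = max(a, 0)
                    hi = min(a + len(source), n)
                    key = (chrom, strand, a)
                    if key in hits or hi <= lo:
                        continue
                    window = s[lo:hi]
                    src = source[lo - a : hi - a]
                    matches = sum(1 for x, y in zip(src, window) if x == y or x == "N")
                    coverage = (hi - lo) / len(source)
                    identity = matches / (hi - lo)
                    if identity >= min_identity and coverage >= min_coverage:
                        if strand == "+":
                            start, end = lo + 1, hi
                        else:
                            start, end = n - hi + 1, n - lo
                        hits[key] = SourceHit(chrom, strand, start, end, identity)
    return _merge_overlapping(list(hits.values()))


def _seed_windows(source: str, seed: int, step: int) -> list[tuple[int, str]]:
    """Exact-match seed windows within the N-free runs of the source. Runs
    shorter than the seed length (as around a SNP wildcard flanked by < seed
    bp) contribute their full extent as a single seed, down to 15 bp."""
    import re

    seeds: list[tuple[int, str]] = []
    for m in re.finditer(r"[^N]+", source):
        run_start, run = m.start(), m.group()
        if len(run) >= seed:
            offsets = list(range(0, len(run) - seed + 1, step))
            if offsets[-1] != len(run) - seed:
                offsets.append(len(run) - seed)
            seeds.extend((run_start + o, run[o : o + seed]) for o in offsets)
        elif len(run) >= 15:
            seeds.append((run_start, run))
    if not seeds:
        raise MapforgeError("source has no seedable (N-free, >= 15 bp) segment")
    return seeds


def _merge_overlapping(hits: list[SourceHit]) -> list[SourceHit]:
    """Overlapping hits on the same sequence collapse to the best identity."""
    hits = sorted(hits, key=lambda h: (h.chromosome, h.start, -h.identity))
    out: list[SourceHit] = []
    for h in hits:
        if out and out[-1].chromosome == h.chromosome and h.start <= out[-1].end:
            if h.identity > out[-1].identity:
                out[-1] = h
        else:
            out.append(h)
    return sorted(out, key=lambda h: (h.chromosome, h.start))


# ---------------------------------------------------------------- placement

def _tandem_motif_present(inner: str, motif: str, min_copies: int) -> bool:
    return (motif * min_copies) in inner or (revcomp(motif) * min_copies) in inner


def place_ssr(
    genome: Mapping[str, str],
    ssr: SsrDescriptor,
    length_tolerance: int = 0,
    min_motif_copies: int = 5,
    max_amplicon: int = 10_000,
) -> PlacementResult:
    """Dual-evidence SSR placement: a region qualifies when a PCR product
    exists there, a source-sequence hit overlaps it, the product has the
    expected length (within ``length_tolerance``) and >= ``min_motif_copies``
    tandem copies of the motif lie between the primer inner ends."""
    products = insilico_pcr(genome, ssr.forward_primer, ssr.reverse_primer, max_amplicon)
    source_hits = match_source(genome, ssr.source_sequence)
    diag = {
        "n_pcr_products": len(products),
        "n_source_hits": len(source_hits),
        "failed": [],
    }
    qualifying = []
    for chrom, strand, start, end in products:
        reasons = []
        if not any(
            h.chromosome == chrom and h.start <= end and start <= h.end for h in source_hits
        ):
            reasons.append("source_overlap")
        if abs((end - start + 1) - ssr.expected_amplicon_length) > length_tolerance:
            reasons.append("amplicon_length")
        inner = str(genome[chrom])[start - 1 + len(ssr.forward_primer) : end - len(ssr.reverse_primer)].upper()
        if not _tandem_motif_present(inner, ssr.motif, min_motif_copies):
            reasons.append("motif_between_primers")
        if reasons:
            diag["failed"].append(((chrom, start), reasons))
        else:
            qualifying.append((chrom, strand, start, end))
    if len(qualifying) == 1:
        chrom, _, start, _ = qualifying[0]
        return PlacementResult(ssr.ssr_id, "UNAMBIGUOUS", (chrom, start), diag)
    if len(qualifying) > 1:
        return PlacementResult(ssr.ssr_id, "AMBIGUOUS", None, diag)
    return PlacementResult(ssr.ssr_id, "UNPLACED", None, diag)


def place_snp(genome: Mapping[str, str], snp: SnpDescriptor) -> PlacementResult:
    """Place a SNP by aligning its concatenated flanks with one wildcard
    position; the reported coordinate is the wildcard's genomic position."""
    source = snp.flank_5prime + "N" + snp.flank_3prime
    hits = match_source(genome, source)
    diag = {"n_source_hits": len(hits)}
    if len(hits) == 1:
        h = hits[0]
        if h.strand == "+":
            pos = h.start + len(snp.flank_5prime)
        else:
            pos = h.end - len(snp.flank_5prime)
        return PlacementResult(snp.snp_id, "UNAMBIGUOUS", (h.chromosome, pos), diag)
    if len(hits) > 1:
        return PlacementResult(snp.snp_id, "AMBIGUOUS", None, diag)
    return PlacementResult(snp.snp_id, "UNPLACED", None, diag)


def load_genome(path) -> dict[str, str]:
    """Read a FASTA file into a name -> sequence mapping."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True)
    return {name: str(fa[name][:]) for name in fa.keys()}
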