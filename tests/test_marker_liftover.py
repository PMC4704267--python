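"""In-silico PCR and dual-evidence marker placement against construction
and exhaustive-scan oracles."""
import numpy as np
import pytest

from mapforge.marker_liftover import (
    PlacementResult,
    SnpDescriptor,
    SsrDescriptor,
    insilico_pcr,
    match_source,
    place_snp,
    place_ssr,
    revcomp,
)
from mapforge.model import MapforgeError

NT = np.array(list("ACGT"))


def rand_seq(rng, n):
    return "".join(rng.choice(NT, n))


def brute_force_pcr(genome, fwd, rev, max_amplicon=10_000):
    """Exhaustive scanner: test every (start, end) primer placement."""
    out = []
    for chrom, seq in genome.items():
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            rc = revcomp(rev)
            for p in range(n - len(fwd) + 1):
                if s[p : p + len(fwd)] != fwd:
                    continue
                for q in range(p + len(fwd), min(n, p + max_amplicon) - len(rev) + 1):
                    if s[q : q + len(rev)] == rc:
                        end = q + len(rev)
                        if end - p <= max_amplicon:
                            if strand == "+":
                                out.append((chrom, "+", p + 1, end))
                            else:
                                out.append((chrom, "-", n - end + 1, n - p))
    return sorted(out)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


class TestInsilicoPcr:
    def test_planted_primer_pair_yields_expected_product(self, rng):
        fwd, rev = rand_seq(rng, 18), rand_seq(rng, 18)
        insert = rand_seq(rng, 20)
        genome = {"c1": rand_seq(rng, 30) + fwd + insert + revcomp(rev) + rand_seq(rng, 30)}
        products = insilico_pcr(genome, fwd, rev)
        assert products == [("c1", "+", 31, 31 + 18 + 20 + 18 - 1)]

    def test_single_mismatch_kills_amplification(self, rng):
        fwd, rev = rand_seq(rng, 18), rand_seq(rng, 18)
        mutated = ("A" if fwd[9] != "A" else "C") + fwd[1:] if False else \
            fwd[:9] + ("A" if fwd[9] != "A" else "C") + fwd[10:]
        genome = {"c1": rand_seq(rng, 30) + mutated + rand_seq(rng, 20) + revcomp(rev)}
        assert insilico_pcr(genome, fwd, rev) == []

    def test_products_found_on_both_strands(self, rng):
        fwd, rev = rand_seq(rng, 16), rand_seq(rng, 16)
        amp = fwd + rand_seq(rng, 25) + revcomp(rev)
        genome = {"c1": rand_seq(rng, 40) + amp + rand_seq(rng, 40) + revcomp(amp) + rand_seq(rng, 40)}
        products = insilico_pcr(genome, fwd, rev)
        assert len(products) == 2
        assert {p[1] for p in products} == {"+", "-"}
        # both products have the same amplicon length
        assert len({p[3] - p[2] for p in products}) == 1

    def test_short_primers_rejected(self):
        with pytest.raises(MapforgeError, match="15 bp"):
            insilico_pcr({"c1": "ACGT" * 30}, "ACGTACGTACGT", "ACGTACGTACGTACGT")

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_exhaustive_scanner(self, seed):
        """On small genomes every product of the fast matcher must coincide
        with the brute-force all-substring scan."""
        r = np.random.default_rng(seed)
        fwd, rev = rand_seq(r, 15), rand_seq(r, 15)
        pieces = [rand_seq(r, 500)]
        for _ in range(int(r.integers(1, 4))):  # plant a few loci
            pieces += [fwd, rand_seq(r, int(r.integers(5, 60))), revcomp(rev),
                       rand_seq(r, 300)]
        genome = {"c1": "".join(pieces), "c2": rand_seq(r, 2000)}
        assert insilico_pcr(genome, fwd, rev) == brute_force_pcr(genome, fwd, rev)


class TestMatchSource:
    def test_verbatim_copy_found_at_full_identity(self, rng):
        src = rand_seq(rng, 300)
        genome = {"c1": rand_seq(rng, 500) + src + rand_seq(rng, 500)}
        (hit,) = match_source(genome, src)
        assert (hit.start, hit.end, hit.identity) == (501, 800, 1.0)

    def test_two_percent_divergence_fails_the_cutoff(self, rng):
        src = rand_seq(rng, 500)
        mutated = list(src)
        for i in range(0, 500, 50):  # 2 % scattered substitutions
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        genome = {"c1": rand_seq(rng, 200) + "".join(mutated) + rand_seq(rng, 200)}
        assert match_source(genome, src) == []

    def test_duplicated_source_gives_two_hits(self, rng):
        src = rand_seq(rng, 200)
        genome = {"c1": rand_seq(rng, 100) + src + rand_seq(rng, 100) + src}
        assert len(match_source(genome, src)) == 2

    def test_reverse_complement_copy_found_on_minus_strand(self, rng):
        src = rand_seq(rng, 200)
        genome = {"c1": rand_seq(rng, 150) + revcomp(src) + rand_seq(rng, 150)}
        (hit,) = match_source(genome, src)
        assert hit.strand == "-" and (hit.start, hit.end) == (151, 350)


def _planted_ssr(rng, ssr_id="ssr1", motif="AG", copies=8):
    fwd, rev = rand_seq(rng, 20), rand_seq(rng, 20)
    inner = rand_seq(rng, 8) + motif * copies + rand_seq(rng, 8)
    amplicon = fwd + inner + revcomp(rev)
    source = rand_seq(rng, 25) + amplicon + rand_seq(rng, 25)
    desc = SsrDescriptor(ssr_id, fwd, rev, motif, source, len(amplicon))
    return desc, amplicon, source


class TestPlaceSsr:
    def test_planted_locus_unambiguous_at_planted_position(self, rng):
        desc, amp, src = _planted_ssr(rng)
        genome = {"c1": rand_seq(rng, 400) + src + rand_seq(rng, 400)}
        res = place_ssr(genome, desc)
        assert res.status == "UNAMBIGUOUS"
        assert res.position == ("c1", 400 + 25 + 1)

    def test_motif_deletion_fails_the_motif_criterion(self, rng):
        desc, amp, src = _planted_ssr(rng)
        gutted = src.replace(desc.motif * 8, rand_seq(rng, 16))
        genome = {"c1": rand_seq(rng, 200) + gutted + rand_seq(rng, 200)}
        res = place_ssr(genome, SsrDescriptor(
            desc.ssr_id, desc.forward_primer, desc.reverse_primer, desc.motif,
            gutted, desc.expected_amplicon_length))
        assert res.status == "UNPLACED"
        assert any("motif_between_primers" in reasons for _, reasons in res.diagnostics["failed"])

    def test_locus_on_two_chromosomes_is_ambiguous(self, rng):
        desc, amp, src = _planted_ssr(rng)
        genome = {"c1": rand_seq(rng, 100) + src + rand_seq(rng, 100),
                  "c2": rand_seq(rng, 300) + src}
        assert place_ssr(genome, desc).status == "AMBIGUOUS"

    def test_wrong_amplicon_length_fails(self, rng):
        desc, amp, src = _planted_ssr(rng)
        genome = {"c1": rand_seq(rng, 100) + src + rand_seq(rng, 100)}
        short = SsrDescriptor(desc.ssr_id, desc.forward_primer, desc.reverse_primer,
                              desc.motif, src, desc.expected_amplicon_length - 7)
        res = place_ssr(genome, short)
        assert res.status == "UNPLACED"
        assert any("amplicon_length" in r for _, r in res.diagnostics["failed"])

    def test_motif_length_validated(self):
        with pytest.raises(MapforgeError, match="motif"):
            SsrDescriptor("x", "A" * 20, "C" * 20, "ACGTA", "A" * 100, 50)


class TestPlaceSnp:
    def test_planted_flanks_place_at_the_wildcard(self, rng):
        f5, f3 = rand_seq(rng, 60), rand_seq(rng, 60)
        genome = {"c1": rand_seq(rng, 700) + f5 + "T" + f3 + rand_seq(rng, 700)}
        res = place_snp(genome, SnpDescriptor("s1", f5, f3, "C/T"))
        assert res.status == "UNAMBIGUOUS"
        assert res.position == ("c1", 761)

    def test_absent_flanks_unplaced(self, rng):
        res = place_snp({"c1": rand_seq(rng, 2000)},
                        SnpDescriptor("s1", rand_seq(rng, 40), rand_seq(rng, 40)))
        assert res.status == "UNPLACED"

    def test_duplicated_flanks_ambiguous(self, rng):
        f5, f3 = rand_seq(rng, 40), rand_seq(rng, 40)
        locus = f5 + "G" + f3
        genome = {"c1": rand_seq(rng, 100) + locus + rand_seq(rng, 100) + locus}
        assert place_snp(genome, SnpDescriptor("s1", f5, f3)).status == "AMBIGUOUS"

    def test_short_combined_flanks_rejected(self):
        with pytest.raises(MapforgeError, match="50 bp"):
            SnpDescriptor("s1", "ACGT" * 5, "ACGT" * 5)


def test_strand_symmetry_of_placements(rng):
    """Reverse-complementing the genome mirrors every placement coordinate."""
    desc, amp, src = _planted_ssr(rng, motif="AT")
    genome = {"c1": rand_seq(rng, 300) + src + rand_seq(rng, 300)}
    n = len(genome["c1"])
    fwd_res = place_ssr(genome, desc)
    rc_res = place_ssr({"c1": revcomp(genome["c1"])}, desc)
    assert fwd_res.status == rc_res.status == "UNAMBIGUOUS"
    # product start on the rc genome mirrors the product END on the original
    fwd_end = fwd_res.position[1] + desc.expected_amplicon_length - 1
    assert rc_res.position[1] == n - fwd_end + 1
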