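"""Round-trip and validation behavior of the on-disk formats."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mapforge import data_io
from mapforge.data_io import AgpPiece
from mapforge.model import (
    ChromatinPartition,
    ChromosomeChromatin,
    GenotypeMatrix,
    MapforgeError,
    PhysicalPlacement,
    Scaffold,
    ScaffoldSet,
)

from conftest import random_genotypes


class TestGenotypesCsv:
    def test_well_formed_file_round_trips_identically(self, tmp_path):
        g = GenotypeMatrix("pop", ["l1", "l2", "l3"], ["m1", "m2"],
                           np.array([[0, 1, 2], [3, 0, 1]], dtype=np.int8))
        path = tmp_path / "g.csv"
        data_io.write_genotypes(g, path)
        back = data_io.read_genotypes(path, population_id="pop")
        assert back.equals(g)

    def test_missing_synonyms_normalize(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("marker_id,l1,l2,l3\nm1,-,NA,.\n")
        g = data_io.read_genotypes(path)
        assert (g.calls == 3).all()

    def test_illegal_symbol_names_the_cell(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("marker_id,l1,l2\nm1,A,X\n")
        with pytest.raises(MapforgeError, match=r"'X'.*'m1'.*'l2'"):
            data_io.read_genotypes(path)

    def test_ragged_row_rejected(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("marker_id,l1,l2\nm1,A\n")
        with pytest.raises(MapforgeError, match="row 2"):
            data_io.read_genotypes(path)

    def test_duplicate_marker_rejected(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("marker_id,l1\nm1,A\nm1,B\n")
        with pytest.raises(MapforgeError, match="duplicate marker_id"):
            data_io.read_genotypes(path)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), m=st.integers(1, 12), n=st.integers(1, 12))
    def test_random_matrices_round_trip(self, tmp_path_factory, seed, m, n):
        g = random_genotypes(np.random.default_rng(seed), m, n)
        path = tmp_path_factory.mktemp("io") / "g.csv"
        data_io.write_genotypes(g, path)
        assert data_io.read_genotypes(path, population_id="RAND").equals(g)


class TestPlacementTsv:
    def test_single_record(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("marker_id\tchromosome\tposition\n"
                        "BARC_1.01_Gm02_22523407_T_C\tGm02\t22523407\n")
        p = data_io.read_placement(path)
        assert len(p) == 1
        assert p.position_of("BARC_1.01_Gm02_22523407_T_C") == ("Gm02", 22523407)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("marker_id\tchromosome\tposition\n")
        assert len(data_io.read_placement(path)) == 0

    def test_position_below_one_rejected(self):
        with pytest.raises(MapforgeError, match="position 0"):
            PhysicalPlacement("a", pd.DataFrame(
                [("m1", "c1", 0)], columns=["marker_id", "chromosome", "position"]))

    def test_duplicate_marker_rejected(self):
        with pytest.raises(MapforgeError, match="duplicate"):
            PhysicalPlacement("a", pd.DataFrame(
                [("m1", "c1", 5), ("m1", "c2", 9)],
                columns=["marker_id", "chromosome", "position"]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_placements_round_trip(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        df = pd.DataFrame({
            "marker_id": [f"m{i}" for i in range(n)],
            "chromosome": rng.choice(["c1", "c2", "c3"], n),
            "position": rng.integers(1, 10**8, n),
        })
        p = PhysicalPlacement("asm", df)
        path = tmp_path / "p.tsv"
        data_io.write_placement(p, path)
        assert data_io.read_placement(path, assembly_id="asm").equals(p)


def _validate_agp(path):
    """Independent AGP v2.1 grammar check: column counts, coordinate algebra,
    sequential part numbers, contiguous object coverage."""
    lines = path.read_text().splitlines()
    assert lines[0].startswith("##agp-version\t2.1")
    state = {}  # object -> (last_end, last_part)
    for line in lines[1:]:
        f = line.split("\t")
        assert len(f) == 9
        obj, beg, end, part = f[0], int(f[1]), int(f[2]), int(f[3])
        last_end, last_part = state.get(obj, (0, 0))
        assert beg == last_end + 1, "object coverage must be contiguous"
        assert part == last_part + 1, "part numbers must be sequential"
        assert end >= beg
        if f[4] == "W":
            cbeg, cend = int(f[6]), int(f[7])
            assert end - beg == cend - cbeg
            assert f[8] in "+-"
        elif f[4] == "U":
            assert int(f[5]) == end - beg + 1
            assert f[6:9] == ["scaffold", "yes", "map"]
        else:
            raise AssertionError(f"unexpected component type {f[4]}")
        state[obj] = (end, part)


class TestAgp:
    def test_single_piece_spans_whole_object(self, tmp_path):
        path = tmp_path / "a.agp"
        data_io.write_agp([AgpPiece("chr1", 1, 1000, "scaf1", 1, 1000, "+")], path)
        w = path.read_text().splitlines()[1].split("\t")
        assert (w[0], w[1], w[2], w[4], w[8]) == ("chr1", "1", "1000", "W", "+")
        _validate_agp(path)

    def test_reoriented_piece_gets_minus(self, tmp_path):
        path = tmp_path / "a.agp"
        data_io.write_agp([
            AgpPiece("chr1", 1, 100, "s1", 1, 100, "+"),
            AgpPiece("chr1", 201, 300, "s2", 1, 100, "-"),
        ], path)
        rows = [l.split("\t") for l in path.read_text().splitlines()[1:]]
        assert [r[4] for r in rows] == ["W", "U", "W"]
        assert rows[2][8] == "-"
        _validate_agp(path)

    def test_overlapping_object_coordinates_rejected(self, tmp_path):
        with pytest.raises(MapforgeError, match="overlapping"):
            data_io.write_agp([
                AgpPiece("chr1", 1, 100, "s1", 1, 100, "+"),
                AgpPiece("chr1", 50, 149, "s2", 1, 100, "+"),
            ], tmp_path / "a.agp")

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_random_layouts_pass_grammar_check(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        pieces, cursor = [], 1
        for i in range(int(rng.integers(2, 10))):
            gap = int(rng.integers(0, 500))
            size = int(rng.integers(100, 5000))
            beg = cursor + gap
            pieces.append(AgpPiece("chr1", beg, beg + size - 1, f"s{i}", 1, size,
                                   rng.choice(["+", "-"])))
            cursor = beg + size
        path = tmp_path / "a.agp"
        data_io.write_agp(pieces, path)
        _validate_agp(path)


class TestBed:
    def test_het_interval_is_zero_based_half_open(self, tmp_path):
        part = ChromatinPartition([ChromosomeChromatin("Chr01", 56_800_000,
                                                       (8_100_000, 47_400_000))])
        path = tmp_path / "p.bed"
        data_io.write_bed(part, path)
        lines = path.read_text().splitlines()
        assert "Chr01\t8099999\t47400000\theterochromatin" in lines

    def test_empty_partition_writes_header_only(self, tmp_path):
        path = tmp_path / "p.bed"
        data_io.write_bed(ChromatinPartition([]), path)
        assert path.read_text().strip() == 'track name="chromatin"'

    def test_end_before_start_rejected(self):
        with pytest.raises(MapforgeError, match="end .* < start"):
            ChromosomeChromatin("c1", 100, (50, 10))

    @pytest.mark.parametrize("seed", [6, 7, 8])
    def test_random_partitions_round_trip(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        entries = []
        for i in range(int(rng.integers(1, 6))):
            length = int(rng.integers(10**6, 10**8))
            if rng.random() < 0.3:
                het = None
            else:
                lo = int(rng.integers(1, length // 2))
                het = (lo, int(rng.integers(lo, length)))
            entries.append(ChromosomeChromatin(f"c{i}", length, het))
        part = ChromatinPartition(entries)
        path = tmp_path / "p.bed"
        data_io.write_bed(part, path)
        back = data_io.read_bed_partition(path)
        assert [(e.chromosome, e.length_bp, e.het) for e in back.entries] == [
            (e.chromosome, e.length_bp, e.het) for e in part.entries
        ]


class TestScaffoldTsv:
    def test_round_trip_with_offsets(self, tmp_path):
        s = ScaffoldSet([
            Scaffold("s1", 5000, [("m1", 100), ("m2", 4999)]),
            Scaffold("s2", 800, []),
        ])
        path = tmp_path / "s.tsv"
        data_io.write_scaffolds(s, path)
        back = data_io.read_scaffolds(path)
        assert [(x.scaffold_id, x.length, x.markers) for x in back.entries] == [
            (x.scaffold_id, x.length, x.markers) for x in s.entries
        ]

    def test_offset_beyond_length_rejected(self):
        with pytest.raises(MapforgeError, match="offset"):
            Scaffold("s1", 50, [("m1", 51)])
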