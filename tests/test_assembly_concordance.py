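"""Correction detection, support merging and ledger application."""
import numpy as np
import pandas as pd
import pytest

from mapforge.assembly_concordance import (
    apply_corrections,
    assign_groups_to_chromosomes,
    detect_corrections,
    merge_support,
)
from mapforge.model import (
    Action,
    CorrectionEntry,
    CorrectionLedger,
    LinkageGroup,
    LinkageMap,
    MapforgeError,
    PhysicalPlacement,
    Support,
)
from mapforge.synthetic_data import reattach_scaffolds


def _placement(rows, assembly_id="asm1"):
    return PhysicalPlacement(
        assembly_id, pd.DataFrame(rows, columns=["marker_id", "chromosome", "position"])
    )


def _map(loci_by_group, population_id="WP"):
    return LinkageMap(
        population_id,
        [LinkageGroup(gid, loci) for gid, loci in loci_by_group.items()],
    )


class TestAssignment:
    def test_majority_wins(self):
        lm = _map({"LG1": [(f"m{i}", float(i)) for i in range(10)]})
        rows = [(f"m{i}", "Gm05" if i else "Gm02", 100 * (i + 1)) for i in range(10)]
        asg = assign_groups_to_chromosomes(lm, _placement(rows))
        assert asg.assignment == {"LG1": "Gm05"}

    def test_even_split_left_unresolved(self):
        lm = _map({"LG1": [(f"m{i}", float(i)) for i in range(10)]})
        rows = [(f"m{i}", "Gm05" if i < 5 else "Gm02", 100 * (i + 1)) for i in range(10)]
        asg = assign_groups_to_chromosomes(lm, _placement(rows))
        assert asg.assignment == {} and asg.unresolved == ["LG1"]

    def test_synthetic_truth_is_a_perfect_bijection(self, small_genome, small_truth,
                                                    small_truth_map):
        asg = assign_groups_to_chromosomes(small_truth_map, small_truth.corrupted_assembly)
        assert asg.assignment == {f"LG_{c.name}": c.name for c in small_genome.chromosomes}
        assert not asg.unresolved and not asg.conflicts


class TestDetect:
    def _collinear(self, n=10):
        rows = [(f"m{i}", "Gm01", 1000 * (i + 1)) for i in range(n)]
        loci = [(f"m{i}", 2.0 * i) for i in range(n)]
        return _placement(rows), _map({"LG1": loci})

    def test_concordant_chromosome_yields_empty_ledger(self):
        placement, lm = self._collinear()
        assert len(detect_corrections(lm, placement)) == 0

    def test_internal_inversion_detected_with_exact_bounds(self):
        """Physical 1..10 with the genetic positions of markers 4-7 reversed
        must yield exactly one REORIENT entry spanning markers 4-7."""
        placement, _ = self._collinear()
        cm = {f"m{i}": 2.0 * i for i in range(10)}
        inv = {"m3": cm["m6"], "m4": cm["m5"], "m5": cm["m4"], "m6": cm["m3"]}
        cm.update(inv)
        lm = _map({"LG1": sorted(cm.items(), key=lambda kv: kv[1])})
        ledger = detect_corrections(lm, placement)
        (entry,) = ledger.entries
        assert entry.action == Action.REORIENT
        assert (entry.first_marker, entry.last_marker) == ("m3", "m6")
        assert entry.span == (4000, 7000)

    def test_whole_chromosome_reversal_flagged_not_segmented(self):
        placement, _ = self._collinear()
        lm = _map({"LG1": [(f"m{i}", 2.0 * (9 - i)) for i in range(9, -1, -1)]})
        ledger = detect_corrections(lm, placement)
        assert len(ledger) == 0
        assert ledger.metadata["chromosome_orientation_flipped"] == ["Gm01"]

    def test_lone_outlier_reported_as_singleton_not_correction(self):
        placement, _ = self._collinear()
        cm = {f"m{i}": 2.0 * i for i in range(10)}
        cm["m5"] = 30.0  # single displaced marker
        lm = _map({"LG1": sorted(cm.items(), key=lambda kv: kv[1])})
        ledger = detect_corrections(lm, placement)
        assert len(ledger) == 0
        assert ledger.metadata["singletons"] == ["m5"]

    def test_disjoint_maps_rejected(self):
        placement, _ = self._collinear()
        lm = _map({"LG1": [("other", 0.0), ("other2", 1.0)]})
        with pytest.raises(MapforgeError, match="share no markers"):
            detect_corrections(lm, placement)

    def test_planted_errors_recovered_exactly(self, small_truth, small_truth_map):
        ledger = detect_corrections(small_truth_map, small_truth.corrupted_assembly)
        key = lambda e: (e.chromosome, e.span, e.action, e.first_marker, e.last_marker)
        assert sorted(map(key, ledger.entries)) == sorted(
            map(key, small_truth.planted_errors.entries))

    def test_detect_apply_detect_is_idempotent(self, small_truth, small_truth_map):
        ledger = detect_corrections(small_truth_map, small_truth.corrupted_assembly)
        corrected, _ = apply_corrections(small_truth.corrupted_assembly, ledger)
        assert len(detect_corrections(small_truth_map, corrected)) == 0


class TestMerge:
    def _entry(self, lo, hi, action=Action.REORIENT, chrom="Gm01", support=Support.POP1_ONLY):
        return CorrectionEntry(chrom, f"f{lo}", f"l{hi}", (lo, hi), action, support=support)

    def test_identical_entries_merge_to_both(self):
        l1 = CorrectionLedger([self._entry(100, 200)])
        l2 = CorrectionLedger([self._entry(100, 200, support=Support.POP2_ONLY)])
        merged = merge_support(l1, l2)
        assert merged.support_counts() == {"BOTH": 1, "POP1_ONLY": 0, "POP2_ONLY": 0}
        assert merged.entries[0].span == (100, 200)

    def test_disjoint_entries_keep_single_support(self):
        l1 = CorrectionLedger([self._entry(100, 200)])
        l2 = CorrectionLedger([self._entry(300, 400, support=Support.POP2_ONLY)])
        merged = merge_support(l1, l2)
        assert merged.support_counts() == {"BOTH": 0, "POP1_ONLY": 1, "POP2_ONLY": 1}

    def test_actions_must_agree_to_merge(self):
        l1 = CorrectionLedger([self._entry(100, 200, Action.REORIENT)])
        l2 = CorrectionLedger([self._entry(150, 250, Action.MOVE, support=Support.POP2_ONLY)])
        # MOVE needs a target distinct from the chromosome
        l2.entries[0].target = "Gm09"
        merged = merge_support(l1, l2)
        assert merged.support_counts()["BOTH"] == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_overlaps_match_interval_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed)

        def ledger(support):
            entries, cursor = [], 0
            for _ in range(rng.integers(1, 6)):
                lo = cursor + int(rng.integers(1, 500))
                hi = lo + int(rng.integers(1, 500))
                cursor = hi + 1
                entries.append(self._entry(lo, hi, support=support))
            return CorrectionLedger(entries)

        l1, l2 = ledger(Support.POP1_ONLY), ledger(Support.POP2_ONLY)
        merged = merge_support(l1, l2)
        expect_both = sum(
            1 for a in l1.entries
            if any(a.overlaps(b) for b in l2.entries)
        )
        assert merged.support_counts()["BOTH"] == expect_both
        for e in merged.entries:
            if e.support == Support.BOTH:
                a = next(x for x in l1.entries if x.overlaps(e))
                b = next(x for x in l2.entries if x.overlaps(e))
                assert e.span == (max(a.span[0], b.span[0]), min(a.span[1], b.span[1]))


class TestApply:
    def test_empty_ledger_is_identity(self):
        placement = _placement([("m1", "c1", 10), ("m2", "c1", 20)])
        out, pieces = apply_corrections(placement, CorrectionLedger([]))
        assert out.records[["marker_id", "chromosome", "position"]].equals(
            placement.records[["marker_id", "chromosome", "position"]])
        assert len(pieces) == 1  # one identity piece per chromosome

    def test_reorient_reflects_span_and_leaves_flanks(self):
        placement = _placement([(f"m{i}", "c1", 100 * (i + 1)) for i in range(5)])
        entry = CorrectionEntry("c1", "m1", "m3", (200, 400), Action.REORIENT)
        out, _ = apply_corrections(placement, CorrectionLedger([entry]))
        pos = dict(out.records[["marker_id", "position"]].itertuples(index=False, name=None))
        assert pos == {"m0": 100, "m1": 400, "m2": 300, "m3": 200, "m4": 500}

    def test_move_without_destination_appends_to_target_end(self):
        placement = _placement([("a", "c1", 100), ("b", "c1", 200), ("x", "c2", 50)])
        entry = CorrectionEntry("c1", "a", "b", (100, 200), Action.MOVE, target="c2")
        out, _ = apply_corrections(placement, CorrectionLedger([entry]))
        rec = out.records.set_index("marker_id")
        assert (rec.loc["a", "chromosome"], rec.loc["b", "chromosome"]) == ("c2", "c2")
        assert rec.loc["a", "position"] > rec.loc["x", "position"]
        assert rec.loc["b", "position"] - rec.loc["a", "position"] == 100

    def test_overlapping_entries_rejected_before_mutation(self):
        placement = _placement([(f"m{i}", "c1", 100 * (i + 1)) for i in range(5)])
        ledger = CorrectionLedger([
            CorrectionEntry("c1", "m0", "m2", (100, 300), Action.REORIENT,
                            support=Support.POP1_ONLY),
            CorrectionEntry("c1", "m1", "m3", (200, 400), Action.REORIENT,
                            support=Support.POP2_ONLY),
        ])
        with pytest.raises(MapforgeError, match="conflicting"):
            apply_corrections(placement, ledger)

    def test_corrupt_detect_apply_restores_truth_up_to_move_positions(
            self, small_truth, small_truth_map):
        ledger = detect_corrections(small_truth_map, small_truth.corrupted_assembly)
        corrected, _ = apply_corrections(small_truth.corrupted_assembly, ledger)
        corrected = reattach_scaffolds(corrected, small_truth.detached_scaffolds,
                                       small_truth.detached_truth)
        a = small_truth.true_assembly.records.set_index("marker_id")
        b = corrected.records.set_index("marker_id")
        moved = set()
        for e in small_truth.planted_errors.entries:
            if e.action in (Action.MOVE, Action.MOVE_AND_REORIENT):
                t = small_truth.corrupted_assembly.records
                sel = t[(t.chromosome == e.chromosome) & t.position.between(*e.span)]
                moved |= set(sel.marker_id)
        assert set(a.index) == set(b.index)
        # every marker lands on its true chromosome
        assert (a["chromosome"] == b.loc[a.index, "chromosome"]).all()
        # non-moved markers recover their exact positions
        fixed = [m for m in a.index if m not in moved]
        assert (a.loc[fixed, "position"] == b.loc[fixed, "position"]).all()
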