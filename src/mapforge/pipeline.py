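"""End-to-end orchestration: simulate two RIL populations over a model
genome, QC and bin their genotypes, build both linkage maps, reconcile them
with a corrupted assembly, anchor detached scaffolds and delimit
heterochromatin — writing every intermediate artifact plus a run manifest
with seeds, parameters and output digests."""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import data_io
from .assembly_concordance import (
    apply_corrections,
    assign_groups_to_chromosomes,
    detect_corrections,
    merge_support,
)
from .chromatin_partition import partition_genome, summarize_partition
from .genotype_qc import run_qc
from .linkage_map import build_map
from .marker_binning import bin_markers, expand_bins, representatives_matrix
from .model import Support
from .scaffold_anchoring import anchor_scaffolds
from .synthetic_data import (
    corrupt_assembly,
    default_genome,
    genome_placement,
    simulate_population,
    true_partition,
)

DEFAULT_CONFIG = {
    # model genome (desk-scale mimic of a 20-chromosome 1-Gb genome)
    "n_chromosomes": 5,
    "markers_per_chromosome": 500,
    # the two emulated mapping populations (F5-derived RIL counts)
    "n_lines_pop1": 1083,
    "n_lines_pop2": 922,
    "selfing_generations": 4,
    "error_rate": 0.002,
    "missing_rate": 0.03,
    # planted assembly errors
    "n_inversions": 8,
    "n_translocations": 4,
    "n_detached_scaffolds": 10,
    # analysis parameters
    "max_missing": 0.10,
    "alpha": 0.01,
    "lod_threshold": 11.0,
}


@dataclass
class RunManifest:
    seed: int
    config: dict
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "config": self.config, "stages": self.stages,
             "outputs": self.outputs},
            indent=2,
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(out_dir: str | Path, seed: int = 1, config: dict | None = None) -> RunManifest:
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, config=cfg)

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            manifest.stages.append(
                {"stage": name, "seconds": round(time.perf_counter() - t0, 3), **info}
            )

        return done

    def save(path: Path):
        manifest.outputs[str(path.relative_to(out))] = _digest(path)

    # 1. simulate
    done = stage("simulate")
    genome = default_genome(cfg["n_chromosomes"], cfg["markers_per_chromosome"])
    truth = corrupt_assembly(
        genome_placement(genome),
        n_inversions=cfg["n_inversions"],
        n_translocations=cfg["n_translocations"],
        n_detached_scaffolds=cfg["n_detached_scaffolds"],
        seed=seed,
        partition=true_partition(genome),
    )
    pops = {}
    for i, key in enumerate(("pop1", "pop2"), start=1):
        pops[key] = simulate_population(
            genome,
            cfg[f"n_lines_{key}"],
            selfing_generations=cfg["selfing_generations"],
            error_rate=cfg["error_rate"],
            missing_rate=cfg["missing_rate"],
            seed=seed + i,
            population_id=key.upper(),
        )
        data_io.write_genotypes(pops[key], out / f"genotypes_{key}.csv")
        save(out / f"genotypes_{key}.csv")
    data_io.write_placement(truth.corrupted_assembly, out / "placement_corrupted.tsv")
    data_io.write_scaffolds(truth.detached_scaffolds, out / "scaffolds.tsv")
    save(out / "placement_corrupted.tsv")
    save(out / "scaffolds.tsv")
    done(n_markers=genome.n_markers(), planted_errors=len(truth.planted_errors))

    # 2-4. qc, bin, map per population
    maps = {}
    assignments = {}
    for key, g in pops.items():
        done = stage(f"qc_{key}")
        filtered, report = run_qc(g, cfg["max_missing"], cfg["alpha"])
        done(markers_in=report.n_input_markers,
             markers_removed=int(report.per_marker["removed"].sum()),
             lines_removed=report.n_lines_removed_missing)

        done = stage(f"bin_{key}")
        bins = bin_markers(filtered)
        reps = representatives_matrix(filtered, bins)
        done(n_bins=len(bins.bins))

        done = stage(f"map_{key}")
        lm = build_map(reps, cfg["lod_threshold"], placement=truth.corrupted_assembly)
        lm = expand_bins(lm, bins)
        maps[key] = lm
        assignments[key] = assign_groups_to_chromosomes(lm, truth.corrupted_assembly)
        path = out / f"map_{key}.tsv"
        with open(path, "w") as fh:
            fh.write("group\tmarker\tcM\n")
            for grp in lm.groups:
                for m, cm in grp.loci:
                    fh.write(f"{grp.group_id}\t{m}\t{cm:.3f}\n")
        save(path)
        done(n_groups=len(lm.groups), total_cm=round(lm.total_length_cm, 1))

    # 5. concordance
    done = stage("concord")
    l1 = detect_corrections(maps["pop1"], truth.corrupted_assembly,
                            assignment=assignments["pop1"], support=Support.POP1_ONLY)
    l2 = detect_corrections(maps["pop2"], truth.corrupted_assembly,
                            assignment=assignments["pop2"], support=Support.POP2_ONLY)
    ledger = merge_support(l1, l2)
    corrected, agp = apply_corrections(
        truth.corrupted_assembly,
        type(ledger)([e for e in ledger.entries if e.support == Support.BOTH]),
    )
    data_io.write_placement(corrected, out / "placement_corrected.tsv")
    data_io.write_agp(agp, out / "corrected.agp")
    ledger_path = out / "ledger.tsv"
    with open(ledger_path, "w") as fh:
        fh.write("chromosome\tfirst_marker\tlast_marker\tstart\tend\taction\ttarget\tsupport\n")
        for e in ledger.entries:
            fh.write(
                f"{e.chromosome}\t{e.first_marker}\t{e.last_marker}\t{e.span[0]}\t"
                f"{e.span[1]}\t{e.action.value}\t{e.target or '.'}\t{e.support.value}\n"
            )
    for p in ("placement_corrected.tsv", "corrected.agp", "ledger.tsv"):
        save(out / p)
    planted = {(e.chromosome, e.span, e.action) for e in truth.planted_errors.entries}
    detected = {(e.chromosome, e.span, e.action) for e in ledger.entries}
    done(entries=len(ledger), support=ledger.support_counts(),
         planted_recovered=len(planted & detected), planted_total=len(planted))

    # 6. anchoring
    done = stage("anchor")
    anchors, summary = anchor_scaffolds(
        truth.detached_scaffolds,
        [maps["pop1"], maps["pop2"]],
        [assignments["pop1"].assignment, assignments["pop2"].assignment],
    )
    path = out / "anchors.tsv"
    with open(path, "w") as fh:
        fh.write("scaffold_id\tlength\tchromosome\torientation\tstatus\tcm_positions\n")
        for a in anchors:
            cms = ";".join(f"{p}:{c:.3f}" for p, c in sorted(a.cm_position.items()))
            fh.write(f"{a.scaffold_id}\t{a.length}\t{a.chromosome or '.'}\t"
                     f"{a.orientation}\t{a.status}\t{cms or '.'}\n")
    save(path)
    done(anchored=summary.n_anchored, total_length=summary.total_anchored_length)

    # 7. chromatin
    done = stage("chromatin")
    lengths = {c.name: c.physical_length for c in genome.chromosomes}
    partition = partition_genome(maps["pop1"], corrected, lengths)
    totals = summarize_partition(partition, lengths)
    data_io.write_bed(partition, out / "partition.bed")
    save(out / "partition.bed")
    done(het_mb=totals.het_mb, euch_mb=totals.euch_mb,
         het_pct=totals.het_pct, euch_pct=totals.euch_pct)

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
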