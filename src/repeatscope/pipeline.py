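"""End-to-end orchestration: simulate -> split/assemble -> merge ->
map -> calibrate -> classify -> annotate -> families -> composition ->
LTR ratios.

``run_all`` executes the full repeat-characterization procedure on a
simulated genome and returns every intermediate product plus the report
tables; with an output directory it also writes the tables as TSV, the
sequence sets as FASTA/FASTQ and a reproducibility manifest (config
snapshot, derived seeds, output checksums). All stage seeds derive from
one global seed, so a rerun with the same config reproduces identical
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as rio
from .align import ScoreScheme
from .assembly import (
    AssemblyParams,
    MergeParams,
    assembly_stats,
    greedy_assemble,
    merge_contig_sets,
    split_reads,
)
from .classify import (
    all_by_all_best_hits,
    annotate_contigs,
    build_families,
    calibrate_threshold,
    classify_contigs,
    detect_tandem_low_complexity,
    exclude_contaminated,
)
from .composition import (
    LTRElementModel,
    composition_by_class,
    ltr_inter_ltr_ratio,
    ratio_means,
    solo_ltr_recovery,
)
from .core import DNA_TRANSPOSON_LABELS, RETRO_LABELS
from .mapping import MappingParams, average_coverage, filter_organellar, map_reads
from .simulate import (
    ReadProfile,
    RepeatFamilySpec,
    SimulationConfig,
    TandemSpec,
    build_repeat_library,
    plant_genome,
    simulate_reads,
)

logger = logging.getLogger("repeatscope")


@dataclass
class ReadPackage:
    """One read set destined for split + unsplit assembly."""

    profile: ReadProfile
    coverage: float
    split_target_coverage: float


@dataclass
class PipelineConfig:
    sim: SimulationConfig
    read_packages: list
    mapping_profile: ReadProfile
    mapping_coverage: float = 4.0
    assembly_params: AssemblyParams = field(default_factory=AssemblyParams)
    merge_params: MergeParams = field(default_factory=MergeParams)
    mapping_params: MappingParams = field(default_factory=MappingParams)
    scheme: ScoreScheme = field(default_factory=ScoreScheme)
    threshold_multiplier: float = 5.0
    annotation_e_cutoff: float = 1e-10
    family_e_cutoff: float = 1e-50
    n_reference_genes: int = 5
    seed: int = 0
    out_dir: str | None = None


@dataclass
class PipelineResult:
    truth: object
    library: dict
    reads_by_package: list
    contig_sets: dict  # (package, "split"/"unsplit") -> contigs
    wgsas: list
    coverage_report: object
    threshold: object
    repeated_ids: list
    low_copy_ids: list
    annotations: dict
    families: list
    singletons: list
    composition: object
    ltr_records: list
    ltr_group_means: dict
    ltr_overall_mean: float | None
    solo_recovery: list
    table1_rows: list
    census: dict
    manifest: dict
    placements: list = None


def default_simulation(seed: int, genome_length: int = 1_000_000) -> SimulationConfig:
    """The standard simulated study: a genome dominated by LTR
    retrotransposons (with solo-LTRs), plus DNA transposons, tandem
    arrays, rDNA-like repeats, single-copy genes and an organellar pool.

    Family copy numbers scale linearly with genome length so the class
    proportions stay fixed."""
    s = genome_length / 1_000_000
    def n(x):
        return max(1, int(round(x * s)))

    families = [
        RepeatFamilySpec("gypsy1", "LTR-Gypsy", full_copies=n(50), ltr_length=300,
                         internal_length=2400, solo_ltr_copies=0, divergence=0.015),
        RepeatFamilySpec("gypsy2", "LTR-Gypsy", full_copies=n(20), ltr_length=300,
                         internal_length=3500, solo_ltr_copies=n(20), divergence=0.015),
        RepeatFamilySpec("copia1", "LTR-Copia", full_copies=n(25), ltr_length=250,
                         internal_length=3000, solo_ltr_copies=n(10), divergence=0.015),
        RepeatFamilySpec("copia2", "LTR-Copia", full_copies=n(15), ltr_length=200,
                         internal_length=2500, solo_ltr_copies=n(45), divergence=0.015),
        RepeatFamilySpec("cacta1", "CACTA", full_copies=n(25), element_length=3000,
                         divergence=0.015),
        RepeatFamilySpec("mite1", "MITE", full_copies=n(100), element_length=400,
                         divergence=0.015),
        RepeatFamilySpec("rdna1", "rDNA", full_copies=n(8), element_length=9000,
                         divergence=0.01),
    ]
    return SimulationConfig(
        genome_length=genome_length,
        seed=seed,
        families=families,
        gene_count=n(20),
        gene_length=2000,
        tandem_specs=[TandemSpec(unit_length=180, unit_count=30, array_copies=n(10))],
        organellar_length=30_000,
        organellar_read_fraction=0.05,
    )


def default_config(seed: int, genome_length: int = 1_000_000,
                   out_dir: str | None = None) -> PipelineConfig:
    illumina = ReadProfile("illumina", length=101, substitution_rate=0.005,
                           indel_rate=0.001)
    # family copy numbers scale with genome length; scale the subpackage
    # coverage inversely so each family keeps the same per-subpackage depth
    split_cov = 0.15 * (1_000_000 / genome_length)
    return PipelineConfig(
        sim=default_simulation(seed, genome_length),
        read_packages=[ReadPackage(illumina, coverage=1.0, split_target_coverage=split_cov)],
        mapping_profile=illumina,
        mapping_coverage=4.0,
        seed=seed,
    )


def contig_true_family(contig, truth, reads_by_id) -> str | None:
    """Dominant planted family among a contig's member reads, resolved
    from the reads' true origin intervals (majority vote of midpoints)."""
    starts = np.array([inst.start for inst in truth.instances])
    ends = np.array([inst.end for inst in truth.instances])
    votes: dict = {}
    for rid in contig.member_read_ids:
        read = reads_by_id.get(rid)
        if read is None or read.origin is None or read.origin[0] != "nuclear":
            continue
        mid = (read.origin[1] + read.origin[2]) // 2
        idx = np.searchsorted(starts, mid, side="right") - 1
        fam = None
        if idx >= 0 and mid < ends[idx]:
            fam = truth.instances[idx].family_id
        votes[fam] = votes.get(fam, 0) + 1
    if not votes:
        return None
    return sorted(votes.items(), key=lambda kv: (-kv[1], str(kv[0])))[0][0]


def _annotation_library(library: dict, config: PipelineConfig, truth) -> list:
    """Labeled library for annotation: canonical elements plus one tandem
    array exemplar per tandem spec and one exemplar gene per planted gene."""
    by_family = {f.family_id: f for f in config.sim.families}
    entries = [(fid, by_family[fid].class_label, seq) for fid, seq in library.items()]
    for t_idx, _spec in enumerate(config.sim.tandem_specs):
        # the planted array sequence is recoverable from the truth intervals
        inst = next(i for i in truth.instances if i.family_id == f"tandem_{t_idx}")
        entries.append(
            (f"tandem_{t_idx}", "tandem/SSR", truth.genome_sequence[inst.start : inst.end])
        )
    for inst in truth.instances:
        if inst.kind == "gene":
            entries.append(
                (inst.family_id, "gene", truth.genome_sequence[inst.start : inst.end])
            )
    return entries


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; see the module docstring for the stage
    order. Raises with the failing stage named; partial outputs written so
    far are retained."""
    stage = "setup"
    try:
        rng = np.random.default_rng(config.seed)
        stage_seeds = rng.integers(0, 2**31 - 1, size=16)
        out_dir = Path(config.out_dir) if config.out_dir else None
        if out_dir:
            out_dir.mkdir(parents=True, exist_ok=True)

        stage = "simulate"
        logger.info("[simulate] building genome (%d nt)", config.sim.genome_length)
        library = build_repeat_library(config.sim)
        truth = plant_genome(library, config.sim)
        organellar_db = [("organellar_0", truth.organellar_sequence)] if truth.organellar_sequence else []
        if out_dir:
            rio.write_fasta(out_dir / "genome.fasta", [("genome", truth.genome_sequence)])
            by_family = {f.family_id: f for f in config.sim.families}
            rio.write_fasta(
                out_dir / "library.fasta",
                [(f"{fid}|class={by_family[fid].class_label}", seq) for fid, seq in library.items()],
            )
            rio.write_truth_tsv(out_dir / "truth.tsv", truth)

        stage = "assemble"
        reads_by_package = []
        contig_sets: dict = {}
        merged_per_package = []
        table1_rows = []
        for p_idx, package in enumerate(config.read_packages):
            reads = simulate_reads(
                truth, package.profile, package.coverage,
                int(stage_seeds[p_idx]), name_prefix=f"p{p_idx}",
            )
            reads_by_package.append(reads)
            logger.info("[assemble] package %d: %d reads", p_idx, len(reads))
            unsplit_raw = greedy_assemble(reads, config.assembly_params,
                                          contig_prefix=f"p{p_idx}_unsplit")
            # second-pass merge within the set (the Minimus2 step)
            sup_u, sing_u = merge_contig_sets([unsplit_raw], config.merge_params,
                                              prefix=f"p{p_idx}_unsplitM")
            unsplit = sup_u + sing_u
            plan = split_reads(reads, config.sim.genome_length,
                               package.split_target_coverage, int(stage_seeds[p_idx + 4]))
            split_raw = []
            for s_idx, sub in enumerate(plan.subpackages(reads)):
                split_raw.append(
                    greedy_assemble(sub, config.assembly_params,
                                    contig_prefix=f"p{p_idx}_split{s_idx}")
                )
            # merge the subpackage assemblies into one deduplicated split set
            sup_s, sing_s = merge_contig_sets(split_raw, config.merge_params,
                                              prefix=f"p{p_idx}_splitM")
            split_contigs = sup_s + sing_s
            stage = "organellar-exclusion"
            if organellar_db:
                unsplit, excl_u = exclude_contaminated(unsplit, organellar_db, config.scheme)
                split_contigs, excl_s = exclude_contaminated(split_contigs, organellar_db, config.scheme)
                logger.info("[organellar-exclusion] dropped %d unsplit / %d split contigs",
                            len(excl_u), len(excl_s))
            else:
                logger.warning("[organellar-exclusion] no organellar db; stage skipped")
            contig_sets[(p_idx, "unsplit")] = unsplit
            contig_sets[(p_idx, "split")] = split_contigs
            stage = "merge"
            supers, singles = merge_contig_sets(
                [unsplit, split_contigs], config.merge_params, prefix=f"p{p_idx}_pair"
            )
            merged_per_package.append(supers + singles)
            for label, n_sub, cov, cset in (
                ("unsplit", 1, package.coverage, unsplit),
                ("split", plan.n_subpackages, plan.target_subpackage_coverage, split_contigs),
            ):
                count, mean_len, n50 = assembly_stats(cset)
                table1_rows.append(
                    {"package": p_idx, "set": label, "n_subpackages": n_sub,
                     "subpackage_coverage": cov, "n_contigs": count,
                     "mean_length": mean_len, "n50": n50, "mean_average_coverage": None}
                )

        stage = "merge-global"
        wgsas_supers, wgsas_singles = merge_contig_sets(
            merged_per_package, config.merge_params, prefix="wgsas"
        )
        wgsas = wgsas_supers + wgsas_singles
        logger.info("[merge-global] WGSAS: %d sequences (%d supercontigs)",
                    len(wgsas), len(wgsas_supers))
        if out_dir:
            rio.write_fasta(out_dir / "wgsas.fasta", wgsas)

        stage = "map"
        map_reads_set = simulate_reads(
            truth, config.mapping_profile, config.mapping_coverage,
            int(stage_seeds[8]), name_prefix="m",
        )
        total_reads = len(map_reads_set)
        if organellar_db:
            nuclear_reads, organellar_count = filter_organellar(
                map_reads_set, organellar_db, config.mapping_params
            )
        else:
            nuclear_reads, organellar_count = list(map_reads_set), 0
        logger.info("[map] %d reads (%d organellar filtered)", total_reads, organellar_count)
        gene_refs = [
            (inst.family_id, truth.genome_sequence[inst.start : inst.end])
            for inst in truth.instances if inst.kind == "gene"
        ][: config.n_reference_genes]
        refs = wgsas + gene_refs
        placements = map_reads(nuclear_reads, refs, config.mapping_params)
        report = average_coverage(placements, refs)

        # per-set mean average coverage for the split-enrichment comparison
        for row in table1_rows:
            cset = contig_sets[(row["package"], row["set"])]
            if not cset:
                row["mean_average_coverage"] = 0.0
                continue
            set_placements = map_reads(nuclear_reads, cset, config.mapping_params)
            set_report = average_coverage(set_placements, cset)
            covs = [set_report.average_coverage(c.contig_id) for c in cset]
            row["mean_average_coverage"] = float(np.mean(covs))

        stage = "calibrate"
        threshold = calibrate_threshold(
            report, [g[0] for g in gene_refs], config.threshold_multiplier
        )
        logger.info("[calibrate] threshold %.2f (mean gene coverage %.2f)",
                    threshold.value, threshold.mean_reference_coverage)

        stage = "classify"
        gene_ids = {g[0] for g in gene_refs}
        repeated_ids, low_copy_ids = classify_contigs(report, threshold)
        repeated_contig_ids = [r for r in repeated_ids if r not in gene_ids]
        low_copy_contig_ids = [r for r in low_copy_ids if r not in gene_ids]

        stage = "annotate"
        ann_library = _annotation_library(library, config, truth)
        wgsas_by_id = {c.contig_id: c for c in wgsas}
        repeated_contigs = [wgsas_by_id[cid] for cid in repeated_contig_ids]
        records = annotate_contigs(repeated_contigs, ann_library, config.scheme,
                                   config.annotation_e_cutoff)
        annotations = {}
        for rec in records:
            if rec.class_label == "no-hit":
                tandem = detect_tandem_low_complexity(wgsas_by_id[rec.contig_id].sequence)
                if tandem is not None:
                    rec = dataclasses.replace(rec, class_label="tandem/SSR")
            annotations[rec.contig_id] = rec
        census: dict = {}
        for rec in annotations.values():
            census[rec.class_label] = census.get(rec.class_label, 0) + 1

        stage = "families"
        te_labels = RETRO_LABELS | DNA_TRANSPOSON_LABELS
        te_contigs = [wgsas_by_id[cid] for cid, rec in annotations.items()
                      if rec.class_label in te_labels]
        if len(te_contigs) >= 2:
            edges = all_by_all_best_hits(te_contigs, config.scheme, config.family_e_cutoff)
            families, singletons = build_families(edges, [c.contig_id for c in te_contigs])
        else:
            families, singletons = [], [c.contig_id for c in te_contigs]

        stage = "composition"
        composition = composition_by_class(
            [p for p in placements if p.ref_id not in gene_ids],
            repeated_contig_ids, annotations,
            total_nuclear=len(nuclear_reads), organellar=organellar_count,
        )

        stage = "ltr-ratio"
        ltr_specs = [f for f in config.sim.families if f.is_ltr]
        ltr_refs = [(f.family_id, library[f.family_id]) for f in ltr_specs]
        ltr_records = []
        if ltr_refs:
            ltr_placements = map_reads(nuclear_reads, ltr_refs, config.mapping_params)
            for spec in ltr_specs:
                model = LTRElementModel.from_family_spec(spec)
                ltr_records.append(
                    ltr_inter_ltr_ratio(model, ltr_placements, len(library[spec.family_id]))
                )
        group_means, overall_mean = ratio_means(ltr_records)
        recovery = solo_ltr_recovery(ltr_specs, ltr_records)

        stage = "report"
        manifest = _build_manifest(config, stage_seeds)
        result = PipelineResult(
            truth=truth, library=library, reads_by_package=reads_by_package,
            contig_sets=contig_sets, wgsas=wgsas, coverage_report=report,
            threshold=threshold, repeated_ids=repeated_contig_ids,
            low_copy_ids=low_copy_contig_ids, annotations=annotations,
            families=families, singletons=singletons, composition=composition,
            ltr_records=ltr_records, ltr_group_means=group_means,
            ltr_overall_mean=overall_mean, solo_recovery=recovery,
            table1_rows=table1_rows, census=census, manifest=manifest,
            placements=placements,
        )
        if out_dir:
            _write_reports(out_dir, result)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _build_manifest(config: PipelineConfig, stage_seeds) -> dict:
    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [plain(x) for x in obj]
        if isinstance(obj, dict):
            return {str(k): plain(v) for k, v in obj.items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, Path):
            return str(obj)
        return obj

    snapshot = {
        "tool": "repeatscope",
        "seed": config.seed,
        "stage_seeds": [int(s) for s in stage_seeds],
        "config": {
            "sim": plain(config.sim),
            "read_packages": plain(config.read_packages),
            "mapping_profile": plain(config.mapping_profile),
            "mapping_coverage": config.mapping_coverage,
            "assembly_params": plain(config.assembly_params),
            "merge_params": plain(config.merge_params),
            "mapping_params": plain(config.mapping_params),
            "threshold_multiplier": config.threshold_multiplier,
            "annotation_e_cutoff": config.annotation_e_cutoff,
            "family_e_cutoff": config.family_e_cutoff,
        },
        "checksums": {},
    }
    return snapshot


def _write_reports(out_dir: Path, result: PipelineResult) -> None:
    rio.write_table_tsv(
        out_dir / "assembly_stats.tsv",
        ["package", "set", "n_subpackages", "subpackage_coverage", "n_contigs",
         "mean_length", "n50", "mean_average_coverage"],
        [[r["package"], r["set"], r["n_subpackages"], r["subpackage_coverage"],
          r["n_contigs"], f"{r['mean_length']:.1f}", r["n50"],
          "" if r["mean_average_coverage"] is None else f"{r['mean_average_coverage']:.1f}"]
         for r in result.table1_rows],
        comment="contig set statistics per read package and splitting strategy",
    )
    rio.write_table_tsv(
        out_dir / "census.tsv", ["class_label", "n_contigs"],
        sorted(result.census.items()),
        comment="repeated-contig census by annotation class",
    )
    comp = result.composition
    rows = [[r.class_label, r.matched_read_count, f"{r.pct_total_nuclear:.2f}",
             f"{r.pct_matched:.2f}"] for r in comp.rows]
    rows.append(["Total matched", comp.matched_total,
                 f"{100.0 * comp.matched_total / comp.total_nuclear:.2f}", "100.00"])
    rows.append(["Not matched", comp.unmatched,
                 f"{100.0 * comp.unmatched / comp.total_nuclear:.2f}", ""])
    rows.append(["Total nuclear", comp.total_nuclear, "100.00", ""])
    rows.append(["Organellar", comp.organellar, "", ""])
    rio.write_table_tsv(
        out_dir / "composition.tsv",
        ["sequence_type", "n_reads", "pct_total_nuclear", "pct_matched"],
        rows, comment="genome composition from read mapping",
    )
    rio.write_table_tsv(
        out_dir / "ltr_ratios.tsv",
        ["element_id", "superfamily", "ltr_avg_cov", "internal_avg_cov", "ratio",
         "solo_ltr_flag"],
        [[r.element_id, r.superfamily, f"{r.ltr_avg_cov:.2f}", f"{r.internal_avg_cov:.2f}",
          f"{r.ratio:.2f}", r.solo_ltr_flag] for r in result.ltr_records],
        comment="LTR vs inter-LTR average coverage per element",
    )
    rio.write_table_tsv(
        out_dir / "families.tsv", ["family_id", "size", "members"],
        [[fam[0], len(fam), ",".join(fam)] for fam in result.families],
        comment="repeat families from all-by-all best-hit clustering",
    )
    rio.write_table_tsv(
        out_dir / "annotations.tsv",
        ["contig_id", "hit_id", "class_label", "match_length", "e_value", "identity"],
        [[rec.contig_id, rec.hit_id or "", rec.class_label, rec.match_length,
          f"{rec.e_value:.3g}", f"{rec.identity:.3f}"]
         for rec in result.annotations.values()],
        comment="repeated-contig annotations (longest significant match)",
    )
    rio.write_table_tsv(
        out_dir / "solo_ltr_recovery.tsv",
        ["family_id", "expected_ratio", "observed_ratio", "abs_error"],
        [[fid, f"{exp:.3f}", f"{obs:.3f}", f"{err:.3f}"]
         for fid, exp, obs, err in result.solo_recovery],
        comment="observed vs expected LTR/inter-LTR ratios per planted family",
    )
    manifest = result.manifest
    for name in sorted(p.name for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json"):
        digest = hashlib.sha256((out_dir / name).read_bytes()).hexdigest()
        manifest["checksums"][name] = digest
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
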