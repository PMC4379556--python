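"""End-to-end orchestration: family -> reads -> alignment -> all analyses.

``run_pipeline`` executes simulate-family, simulate-reads, trim, align,
quantify (all modes), mappability, annotate, mechanism, packaging comparison
and LTR phylogeny, writing plain TSV/FASTA/SAM intermediates plus a manifest
(inputs, seeds, per-stage row counts, every output file).  All stages are
seeded from the config, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .aligner import AlignParams, align_pairs, build_index, write_sam
from .annotate import (
    allocate_orf_abundance,
    classify_catalogue_types,
    find_orfs,
    scan_promoter_motifs,
)
from .catalogue import extract_ltr, write_catalogue
from .enrichment import compare_profiles, comparisons_frame
from .mappability import assess_mappability
from .mechanism import Thresholds, build_coverage, classify_all, write_bedgraph
from .phylo import bootstrap_support, p_distance
from .quant import (
    collect_location_classes,
    compare_modes,
    compute_expression,
    count_fragments,
    target_lengths,
)
from .readsim import (
    cell_library,
    read_fastq_pair,
    simulate_library,
    trim_reads,
    virion_library,
    write_fastq_pair,
)
from .synthetic_family import (
    FamilySpec,
    PlanEntry,
    aligned_ltr_fasta,
    build_host_contexts,
    default_sample_plan,
    default_scenarios,
    generate_family,
    make_truth_profile,
)

log = logging.getLogger("hml2kit")

QUANT_MODES = ("unfiltered_uniform", "unique_only", "em_rescue")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the analysis's canonical parameters
    (2-mismatch budget, MAPQ-50 uniqueness, 20X/250 b mappability simulation,
    15% underrepresentation threshold, 0.01% detection floor)."""

    outdir: str = "hml2kit_run"
    seed: int = 0
    # synthetic family + truth
    family: dict = field(default_factory=dict)  # FamilySpec overrides
    plan: dict = field(default_factory=dict)  # element -> PlanEntry fields
    n_fragments_cell: int = 50_000
    n_fragments_virion: int = 50_000
    error_rate: float = 0.005
    # trimming
    qual_threshold: float = 25.0
    min_read_len: int = 100
    adapters: tuple[str, ...] = ()
    # alignment
    max_mm: int = 2
    seed_len: int = 20
    insert_bounds: tuple[int, int] = (50, 700)
    # quant
    modes: tuple[str, ...] = QUANT_MODES
    # mappability
    mappability_depth: float = 20.0
    mappability_read_len: int = 250
    mappability_threshold: float = 0.15
    # enrichment
    floor: float = 0.01
    similar_band: tuple[float, float] = (0.5, 2.0)
    # phylogeny
    bootstrap_replicates: int = 1000
    # mechanism
    mechanism_thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.insert_bounds = tuple(cfg.insert_bounds)
        cfg.similar_band = tuple(cfg.similar_band)
        cfg.adapters = tuple(cfg.adapters)
        cfg.modes = tuple(cfg.modes)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def demo_config(outdir: str, seed: int = 0, **overrides) -> RunConfig:
    """The 12-provirus demonstration run (50k pairs per sample)."""
    cfg = RunConfig(outdir=outdir, seed=seed, bootstrap_replicates=200)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def _write_tsv(df, path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}, "files": []}

    def record(stage: str, path: Path, rows: int | None = None) -> None:
        manifest["files"].append(path.name)
        manifest["stages"].setdefault(stage, {})[path.name] = rows

    # ---------------------------------------------------------------- family
    log.info("[simulate-family] generating catalogue")
    fam_kw = dict(config.family)
    fam_kw.setdefault("seed", config.seed)
    spec = FamilySpec(**fam_kw)
    catalogue, ancestry = generate_family(spec)
    write_catalogue(catalogue, out / "catalogue.fa", out / "catalogue.gtf")
    record("simulate-family", out / "catalogue.fa", len(catalogue))
    record("simulate-family", out / "catalogue.gtf")

    plan = (
        {eid: PlanEntry(**entry) for eid, entry in config.plan.items()}
        if config.plan
        else default_sample_plan()
    )
    plan = {eid: entry for eid, entry in plan.items() if eid in catalogue.elements}
    contexts = build_host_contexts(
        catalogue, default_scenarios(plan), seed=config.seed + 1, ancestry=ancestry
    )
    truth = make_truth_profile(catalogue, contexts, plan)
    truth.write_tsv(out / "truth_profile.tsv")
    record("simulate-family", out / "truth_profile.tsv", len(truth.transcripts))
    augmented, placements = contexts.augmented_catalogue(catalogue)
    write_catalogue(augmented, out / "reference.fa", out / "reference.gtf")
    record("simulate-family", out / "reference.fa", len(augmented))
    record("simulate-family", out / "reference.gtf")

    # ----------------------------------------------------------- simulate-reads
    lib_params = {
        "cell": cell_library(
            n_fragments=config.n_fragments_cell, seed=config.seed + 2,
            error_rate=config.error_rate,
        ),
        "virion": virion_library(
            n_fragments=config.n_fragments_virion, seed=config.seed + 3,
            error_rate=config.error_rate,
        ),
    }
    fastqs: dict[str, tuple[Path, Path]] = {}
    for sample, params in lib_params.items():
        log.info("[simulate-reads] %s library (%d fragments)", sample, params.n_fragments)
        pairs, report = simulate_library(truth, sample, params)
        fq1, fq2 = out / f"{sample}_1.fastq", out / f"{sample}_2.fastq"
        n = write_fastq_pair(pairs, fq1, fq2, out / f"{sample}_truth.tsv")
        record("simulate-reads", fq1, n)
        record("simulate-reads", fq2, n)
        record("simulate-reads", out / f"{sample}_truth.tsv", n)
        fastqs[sample] = (fq1, fq2)

    # ------------------------------------------------------------------- trim
    trimmed: dict[str, tuple[Path, Path]] = {}
    for sample, (fq1, fq2) in fastqs.items():
        t1, t2 = out / f"{sample}_trimmed_1.fastq", out / f"{sample}_trimmed_2.fastq"
        report = trim_reads(
            fq1, fq2, t1, t2,
            qual_threshold=config.qual_threshold,
            min_len=config.min_read_len,
            adapters=config.adapters,
        )
        report.write_tsv(out / f"{sample}_trim_report.tsv")
        log.info("[trim] %s: kept %d/%d pairs", sample, report.kept_pairs, report.input_pairs)
        record("trim", out / f"{sample}_trim_report.tsv", report.kept_pairs)
        record("trim", t1)
        record("trim", t2)
        trimmed[sample] = (t1, t2)

    # ------------------------------------------------------------------ align
    index = build_index(augmented, seed_len=config.seed_len)
    align_params = AlignParams(per_mate_mm=config.max_mm, insert_bounds=config.insert_bounds)
    alignments: dict[str, list] = {}
    for sample, (t1, t2) in trimmed.items():
        log.info("[align] %s", sample)
        sam_path = out / f"{sample}.sam"
        alns = []

        def stream():
            for pair, aln in align_pairs(read_fastq_pair(t1, t2), index, align_params):
                alns.append(aln)
                yield pair, aln

        n = write_sam(stream(), augmented, sam_path)
        alignments[sample] = alns
        record("align", sam_path, n)

    # --------------------------------------------------------------- quantify
    lengths = target_lengths(catalogue, placements)
    expression: dict[tuple[str, str], object] = {}
    strand_modes = {"cell": "plus_stranded", "virion": "unstranded"}
    for sample, alns in alignments.items():
        classes = collect_location_classes(alns, strand_modes[sample], placements)
        by_mode = {}
        for mode in config.modes:
            table = count_fragments(classes, mode, strand_modes[sample], lengths)
            df = compute_expression(table, catalogue, lengths, N=classes.n_pairs)
            expression[(sample, mode)] = df
            by_mode[mode] = df
            rows = _write_tsv(df, out / f"expression_{sample}_{mode}.tsv")
            record("quantify", out / f"expression_{sample}_{mode}.tsv", rows)
        if {"unfiltered_uniform", "unique_only"} <= set(by_mode):
            cmp_df = compare_modes(by_mode)
            rows = _write_tsv(cmp_df, out / f"mode_comparison_{sample}.tsv")
            record("quantify", out / f"mode_comparison_{sample}.tsv", rows)

    # ------------------------------------------------------------ mappability
    log.info("[mappability] simulating %gX coverage", config.mappability_depth)
    mapp = assess_mappability(
        catalogue,
        depth=config.mappability_depth,
        read_len=config.mappability_read_len,
        threshold=config.mappability_threshold,
        seed=config.seed + 4,
        per_mate_mm=config.max_mm,
    )
    record("mappability", out / "mappability.tsv", _write_tsv(mapp, out / "mappability.tsv"))

    # --------------------------------------------------------------- annotate
    orf_calls = []
    orf_rows = []
    motif_rows = []
    for elem in catalogue:
        ann = catalogue.annotations.get(elem.id)
        if elem.elem_class == "provirus" and ann is not None:
            for call in find_orfs(elem, ann):
                orf_calls.append(call)
                orf_rows.append(
                    {
                        "element_id": call.element_id,
                        "gene": call.gene,
                        "orf_start": call.span[0] if call.span else None,
                        "orf_end": call.span[1] if call.span else None,
                        "length_aa": call.length_aa,
                        "status": call.status,
                    }
                )
        if elem.ltr5_span is not None:
            hits, summary = scan_promoter_motifs(extract_ltr(catalogue, elem.id, "5prime"))
            for h in hits:
                motif_rows.append(
                    {
                        "element_id": elem.id,
                        "motif": h.name,
                        "canonical_pos": h.canonical_pos,
                        "found_pos": h.found_pos,
                        "mismatches": h.mismatches,
                        "status": h.status,
                    }
                )
    import pandas as pd

    record("annotate", out / "orfs.tsv", _write_tsv(pd.DataFrame(orf_rows), out / "orfs.tsv"))
    record(
        "annotate", out / "motifs.tsv", _write_tsv(pd.DataFrame(motif_rows), out / "motifs.tsv")
    )
    types = classify_catalogue_types(catalogue, ancestry.boundary_reference())
    record("annotate", out / "types.tsv", _write_tsv(types, out / "types.tsv"))
    cell_unique = expression.get(("cell", "unique_only"))
    if cell_unique is not None:
        alloc = allocate_orf_abundance(cell_unique, orf_calls)
        record(
            "annotate",
            out / "orf_allocation.tsv",
            _write_tsv(alloc, out / "orf_allocation.tsv"),
        )

    # -------------------------------------------------------------- mechanism
    profiles = build_coverage(
        alignments["cell"], augmented, placements, stranded=True, unique_only=True
    )
    thresholds = Thresholds(**config.mechanism_thresholds)
    mech = classify_all(profiles, thresholds)
    record("mechanism", out / "mechanism.tsv", _write_tsv(mech, out / "mechanism.tsv"))
    write_bedgraph(profiles, out / "coverage.bedgraph")
    record("mechanism", out / "coverage.bedgraph")

    # ---------------------------------------------------------------- compare
    cell_expr = expression.get(("cell", "unique_only"))
    virion_expr = expression.get(("virion", "unique_only"))
    if cell_expr is not None and virion_expr is not None:
        comparisons = compare_profiles(
            cell_expr, virion_expr, floor=config.floor, similar_band=config.similar_band
        )
        df = comparisons_frame(comparisons)
        record("compare", out / "packaging_comparison.tsv", _write_tsv(df, out / "packaging_comparison.tsv"))

    # ------------------------------------------------------------------ phylo
    ltrs = aligned_ltr_fasta(catalogue)
    dm = p_distance(ltrs)
    dist_df = dm.to_frame().reset_index().rename(columns={"index": "element_id"})
    record("phylo", out / "ltr_distances.tsv", _write_tsv(dist_df, out / "ltr_distances.tsv"))
    tree = bootstrap_support(
        ltrs, n_replicates=config.bootstrap_replicates, seed=config.seed + 5
    )
    (out / "ltr_tree.nwk").write_text(tree.newick() + "\n")
    record("phylo", out / "ltr_tree.nwk")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("[done] %d output files in %s", len(manifest["files"]), out)
    return manifest
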