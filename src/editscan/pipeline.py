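"""End-to-end analysis: inputs -> pileups -> calling -> filters ->
annotation -> enrichment -> report.

The stage order mirrors the published pipeline overview: strand-resolved
pileups are built per sample and pooled across technical runs; candidate
sites are called per tissue across its biological replicates and unioned;
known SNPs and 100%-ratio fixed differences are removed; the Fisher
strand-bias filter is applied with run-level Bonferroni control; retained
sites are oriented, classified, checked for coding effects and per-gene
artifact clusters; and permutation tests measure feature and microRNA
seed-target enrichment. Every stage's output is serialized and all
randomness derives from the configured seed, so a rerun is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import annotate as ann
from . import enrichment as enr
from . import io as eio
from . import pileup as pu
from . import strand_bias as sb
from .params import PipelineParams
from .simulate import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)

STAGES = ("inputs", "pileup", "call", "filter-snp", "filter-fixed",
          "filter-bias", "annotate", "enrich", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    """Counts and results for every pipeline stage."""

    n_reads: int = 0
    n_samples: int = 0
    n_candidates: int = 0
    n_after_snp_filter: int = 0
    n_after_fixed_filter: int = 0
    n_tested_for_bias: int = 0
    n_strand_biased: int = 0
    n_retained: int = 0
    edit_type_counts_all: dict = field(default_factory=dict)
    edit_type_counts_retained: dict = field(default_factory=dict)
    class_counts_retained: dict = field(default_factory=dict)
    feature_counts: dict = field(default_factory=dict)
    background_feature_counts: dict = field(default_factory=dict)
    feature_enrichment: dict = field(default_factory=dict)
    seed_summary: dict = field(default_factory=dict)
    artifact_genes: list = field(default_factory=list)
    error_motif_fraction: float | None = None

    def validate_cascade(self) -> None:
        counts = [self.n_candidates, self.n_after_snp_filter,
                  self.n_after_fixed_filter, self.n_retained]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"filter cascade counts increased: {counts}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise StageError("inputs", f"config {path} did not parse to a mapping")
    return cfg


def _resolve_inputs(cfg: dict, out_dir: Path) -> dict:
    if "sim" in cfg:
        sim_cfg = SimConfig.from_dict(cfg.get("sim") or {})
        manifest = simulate_dataset(sim_cfg, out_dir / "sim")
        return {
            "genome": manifest["genome_fasta"],
            "genes": manifest["genes_bed"],
            "snps": manifest["snps_vcf"],
            "mirnas": manifest["mirnas_tsv"],
            "alignments": [str(p) for p in manifest["sam_paths"]],
            "truth": manifest["truth_tsv"],
        }
    if "inputs" not in cfg:
        raise StageError("inputs", "config must contain either 'sim' or 'inputs'")
    return dict(cfg["inputs"])


def run_pipeline(config: dict | str | Path, stop_after: str = "report"
                 ) -> tuple[RunReport, list[pu.EditingSiteCandidate]]:
    """Execute the pipeline described by a config mapping or YAML path.

    ``stop_after`` truncates the stage sequence (used by the step-wise
    CLI subcommands). Returns the report and the current site list;
    outputs are written under the configured ``out_dir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    stop_idx = STAGES.index(stop_after)
    out_dir = Path(config.get("out_dir", "editscan_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    params = PipelineParams.from_dict(config.get("params") or {})
    report = RunReport()

    # ---- inputs ----------------------------------------------------------
    try:
        inputs = _resolve_inputs(config, out_dir)
        genome = eio.read_fasta(inputs["genome"])
        models = eio.read_gene_models(inputs["genes"]) if inputs.get("genes") else []
        snps = eio.read_snps(inputs["snps"]) if inputs.get("snps") else set()
        mirnas = eio.read_mirnas(inputs["mirnas"]) if inputs.get("mirnas") else []
        sam_paths = list(inputs.get("alignments") or [])
        sheet = (eio.read_sample_sheet(inputs["sample_sheet"])
                 if inputs.get("sample_sheet") else None)
        if not sam_paths:
            raise StageError("inputs", "no alignment files configured")
    except (OSError, eio.ParseError, ValueError) as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError("inputs", str(exc)) from exc
    logger.info("stage=inputs genome_chroms=%d genes=%d mirnas=%d snps=%d sams=%d",
                len(genome.chroms()), len(models), len(mirnas), len(snps),
                len(sam_paths))
    if stop_idx < STAGES.index("pileup"):
        return report, []

    # ---- pileups (per file, streamed) ------------------------------------
    try:
        run_pileups: dict[tuple[str, str, str], pu.SamplePileup] = {}
        for path in sam_paths:
            reads = eio.read_alignments(path, sample_sheet=sheet)
            report.n_reads += len(reads)
            for key, pile in pu.build_pileups(reads, genome, params).items():
                if key in run_pileups:
                    run_pileups[key].add(pile)
                else:
                    run_pileups[key] = pile
        pooled = pu.pool_technical_replicates(run_pileups)
        combined = pu.SamplePileup.combine(pooled.values(), genome)
        report.n_samples = len(run_pileups)
    except (eio.ParseError, ValueError) as exc:
        raise StageError("pileup", str(exc)) from exc
    logger.info("stage=pileup reads=%d samples=%d pooled=%d",
                report.n_reads, len(run_pileups), len(pooled))
    if stop_idx < STAGES.index("call"):
        return report, []

    # ---- candidate calling per tissue ------------------------------------
    try:
        by_tissue: dict[str, dict[str, pu.SamplePileup]] = {}
        for (tissue, rep), pile in pooled.items():
            by_tissue.setdefault(tissue, {})[rep] = pile
        per_tissue_calls = {
            tissue: pu.call_candidate_sites(reps, genome, params, tissue=tissue)
            for tissue, reps in sorted(by_tissue.items())}
        sites = pu.merge_tissue_calls(per_tissue_calls)
    except ValueError as exc:
        raise StageError("call", str(exc)) from exc
    report.n_candidates = len(sites)
    logger.info("stage=call candidates=%d", len(sites))
    if stop_idx < STAGES.index("filter-snp"):
        return report, sites

    sites = pu.filter_known_snps(sites, snps)
    report.n_after_snp_filter = len(sites)
    logger.info("stage=filter-snp kept=%d", len(sites))
    if stop_idx < STAGES.index("filter-fixed"):
        return report, sites

    sites = pu.filter_fixed_sites(sites, pooled)
    report.n_after_fixed_filter = len(sites)
    logger.info("stage=filter-fixed kept=%d", len(sites))
    if stop_idx < STAGES.index("filter-bias"):
        return report, sites

    # ---- strand-bias filter ----------------------------------------------
    sites = sb.apply_strand_bias_filter(sites, combined, params)
    retained, flagged = sb.split_by_bias(sites)
    report.n_tested_for_bias = sum(1 for s in sites if s.bias_p_raw is not None)
    report.n_strand_biased = len(flagged)
    report.n_retained = len(retained)
    logger.info("stage=filter-bias tested=%d biased=%d retained=%d",
                report.n_tested_for_bias, len(flagged), len(retained))
    if stop_idx < STAGES.index("annotate"):
        _write_outputs(out_dir, sites, retained, report, params, finalize=False)
        return report, retained

    # ---- annotation -------------------------------------------------------
    try:
        index = ann.GeneIndex(models, genome) if models else None
        for s in sites:
            if index is not None:
                ann.orient_edit_type(s, index)
                ann.classify_genomic_feature(s, index)
            else:
                s.gene_from, s.gene_to = s.ref_base, s.alt_base
                s.edit_class = ann.EditType(s.ref_base, s.alt_base).edit_class
                s.strand_context = "intergenic"
                s.feature = "intergenic"
        for s in retained:
            if index is not None and s.feature == "coding":
                ann.annotate_coding_effect(s, index, genome)
            else:
                s.coding_effect = ann.NOT_CODING
        report.artifact_genes = ann.flag_clustered_gene_artifacts(
            retained, params.max_gene_artifact_fraction)
        report.edit_type_counts_all = ann.edit_type_counts(sites)
        report.edit_type_counts_retained = ann.edit_type_counts(retained)
        report.class_counts_retained = _class_counts(retained)
        report.feature_counts = _feature_counts(retained)
        if flagged:
            frac, _ = sb.scan_error_motif(flagged, genome, params.error_motif,
                                          params.motif_window)
            report.error_motif_fraction = frac
    except ValueError as exc:
        raise StageError("annotate", str(exc)) from exc
    logger.info("stage=annotate retained=%d artifact_genes=%s",
                len(retained), report.artifact_genes)
    if stop_idx < STAGES.index("enrich"):
        _write_outputs(out_dir, sites, retained, report, params, finalize=False)
        return report, retained

    # ---- enrichment and microRNA seed analysis ---------------------------
    seed_targets: list[enr.SeedTarget] = []
    try:
        if retained and index is not None:
            bg = enr.sample_background_positions(
                combined, min(params.n_background, _n_eligible(combined, params)),
                params.background_min_coverage, seed=[params.rng_seed, 101])
            report.background_feature_counts = _count_classes(
                [index.classify(c, p) for c, p in bg])
            report.feature_enrichment = _summarize_feature_enrichment(
                enr.feature_enrichment(retained, combined, index, params,
                                       seed=[params.rng_seed, 102]))
        if mirnas and index is not None:
            seed_targets = enr.build_seed_targets(models, genome, mirnas)
        sites_3utr = [s for s in retained if s.feature == "3UTR"]
        if seed_targets and sites_3utr:
            enr.detect_seed_disruption(sites_3utr, seed_targets)
            enr.detect_seed_creation(sites_3utr, index, genome, mirnas)
            seed_res = enr.seed_enrichment(
                sites_3utr, combined, seed_targets, index, genome, mirnas,
                params, seed=[params.rng_seed, 103])
            report.seed_summary = {
                "n_3utr_sites": len(sites_3utr),
                "n_in_target": sum(1 for s in sites_3utr if s.mirna_disrupted),
                "n_creating": sum(1 for s in sites_3utr if s.mirna_created),
                "n_targets": len(seed_targets),
                "disruption": _perm_dict(seed_res["disruption"]),
                "creation": _perm_dict(seed_res["creation"]),
            }
    except ValueError as exc:
        raise StageError("enrich", str(exc)) from exc
    logger.info("stage=enrich seed_targets=%d", len(seed_targets))

    report.validate_cascade()
    _write_outputs(out_dir, sites, retained, report, params, finalize=True,
                   seed_targets=seed_targets)
    return report, retained


# ---------------------------------------------------------------------------
# reporting helpers
# ---------------------------------------------------------------------------

def _n_eligible(pileup: pu.SamplePileup, params: PipelineParams) -> int:
    return sum(pos.size for _c, pos in
               enr.eligible_positions(pileup, params.background_min_coverage))


def _class_counts(sites) -> dict:
    out = {c: 0 for c in (ann.CANONICAL, ann.COMPLEMENTARY, ann.NON_CANONICAL)}
    for s in sites:
        if s.edit_class:
            out[s.edit_class] += 1
    return out


def _feature_counts(sites) -> dict:
    return _count_classes([s.feature for s in sites if s.feature])


def _count_classes(classes) -> dict:
    out = {c: 0 for c in ann.FEATURE_CLASSES}
    for c in classes:
        out[c] += 1
    return out


def _perm_dict(res: enr.PermutationResult) -> dict:
    return {"observed": res.observed, "expected_mean": res.expected_mean,
            "n_permutations": res.n_permutations, "p_value": res.p_value}


def _summarize_feature_enrichment(results: Mapping[str, Mapping[str, enr.PermutationResult]]
                                  ) -> dict:
    out = {}
    for cls, pair in results.items():
        out[cls] = {
            "observed": pair["enrichment"].observed,
            "expected_mean": pair["enrichment"].expected_mean,
            "p_enrichment": pair["enrichment"].p_value,
            "p_depletion": pair["depletion"].p_value,
        }
    return out


def _write_outputs(out_dir: Path, sites, retained, report: RunReport,
                   params: PipelineParams, finalize: bool,
                   seed_targets: Sequence[enr.SeedTarget] = ()) -> None:
    eio.write_site_table(sites, out_dir / "sites_all.tsv")
    eio.write_site_table(retained, out_dir / "sites_retained.tsv")
    if seed_targets:
        with open(out_dir / "seed_targets.bed", "w") as fh:
            for t in seed_targets:
                for s, e in t.genomic_intervals:
                    fh.write(f"{t.chrom}\t{s}\t{e}\t{t.mirna_id}|{t.transcript_id}\n")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "report.txt", "w") as fh:
        d = report.to_dict()
        fh.write("editscan run report\n")
        fh.write("===================\n")
        for key in ("n_reads", "n_samples", "n_candidates", "n_after_snp_filter",
                    "n_after_fixed_filter", "n_tested_for_bias",
                    "n_strand_biased", "n_retained"):
            fh.write(f"{key:24s} {d[key]}\n")
        if report.class_counts_retained:
            fh.write("\nretained sites by editing class:\n")
            for k, v in report.class_counts_retained.items():
                fh.write(f"  {k:24s} {v}\n")
        if report.feature_counts:
            fh.write("\nretained sites by genomic feature (background in brackets):\n")
            for k in ann.FEATURE_CLASSES:
                bg = report.background_feature_counts.get(k, 0)
                fh.write(f"  {k:12s} {report.feature_counts.get(k, 0)} [{bg}]\n")
        if report.feature_enrichment:
            fh.write("\nfeature enrichment (permutation):\n")
            for k, v in report.feature_enrichment.items():
                fh.write(f"  {k:12s} observed={v['observed']} "
                         f"expected={v['expected_mean']:.2f} "
                         f"p_enrich={v['p_enrichment']:.4g} "
                         f"p_deplete={v['p_depletion']:.4g}\n")
        if report.seed_summary:
            ss = report.seed_summary
            fh.write("\nmicroRNA seed-target analysis:\n")
            fh.write(f"  3'UTR sites            {ss['n_3utr_sites']}\n")
            fh.write(f"  in seed targets        {ss['n_in_target']} "
                     f"(p={ss['disruption']['p_value']:.4g})\n")
            fh.write(f"  creating new targets   {ss['n_creating']} "
                     f"(p={ss['creation']['p_value']:.4g})\n")
        if report.artifact_genes:
            fh.write(f"\nsuspect clustered-artifact genes: "
                     f"{', '.join(report.artifact_genes)}\n")
        if report.error_motif_fraction is not None:
            fh.write(f"\nerror-motif ({params.error_motif}) fraction near "
                     f"strand-biased sites: {report.error_motif_fraction:.3f}\n")
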