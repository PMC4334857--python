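"""End-to-end orchestration of the differential-methylation pipeline.

One validated configuration drives every stage in dependency order:

  simulate/load -> binned coverage -> per-sample peaks -> per-case DMRs
  -> ultra-DMR consensus -> feature & band enrichment -> promoter
  pattern calls -> expression integration -> summary report

Every artifact file carries the configuration hash in its header, and a
summary JSON reports the counts per stage.  A fixed seed makes the whole
artifact directory byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import coverage as cov_mod
from . import dmr as dmr_mod
from . import enrichment as enr_mod
from . import expression as expr_mod
from . import patterns as pat_mod
from . import peaks as peaks_mod
from .genome_features import GenomeAnnotation, read_annotation
from .intervals import AlignedReadSet, GenomicInterval, read_bed_reads
from .synthetic_data import SimulationConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

_THRESHOLD_DEFAULTS = dict(
    p_threshold=1e-5,
    q_max=0.05,
    min_fold=2.0,
    segment_bp=500,
    min_overlap_bp=250,
    min_case_support=4,
    flank_bp=2000,
    shore_bp=2000,
    coverage_bin_bp=10_000,
    gsea_n_perm=1000,
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: Optional[dict] = None
    reads: Optional[dict] = None        # {control: path, cases: [paths]}
    annotation: Optional[dict] = None   # {genes, cgis, bands, repeats, chrom_sizes}
    expression_counts: Optional[str] = None
    gene_sets_gmt: Optional[str] = None
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.simulate is None and (self.reads is None or self.annotation is None):
            raise ValueError(
                "config must provide either a 'simulate' block or both "
                "'reads' and 'annotation'"
            )
        unknown = set(self.thresholds) - set(_THRESHOLD_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        merged = dict(_THRESHOLD_DEFAULTS)
        merged.update(self.thresholds)
        self.thresholds = merged

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"outdir", "seed", "simulate", "reads", "annotation",
                 "expression_counts", "gene_sets_gmt", "thresholds"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)  # run location is not analysis configuration
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:12]


def _header(config: PipelineConfig) -> List[str]:
    th = config.thresholds
    return [
        f"config_hash: {config.config_hash()}",
        f"seed: {config.seed}",
    ] + [f"{k}: {th[k]}" for k in sorted(th)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the summary dict (also written as JSON).

    On failure the partial outputs are moved under ``<outdir>/failed/``
    and a :class:`PipelineError` naming the stage is raised.
    """
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    th = config.thresholds
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                     "stages": {}}
    stage = "setup"
    try:
        # ---------------- data
        stage = "data"
        expression_df: Optional[pd.DataFrame] = None
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            sim_config = SimulationConfig(**sim_kwargs)
            ds = simulate_dataset(sim_config)
            write_dataset(ds, os.path.join(outdir, "simulated"))
            annotation = ds.annotation
            control, cases = ds.control, ds.cases
            expression_df = ds.expression
        else:
            ann_paths = config.annotation
            annotation = read_annotation(
                gene_path=ann_paths["genes"],
                cgi_path=ann_paths["cgis"],
                band_path=ann_paths.get("bands"),
                repeat_path=ann_paths.get("repeats"),
                chrom_sizes_path=ann_paths["chrom_sizes"],
                mirna_path=ann_paths.get("mirnas"),
                flank_bp=th["flank_bp"],
                shore_bp=th["shore_bp"],
            )
            control = read_bed_reads(config.reads["control"], "control_1")
            cases = [
                read_bed_reads(p, f"case_{i + 1}")
                for i, p in enumerate(config.reads["cases"])
            ]
        if config.expression_counts:
            expression_df = pd.read_csv(config.expression_counts, sep="\t")
        samples = [control] + cases
        summary["stages"]["data"] = {
            "n_samples": len(samples),
            "urc": {s.sample_id: s.urc for s in samples},
        }

        # ---------------- coverage
        stage = "coverage"
        covdir = os.path.join(outdir, "coverage")
        os.makedirs(covdir, exist_ok=True)
        covs = []
        for s in samples:
            cov = cov_mod.bin_counts(s, th["coverage_bin_bp"],
                                     annotation.chrom_sizes)
            cov_mod.normalize_am(cov)
            cov_mod.write_bedgraph(
                cov, os.path.join(covdir, f"{s.sample_id}.bedgraph"))
            covs.append(cov)
        corr = cov_mod.correlation_matrix(covs)
        ids = [s.sample_id for s in samples]
        pd.DataFrame(corr, index=ids, columns=ids).to_csv(
            os.path.join(covdir, "correlation.tsv"), sep="\t",
            float_format="%.6f",
        )
        summary["stages"]["coverage"] = {
            "bin_size_bp": th["coverage_bin_bp"],
            "min_offdiag_r": float(corr[~pd.isna(corr)].min())
            if corr.size else None,
        }

        # ---------------- peaks
        stage = "peaks"
        peakdir = os.path.join(outdir, "peaks")
        os.makedirs(peakdir, exist_ok=True)
        params = peaks_mod.PeakParams(p_threshold=th["p_threshold"])
        peaks_by_sample: Dict[str, list] = {}
        for s in samples:
            pk = peaks_mod.call_peaks(s, annotation.chrom_sizes, params)
            peaks_by_sample[s.sample_id] = pk
            peaks_mod.write_peaks(
                pk, os.path.join(peakdir, f"{s.sample_id}.peaks.bed"))
        summary["stages"]["peaks"] = {
            s.sample_id: len(peaks_by_sample[s.sample_id]) for s in samples
        }

        # ---------------- DMRs per case
        stage = "dmrs"
        dmrdir = os.path.join(outdir, "dmrs")
        os.makedirs(dmrdir, exist_ok=True)
        dmrs_by_case: Dict[str, list] = {}
        for case in cases:
            candidates = dmr_mod.merge_candidate_regions(
                peaks_by_sample[control.sample_id],
                peaks_by_sample[case.sample_id],
            )
            dmrs = dmr_mod.call_dmrs(candidates, control, case,
                                     q_max=th["q_max"], min_fold=th["min_fold"])
            dmrs_by_case[case.sample_id] = dmrs
            dmr_mod.write_dmrs(
                dmrs, os.path.join(dmrdir, f"{case.sample_id}.dmrs.tsv"),
                header_lines=_header(config),
            )
        summary["stages"]["dmrs"] = {
            cid: {
                "total": len(ds_),
                "hyper": sum(d.direction == "hyper" for d in ds_),
                "hypo": sum(d.direction == "hypo" for d in ds_),
            }
            for cid, ds_ in dmrs_by_case.items()
        }

        # ---------------- ultra DMRs
        stage = "ultra_dmrs"
        ultras = dmr_mod.ultra_dmrs(
            list(dmrs_by_case.values()), annotation.chrom_sizes,
            segment_bp=th["segment_bp"], min_overlap_bp=th["min_overlap_bp"],
        )
        dmr_mod.write_ultra_dmrs(
            ultras, os.path.join(outdir, "ultra_dmrs.tsv"),
            header_lines=_header(config),
        )
        summary["stages"]["ultra_dmrs"] = {
            "total": len(ultras),
            "hyper": sum(u.direction == "hyper" for u in ultras),
            "hypo": sum(u.direction == "hypo" for u in ultras),
        }

        # ---------------- enrichment
        stage = "enrichment"
        enrdir = os.path.join(outdir, "enrichment")
        os.makedirs(enrdir, exist_ok=True)
        ultra_iv = [u.segment for u in ultras]
        feat = enr_mod.enrichment_test(ultra_iv, annotation,
                                       segment_bp=th["segment_bp"])
        enr_mod.write_enrichment(
            feat, os.path.join(enrdir, "features.tsv"),
            header_lines=_header(config))
        bands = enr_mod.band_enrichment(ultra_iv, annotation,
                                        segment_bp=th["segment_bp"])
        enr_mod.write_enrichment(
            bands, os.path.join(enrdir, "bands.tsv"),
            header_lines=_header(config))
        summary["stages"]["enrichment"] = {
            "flagged_features": sorted(
                r.feature_class for r in feat if r.flagged),
            "n_flagged_bands": sum(r.flagged for r in bands),
        }

        # ---------------- promoter patterns
        stage = "patterns"
        all_dmr_iv = [d.interval for case_d in dmrs_by_case.values()
                      for d in case_d]
        dmr_idx_tree = None
        if all_dmr_iv:
            from .intervals import IntervalIndex
            dmr_idx_tree = IntervalIndex.from_intervals(all_dmr_iv)
        covered = [
            p for p in annotation.promoters
            if not p.clipped and dmr_idx_tree is not None
            and dmr_idx_tree.any_overlap(p.interval.chrom, p.interval.start,
                                         p.interval.end)
        ]
        case_masks = {
            case.sample_id: {
                p.gene_id: pat_mod.binarize_promoter(
                    p, peaks_by_sample[case.sample_id], annotation.cgis)
                for p in covered
            }
            for case in cases
        }
        control_masks = {
            p.gene_id: pat_mod.binarize_promoter(
                p, peaks_by_sample[control.sample_id], annotation.cgis)
            for p in covered
        }
        calls = pat_mod.select_specific_promoters(
            case_masks, control_masks, min_case_support=th["min_case_support"])
        pat_mod.write_pattern_calls(
            calls, os.path.join(outdir, "pattern_calls.tsv"),
            header_lines=_header(config))
        pattern_counts: Dict[str, int] = {}
        for call in calls:
            pattern_counts[call.pattern] = pattern_counts.get(call.pattern, 0) + 1
        summary["stages"]["patterns"] = {
            "n_covered_promoters": len(covered),
            "n_calls": len(calls),
            "by_pattern": dict(sorted(pattern_counts.items())),
        }

        # ---------------- expression integration
        stage = "expression"
        if expression_df is not None:
            exprdir = os.path.join(outdir, "expression")
            os.makedirs(exprdir, exist_ok=True)
            rpkm = expr_mod.compute_rpkm(expression_df)
            rpkm.to_csv(os.path.join(exprdir, "rpkm.tsv"), sep="\t",
                        index=False, float_format="%.6g")
            sample_cols = [c for c in expression_df.columns
                           if c not in ("gene_id", "length")]
            case_cols = [c for c in sample_cols if c.startswith("case")]
            ctrl_cols = [c for c in sample_cols if not c.startswith("case")]
            indexed = rpkm.set_index("gene_id")
            ranked = expr_mod.rank_genes(
                indexed[[f"rpkm_{c}" for c in case_cols]],
                indexed[f"rpkm_{ctrl_cols[0]}"],
            )
            gene_sets = derive_methylation_gene_sets(ultras, annotation)
            gsea_results = []
            for name, members in sorted(gene_sets.items()):
                members = [g for g in members if g in ranked.index]
                if 1 <= len(members) < len(ranked):
                    gsea_results.append(
                        expr_mod.gsea_permutation_p(
                            ranked, members, gene_set_name=name,
                            n_perm=th["gsea_n_perm"], seed=config.seed,
                        )
                    )
            expr_mod.write_gsea_results(
                gsea_results, os.path.join(exprdir, "gsea.tsv"))
            if config.gene_sets_gmt:
                gmt = expr_mod.read_gmt(config.gene_sets_gmt)
                interesting = sorted(
                    {call.gene_id for call in calls
                     if call.specificity == "case_specific"}
                )
                pres = expr_mod.pathway_hypergeom(
                    interesting, gmt, list(ranked.index))
                expr_mod.write_pathway_results(
                    pres, os.path.join(exprdir, "pathways.tsv"))
                summary["stages"]["pathways"] = {
                    "n_flagged": sum(r.flagged for r in pres)
                }
            summary["stages"]["expression"] = {
                r.gene_set_name: {"es": round(r.es, 6), "perm_p": r.perm_p}
                for r in gsea_results
            }

        # ---------------- summary
        stage = "summary"
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return summary
    except Exception as exc:
        faildir = os.path.join(outdir, "failed")
        os.makedirs(faildir, exist_ok=True)
        for entry in sorted(os.listdir(outdir)):
            if entry == "failed":
                continue
            shutil.move(os.path.join(outdir, entry),
                        os.path.join(faildir, entry))
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc


def derive_methylation_gene_sets(
    ultras,
    annotation: GenomeAnnotation,
) -> Dict[str, List[str]]:
    """Gene sets defined by consensus promoter methylation events.

    ``promoter_cgi_hyper``: genes whose promoter CGI overlaps an ultra
    hypermethylated segment.  ``shore_3p_hypo``: genes whose promoter
    CGI 3'-shore overlaps an ultra hypomethylated segment.
    """
    from .intervals import IntervalIndex

    hyper = [u.segment for u in ultras if u.direction == "hyper"]
    hypo = [u.segment for u in ultras if u.direction == "hypo"]
    hyper_idx = IntervalIndex.from_intervals(hyper) if hyper else None
    hypo_idx = IntervalIndex.from_intervals(hypo) if hypo else None

    cgi_gene: Dict[int, str] = getattr(annotation, "cgi_gene", None) or {}
    if not cgi_gene:
        # associate each CGI with the gene whose promoter contains its midpoint
        prom_idx = annotation.index("promoter")
        for ci, c in enumerate(annotation.cgis):
            mid = (c.interval.start + c.interval.end) // 2
            hits = prom_idx.query(c.interval.chrom, mid, mid + 1)
            if hits:
                pi = sorted(hits)[0]
                cgi_gene[ci] = annotation.promoters[pi].gene_id

    sets: Dict[str, List[str]] = {"promoter_cgi_hyper": [],
                                  "shore_3p_hypo": []}
    for ci, gid in sorted(cgi_gene.items()):
        iv = annotation.cgis[ci].interval
        if hyper_idx is not None and hyper_idx.any_overlap(iv.chrom, iv.start,
                                                           iv.end):
            sets["promoter_cgi_hyper"].append(gid)
    shore3 = {s.cgi_index: s for s in annotation.shores if s.orientation == "3p"}
    for ci, gid in sorted(cgi_gene.items()):
        s = shore3.get(ci)
        if s is None or hypo_idx is None:
            continue
        iv = s.interval
        if hypo_idx.any_overlap(iv.chrom, iv.start, iv.end):
            sets["shore_3p_hypo"].append(gid)
    return {k: sorted(set(v)) for k, v in sets.items()}
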