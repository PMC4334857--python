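"""Seeded toy-genome simulator with planted differential methylation.

Emulates the data-generating process of a MeDIP-seq case/control study:

* a toy genome with genes, promoter and intergenic CpG islands, shores,
  cytogenetic bands, and a CpG position map (CpG density ~10x inside
  islands);
* per-sample aligned reads drawn from an inhomogeneous Poisson process
  whose local rate is proportional to CpG density times methylation
  level, with per-sample library-size variation;
* planted hyper-/hypomethylated regions at a configurable fold effect in
  chosen genomic feature classes, recorded in a machine-readable truth
  table;
* an expression table in which promoter-CGI hypermethylation represses
  the downstream gene and 3'-shore hypomethylation increases expression.

Everything is driven by one integer seed; a fixed seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .genome_features import (
    CGI,
    Band,
    GeneModel,
    GenomeAnnotation,
    classify_cgi_length,
    derive_promoters,
    derive_shores,
)
from .intervals import AlignedReadSet, GenomicInterval

FEATURE_TARGETS = ("promoter_cgi", "shore_5p", "shore_3p", "promoter_nocgi",
                   "intergenic")

# MeDIP weight (CpG density x methylation) relative to genomic background.
BACKGROUND_WEIGHT = 1.0
CGI_BASELINE_WEIGHT = 2.5    # CpG-dense but mostly unmethylated islands
SHORE_BASELINE_WEIGHT = 3.0  # moderate density, partially methylated
METHYLATED_WEIGHT = 8.0      # a fully methylated, CpG-bearing region
HYPER_BASE_WEIGHT = 2.0      # moderately methylated control state of hyper events


@dataclass
class SimulationConfig:
    """All knobs of the simulator; defaults are the study conditions."""

    n_chromosomes: int = 2
    chrom_length_bp: int = 5_000_000
    n_genes: int = 300
    n_cgis: int = 200
    reads_per_sample: int = 200_000
    fragment_length_bp: int = 200
    n_case_samples: int = 6
    n_planted_hyper: int = 50
    n_planted_hypo: int = 50
    effect_fold: float = 4.0
    feature_targets: Tuple[str, ...] = FEATURE_TARGETS
    expression_coupling_strength: float = 1.0
    n_expression_case: int = 3
    seed: int = 0
    # secondary knobs
    cgi_promoter_fraction: float = 0.6
    planted_region_bp: int = 2000
    library_size_cv: float = 0.2
    expression_baseline_mean: float = 300.0
    expression_noise_sigma: float = 0.25  # log-scale biological noise

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length_bp", "n_genes",
                     "reads_per_sample", "fragment_length_bp", "n_case_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("n_cgis", "n_planted_hyper", "n_planted_hypo"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        self.feature_targets = tuple(self.feature_targets)
        for t in self.feature_targets:
            if t not in FEATURE_TARGETS:
                raise ValueError(f"unknown feature target {t!r}")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["feature_targets"] = list(d["feature_targets"])
        return yaml.safe_dump(d, sort_keys=True)


@dataclass
class PlantedRegion:
    interval: GenomicInterval
    direction: str  # hyper | hypo
    fold: float
    feature_class: str
    gene_id: Optional[str] = None


@dataclass
class TruthTable:
    """Planted regions plus the genes designated for expression coupling."""

    planted: List[PlantedRegion] = field(default_factory=list)
    repressed_genes: List[str] = field(default_factory=list)
    overexpressed_genes: List[str] = field(default_factory=list)

    def regions(self, direction: Optional[str] = None) -> List[PlantedRegion]:
        if direction is None:
            return list(self.planted)
        return [p for p in self.planted if p.direction == direction]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "direction": p.direction,
                "fold": p.fold,
                "feature_class": p.feature_class,
                "gene_id": p.gene_id if p.gene_id else ".",
            }
            for p in self.planted
        ]
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "direction", "fold",
                     "feature_class", "gene_id"],
        )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    cpg_positions: Dict[str, np.ndarray]
    truth: TruthTable
    control: AlignedReadSet
    cases: List[AlignedReadSet]
    expression: pd.DataFrame


def _rng(seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


# ---------------------------------------------------------------------------
# Genome


def simulate_genome(
    config: SimulationConfig,
) -> Tuple[GenomeAnnotation, Dict[str, np.ndarray]]:
    """Build the toy genome annotation and its CpG position map.

    Genes are placed on a jittered regular grid; about 60% of promoters
    receive a CpG island spanning the TSS (log-normal lengths); leftover
    islands go to intergenic positions.  CpG sites are sampled at ~10x
    background density inside islands and ~3x in shores.
    """
    rng = _rng(config.seed, 0)
    L = config.chrom_length_bp
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_sizes = {c: L for c in chroms}

    margin = min(20_000, L // 10)
    genes: List[GeneModel] = []
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    gap_midpoints: List[Tuple[str, int]] = []
    for ci, chrom in enumerate(chroms):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        slot = (L - 2 * margin) / n
        if slot < 20_000:
            raise ValueError("requested features exceed genome capacity")
        for j in range(n):
            center = margin + slot * (j + 0.5)
            center += rng.uniform(-slot / 8, slot / 8)
            glen = int(rng.integers(5_000, 15_000))
            start = int(center - glen / 2)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    f"gene_{chrom}_{j:04d}",
                    GenomicInterval(chrom, start, start + glen, strand),
                )
            )
            if j > 0:
                gap_midpoints.append((chrom, int(margin + slot * j)))

    # promoter CGIs
    n_prom_cgi = min(config.n_cgis, int(round(config.cgi_promoter_fraction
                                              * len(genes))))
    prom_idx = rng.choice(len(genes), size=n_prom_cgi, replace=False)
    cgis: List[CGI] = []
    cgi_gene: Dict[int, str] = {}
    for gi in sorted(prom_idx):
        g = genes[gi]
        clen = int(np.clip(rng.lognormal(np.log(800), 0.45), 200, 2500))
        tss = g.tss
        start = max(0, tss - clen // 2)
        end = min(L, start + clen)
        cgi_gene[len(cgis)] = g.gene_id
        cgis.append(CGI(GenomicInterval(g.interval.chrom, start, end)))

    # intergenic CGIs at gene-gap midpoints
    n_inter = config.n_cgis - n_prom_cgi
    if n_inter > 0:
        if n_inter > len(gap_midpoints):
            raise ValueError("requested features exceed genome capacity")
        pick = rng.choice(len(gap_midpoints), size=n_inter, replace=False)
        for k in sorted(pick):
            chrom, mid = gap_midpoints[k]
            clen = int(np.clip(rng.lognormal(np.log(800), 0.45), 200, 2500))
            start = max(0, mid - clen // 2)
            cgis.append(CGI(GenomicInterval(chrom, start, min(L, start + clen))))

    classify_cgi_length(cgis)
    shores = derive_shores(cgis, width_bp=2000, chrom_sizes=chrom_sizes, genes=genes)

    # cytogenetic bands: 10 equal bands per chromosome
    bands: List[Band] = []
    band_names = [f"p{i}" for i in range(5, 0, -1)] + [f"q{i}" for i in range(1, 6)]
    for chrom in chroms:
        edges = np.linspace(0, L, 11).astype(int)
        for bi in range(10):
            bands.append(
                Band(GenomicInterval(chrom, int(edges[bi]), int(edges[bi + 1])),
                     f"{chrom}:{band_names[bi]}")
            )

    # a sprinkle of repeats in intergenic background
    repeats: List[Tuple[GenomicInterval, str]] = []
    fams = ("SINE", "LINE", "LTR")
    for ci, chrom in enumerate(chroms):
        for r in range(30):
            pos = int(rng.integers(margin, L - margin))
            repeats.append(
                (GenomicInterval(chrom, pos, pos + 300), fams[r % 3])
            )

    ann = GenomeAnnotation(
        chrom_sizes=chrom_sizes, genes=genes, cgis=cgis, shores=shores,
        bands=bands, repeats=repeats,
    )
    ann.promoters = derive_promoters(genes, flank_bp=2000, chrom_sizes=chrom_sizes)
    cgi_idx = ann.index("cgi")
    for p in ann.promoters:
        p.overlapping_cgis = sorted(
            cgi_idx.query(p.interval.chrom, p.interval.start, p.interval.end)
        )
    ann.cgi_gene = cgi_gene  # promoter-CGI index -> gene id

    cpg_positions = _sample_cpg_positions(ann, rng)
    for i, c in enumerate(ann.cgis):
        pos = cpg_positions[c.interval.chrom]
        c.cpg_count = int(
            np.searchsorted(pos, c.interval.end) - np.searchsorted(pos, c.interval.start)
        )
    return ann, cpg_positions


def _sample_cpg_positions(
    ann: GenomeAnnotation, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    """CpG sites as a Poisson process: 1/100 bp background, 10x in CGIs, 3x in shores."""
    out: Dict[str, np.ndarray] = {}
    for chrom, size in sorted(ann.chrom_sizes.items()):
        segs = _weight_segments_chrom(ann, None, chrom)
        positions = []
        for start, end, w_ctrl, _ in segs:
            density = {BACKGROUND_WEIGHT: 0.01, CGI_BASELINE_WEIGHT: 0.1,
                       SHORE_BASELINE_WEIGHT: 0.03}.get(w_ctrl, 0.01)
            n = rng.poisson(density * (end - start))
            if n:
                positions.append(rng.integers(start, end, size=n))
        pos = (np.sort(np.concatenate(positions)) if positions
               else np.empty(0, dtype=np.int64))
        out[chrom] = pos
    return out


# ---------------------------------------------------------------------------
# Truth planting


def plant_truth(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> TruthTable:
    """Choose planted hyper/hypo regions in the configured feature classes.

    Planted regions are pairwise disjoint.  Genes whose promoter CGI is
    hypermethylated are designated repressed; genes whose promoter-CGI
    3'-shore is hypomethylated are designated overexpressed.
    """
    rng = _rng(config.seed, 3)
    ann = annotation
    cgi_gene: Dict[int, str] = getattr(ann, "cgi_gene", {})
    gene_by_id = {g.gene_id: g for g in ann.genes}

    # pools per feature class
    prom_cgi_pool = [ci for ci, gid in cgi_gene.items() if ann.cgis[ci].length >= 400]
    shores_by_cgi: Dict[int, Dict[str, int]] = {}
    for si, s in enumerate(ann.shores):
        shores_by_cgi.setdefault(s.cgi_index, {})[s.orientation] = si
    genes_with_cgi = set(cgi_gene.values())
    nocgi_pool = [g.gene_id for g in ann.genes if g.gene_id not in genes_with_cgi]
    occupied = []  # intervals already used, to keep regions disjoint

    def free(iv: GenomicInterval) -> bool:
        return not any(iv.overlaps(o) for o in occupied)

    # intergenic pool: gap positions far from genes/CGIs
    gene_tree = ann.index("gene")
    cgi_tree = ann.index("cgi")
    shore_tree = ann.index("shore")
    inter_pool: List[GenomicInterval] = []
    half = config.planted_region_bp // 2
    for chrom, size in sorted(ann.chrom_sizes.items()):
        for pos in range(30_000, size - 30_000, 16_000):
            iv = GenomicInterval(chrom, pos - half, pos + half)
            pad = GenomicInterval(chrom, max(0, pos - half - 3000), pos + half + 3000)
            if (gene_tree.any_overlap(pad.chrom, pad.start, pad.end)
                    or cgi_tree.any_overlap(pad.chrom, pad.start, pad.end)
                    or shore_tree.any_overlap(pad.chrom, pad.start, pad.end)):
                continue
            inter_pool.append(iv)

    rng.shuffle(prom_cgi_pool)
    rng.shuffle(nocgi_pool)
    inter_order = rng.permutation(len(inter_pool))
    inter_iter = iter(inter_order)
    shore_cgi_pool = [ci for ci in cgi_gene if ci in shores_by_cgi]
    rng.shuffle(shore_cgi_pool)
    prom_iter = iter(prom_cgi_pool)
    shore_iter = iter(shore_cgi_pool)
    nocgi_iter = iter(nocgi_pool)

    def draw(feature: str) -> Tuple[GenomicInterval, Optional[str]]:
        while True:
            if feature == "promoter_cgi":
                ci = next(prom_iter)
                iv, gid = ann.cgis[ci].interval, cgi_gene[ci]
            elif feature in ("shore_5p", "shore_3p"):
                ci = next(shore_iter)
                want = "5p" if feature == "shore_5p" else "3p"
                si = shores_by_cgi[ci].get(want)
                if si is None:
                    continue
                iv, gid = ann.shores[si].interval, cgi_gene.get(ci)
            elif feature == "promoter_nocgi":
                gid = next(nocgi_iter)
                g = gene_by_id[gid]
                tss = g.tss
                iv = GenomicInterval(g.interval.chrom, max(0, tss - half), tss + half)
            else:  # intergenic
                iv = inter_pool[next(inter_iter)]
                gid = None
            if free(iv):
                return iv, gid

    truth = TruthTable()
    targets = list(config.feature_targets)
    for direction, total in (("hyper", config.n_planted_hyper),
                             ("hypo", config.n_planted_hypo)):
        counts = [total // len(targets)] * len(targets)
        for i in range(total % len(targets)):
            counts[i] += 1
        for feature, n in zip(targets, counts):
            for _ in range(n):
                try:
                    iv, gid = draw(feature)
                except StopIteration as exc:
                    raise ValueError(
                        "requested features exceed genome capacity"
                    ) from exc
                occupied.append(iv)
                truth.planted.append(
                    PlantedRegion(iv, direction, config.effect_fold, feature, gid)
                )
                if direction == "hyper" and feature == "promoter_cgi" and gid:
                    truth.repressed_genes.append(gid)
                if direction == "hypo" and feature == "shore_3p" and gid:
                    truth.overexpressed_genes.append(gid)
    return truth


# ---------------------------------------------------------------------------
# Reads


def _weight_segments_chrom(
    ann: GenomeAnnotation, truth: Optional[TruthTable], chrom: str
) -> List[Tuple[int, int, float, float]]:
    """Piecewise-constant (start, end, control_weight, case_weight) track.

    Planted regions override the feature baseline: hyper events sit at a
    moderately methylated control weight and are multiplied by the fold
    in cases; hypo events sit at the fully methylated weight and are
    divided by the fold in cases.
    """
    size = ann.chrom_sizes[chrom]
    cgi_iv = [c.interval for c in ann.cgis if c.interval.chrom == chrom]
    shore_iv = [s.interval for s in ann.shores if s.interval.chrom == chrom]
    planted = ([p for p in truth.planted if p.interval.chrom == chrom]
               if truth else [])

    edges = {0, size}
    for iv in cgi_iv + shore_iv + [p.interval for p in planted]:
        edges.add(max(0, iv.start))
        edges.add(min(size, iv.end))
    bounds = np.array(sorted(edges), dtype=np.int64)

    cgi_starts = np.array(sorted(iv.start for iv in cgi_iv), dtype=np.int64)
    cgi_ends = np.array(sorted(iv.end for iv in cgi_iv), dtype=np.int64)
    sh_starts = np.array(sorted(iv.start for iv in shore_iv), dtype=np.int64)
    sh_ends = np.array(sorted(iv.end for iv in shore_iv), dtype=np.int64)
    planted_sorted = sorted(planted, key=lambda p: p.interval.start)
    pl_starts = np.array([p.interval.start for p in planted_sorted], dtype=np.int64)

    def in_sorted(starts: np.ndarray, ends: np.ndarray, point: int) -> bool:
        # membership in a union of (possibly overlapping) sorted intervals
        i = np.searchsorted(starts, point, side="right")
        return bool(i > 0 and np.any(ends[max(0, i - 64):i] > point))

    segments: List[Tuple[int, int, float, float]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        mid = int(a)
        pi = int(np.searchsorted(pl_starts, mid, side="right")) - 1
        if pi >= 0 and planted_sorted[pi].interval.end > mid:
            p = planted_sorted[pi]
            if p.direction == "hyper":
                w_ctrl, w_case = HYPER_BASE_WEIGHT, HYPER_BASE_WEIGHT * p.fold
            else:
                w_ctrl, w_case = METHYLATED_WEIGHT, METHYLATED_WEIGHT / p.fold
        elif in_sorted(cgi_starts, cgi_ends, mid):
            w_ctrl = w_case = CGI_BASELINE_WEIGHT
        elif in_sorted(sh_starts, sh_ends, mid):
            w_ctrl = w_case = SHORE_BASELINE_WEIGHT
        else:
            w_ctrl = w_case = BACKGROUND_WEIGHT
        segments.append((int(a), int(b), w_ctrl, w_case))
    return segments


def simulate_reads(
    annotation: GenomeAnnotation,
    truth: Optional[TruthTable],
    config: SimulationConfig,
) -> Tuple[AlignedReadSet, List[AlignedReadSet]]:
    """Draw per-sample reads from the inhomogeneous rate field.

    Fragment midpoints follow a multinomial over the weight track (an
    inhomogeneous Poisson process conditioned on the library size); each
    sample's library size is the configured read count scaled by a
    uniform +/-CV factor.  Returns (control, [case samples]).
    """
    chroms = sorted(annotation.chrom_sizes)
    segs = {c: _weight_segments_chrom(annotation, truth, c) for c in chroms}

    flat = []
    for c in chroms:
        for (a, b, wc, wk) in segs[c]:
            flat.append((c, a, b, wc * (b - a), wk * (b - a)))
    ctrl_mass = np.array([f[3] for f in flat])
    case_mass = np.array([f[4] for f in flat])

    def one_sample(sample_idx: int, is_case: bool, name: str) -> AlignedReadSet:
        rng = _rng(config.seed, 1, sample_idx)
        factor = rng.uniform(1 - config.library_size_cv, 1 + config.library_size_cv)
        n_reads = int(round(config.reads_per_sample * factor))
        mass = case_mass if is_case else ctrl_mass
        counts = rng.multinomial(n_reads, mass / mass.sum())
        frag = config.fragment_length_bp
        by_chrom: Dict[str, List[np.ndarray]] = {c: [] for c in chroms}
        for (chrom, a, b, _, _), k in zip(flat, counts):
            if k == 0:
                continue
            mids = rng.integers(a, b, size=int(k))
            by_chrom[chrom].append(mids)
        reads: Dict[str, np.ndarray] = {}
        for chrom in chroms:
            if not by_chrom[chrom]:
                continue
            mids = np.sort(np.concatenate(by_chrom[chrom]))
            size = annotation.chrom_sizes[chrom]
            starts = np.clip(mids - frag // 2, 0, max(0, size - frag))
            ends = np.minimum(starts + frag, size)
            reads[chrom] = np.column_stack([starts, ends])
        return AlignedReadSet(sample_id=name, reads=reads, urc=n_reads)

    control = one_sample(0, False, "control_1")
    cases = [
        one_sample(1 + i, True, f"case_{i + 1}")
        for i in range(config.n_case_samples)
    ]
    return control, cases


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    annotation: GenomeAnnotation,
    truth: TruthTable,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-gene read counts for one control and ``n_expression_case`` cases.

    Baselines are log-normal across genes; counts add Poisson sampling on
    top of log-normal biological noise.  Repressed genes (promoter-CGI
    hypermethylation) have their case means divided by
    ``2**expression_coupling_strength``; overexpressed genes (3'-shore
    hypomethylation) multiplied by it.
    """
    rng = _rng(config.seed, 2)
    genes = annotation.genes
    baseline = rng.lognormal(np.log(config.expression_baseline_mean), 0.7,
                             size=len(genes))
    repressed = set(truth.repressed_genes)
    overexpressed = set(truth.overexpressed_genes)
    coupling = 2.0 ** config.expression_coupling_strength

    rows = []
    sigma = config.expression_noise_sigma
    for gi, g in enumerate(genes):
        mu = baseline[gi]
        ctrl = rng.poisson(mu * rng.lognormal(-sigma**2 / 2, sigma))
        if g.gene_id in repressed:
            case_mu = mu / coupling
        elif g.gene_id in overexpressed:
            case_mu = mu * coupling
        else:
            case_mu = mu
        case_counts = [
            int(rng.poisson(case_mu * rng.lognormal(-sigma**2 / 2, sigma)))
            for _ in range(config.n_expression_case)
        ]
        row = {"gene_id": g.gene_id, "length": g.longest_transcript,
               "control_1": int(ctrl)}
        for j, c in enumerate(case_counts):
            row[f"case_{j + 1}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# One-call dataset


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate genome, truth, reads, and expression in one call."""
    annotation, cpg_positions = simulate_genome(config)
    truth = plant_truth(annotation, config)
    control, cases = simulate_reads(annotation, truth, config)
    expression = simulate_expression(annotation, truth, config)
    return SimulatedDataset(
        config=config, annotation=annotation, cpg_positions=cpg_positions,
        truth=truth, control=control, cases=cases, expression=expression,
    )


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write BEDs, annotation, truth table, expression, and config YAML."""
    from .genome_features import write_annotation
    from .intervals import write_bed_reads

    os.makedirs(outdir, exist_ok=True)
    write_annotation(ds.annotation, os.path.join(outdir, "annotation"))
    for sample in [ds.control] + ds.cases:
        write_bed_reads(sample, os.path.join(outdir, f"{sample.sample_id}.bed"))
    ds.truth.to_frame().to_csv(
        os.path.join(outdir, "truth.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "truth_genes.tsv"), "w") as fh:
        fh.write("gene_id\teffect\n")
        for gid in ds.truth.repressed_genes:
            fh.write(f"{gid}\trepressed\n")
        for gid in ds.truth.overexpressed_genes:
            fh.write(f"{gid}\toverexpressed\n")
    ds.expression.to_csv(
        os.path.join(outdir, "expression_counts.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        fh.write(ds.config.to_yaml())


def simulate_promoter_sequence(
    promoter_interval: GenomicInterval,
    cpg_positions: np.ndarray,
    seed: int = 0,
    gc_background: float = 0.45,
) -> str:
    """Synthesize a promoter sequence consistent with the CpG position map.

    Random background bases at the given GC content, with a CG
    dinucleotide written at every mapped CpG site inside the promoter.
    Intended for CpG-content classification of simulated promoters.
    """
    rng = _rng(seed, 4, promoter_interval.start)
    L = promoter_interval.length
    p_gc = gc_background / 2
    seq = rng.choice(
        np.array(list("ACGT")), size=L,
        p=[0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc],
    )
    lo = np.searchsorted(cpg_positions, promoter_interval.start)
    hi = np.searchsorted(cpg_positions, promoter_interval.end)
    for pos in cpg_positions[lo:hi]:
        off = int(pos - promoter_interval.start)
        if off + 1 < L:
            seq[off] = "C"
            seq[off + 1] = "G"
    return "".join(seq)
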