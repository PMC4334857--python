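"""Feature and chromosome-band enrichment of differential methylation.

Regions are mapped to every genomic feature class they overlap
(multi-label; a base can be both promoter and CGI).  Enrichment is then
assessed on the equal-sized 500 bp segment grid: the 2x2 table crosses
{segment in regions vs rest of genome} x {segment overlaps feature vs
not}, scored with an odds ratio and a two-sided Fisher exact test, with
Benjamini-Hochberg adjustment across classes.  A class is flagged
enriched at q < 0.01 and OR > 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .dmr import bh_adjust
from .genome_features import GenomeAnnotation
from .intervals import GenomicInterval, IntervalIndex

logger = logging.getLogger(__name__)

NEAREST_MAX_BP = 10_000


@dataclass
class EnrichmentResult:
    feature_class: str
    k_in: int      # region segments overlapping the feature
    k_out: int     # region segments not overlapping it
    bg_in: int     # background segments overlapping the feature
    bg_out: int    # background segments not overlapping it
    odds_ratio: float
    p_value: float
    q_value: float = np.nan
    flagged: bool = False
    continuity_corrected: bool = False


def _feature_tracks(annotation: GenomeAnnotation) -> Dict[str, List[GenomicInterval]]:
    tracks: Dict[str, List[GenomicInterval]] = {
        "promoter": [p.interval for p in annotation.promoters],
        "cgi": [c.interval for c in annotation.cgis],
        "shore_5p": [s.interval for s in annotation.shores
                     if s.orientation == "5p"],
        "shore_3p": [s.interval for s in annotation.shores
                     if s.orientation == "3p"],
        "gene_body": [g.interval for g in annotation.genes],
    }
    for iv, fam in annotation.repeats:
        tracks.setdefault(fam, []).append(iv)
    if annotation.mirna_promoters:
        tracks["mirna_promoter"] = list(annotation.mirna_promoters)
    return {k: v for k, v in tracks.items() if v}


def map_to_features(
    regions: Sequence[GenomicInterval],
    annotation: GenomeAnnotation,
    nearest_max_bp: int = NEAREST_MAX_BP,
) -> List[List[str]]:
    """Assign each region every feature class it overlaps.

    Regions overlapping nothing are assigned the nearest feature class
    within ``nearest_max_bp`` (ties broken by smaller distance, then
    alphabetical class name), else 'intergenic'.
    """
    tracks = _feature_tracks(annotation)
    indexes = {
        name: IntervalIndex.from_intervals(ivs) for name, ivs in tracks.items()
    }
    out: List[List[str]] = []
    for region in regions:
        hit = sorted(
            name for name, idx in indexes.items()
            if idx.any_overlap(region.chrom, region.start, region.end)
        )
        if not hit:
            best: Optional[Tuple[int, str]] = None
            for name, ivs in tracks.items():
                for iv in ivs:
                    if iv.chrom != region.chrom:
                        continue
                    dist = max(iv.start - region.end, region.start - iv.end, 0)
                    if dist <= nearest_max_bp:
                        cand = (dist, name)
                        if best is None or cand < best:
                            best = cand
            hit = [best[1]] if best else ["intergenic"]
        out.append(hit)
    return out


def _segment_grid(chrom_sizes: Dict[str, int], segment_bp: int):
    """(chrom, start) arrays of the genome-wide segment grid."""
    chroms, starts = [], []
    for chrom in sorted(chrom_sizes):
        n = (chrom_sizes[chrom] + segment_bp - 1) // segment_bp
        chroms.extend([chrom] * n)
        starts.extend(range(0, n * segment_bp, segment_bp))
    return chroms, np.array(starts, dtype=np.int64)


def _segment_mask(
    chrom_sizes: Dict[str, int],
    segment_bp: int,
    intervals: Sequence[GenomicInterval],
) -> np.ndarray:
    """Boolean mask over the segment grid: segment overlaps any interval."""
    offsets: Dict[str, int] = {}
    total = 0
    for chrom in sorted(chrom_sizes):
        offsets[chrom] = total
        total += (chrom_sizes[chrom] + segment_bp - 1) // segment_bp
    mask = np.zeros(total, dtype=bool)
    for iv in intervals:
        if iv.chrom not in offsets:
            continue
        size = chrom_sizes[iv.chrom]
        first = max(0, iv.start) // segment_bp
        last = (min(iv.end, size) - 1) // segment_bp
        mask[offsets[iv.chrom] + first : offsets[iv.chrom] + last + 1] = True
    return mask


def odds_ratio_2x2(
    k_in: int, k_out: int, bg_in: int, bg_out: int
) -> Tuple[float, bool]:
    """OR = (k_in * bg_out) / (k_out * bg_in); Haldane 0.5 on zero cells."""
    cells = [k_in, k_out, bg_in, bg_out]
    corrected = any(c == 0 for c in cells)
    if corrected:
        a, b, c, d = (x + 0.5 for x in cells)
    else:
        a, b, c, d = cells
    return (a * d) / (b * c), corrected


def enrichment_test(
    regions: Sequence[GenomicInterval],
    annotation: GenomeAnnotation,
    feature_classes: Optional[Sequence[str]] = None,
    segment_bp: int = 500,
    q_flag: float = 0.01,
) -> List[EnrichmentResult]:
    """Segment-grid enrichment of regions in each feature class.

    The background is every genome segment not covered by the regions.
    """
    tracks = _feature_tracks(annotation)
    if feature_classes is not None:
        tracks = {k: v for k, v in tracks.items() if k in feature_classes}
    region_mask = _segment_mask(annotation.chrom_sizes, segment_bp, regions)
    results: List[EnrichmentResult] = []
    for name in sorted(tracks):
        feat_mask = _segment_mask(annotation.chrom_sizes, segment_bp, tracks[name])
        k_in = int(np.sum(region_mask & feat_mask))
        k_out = int(np.sum(region_mask & ~feat_mask))
        bg_in = int(np.sum(~region_mask & feat_mask))
        bg_out = int(np.sum(~region_mask & ~feat_mask))
        oratio, corrected = odds_ratio_2x2(k_in, k_out, bg_in, bg_out)
        _, p = stats.fisher_exact([[k_in, k_out], [bg_in, bg_out]],
                                  alternative="two-sided")
        results.append(
            EnrichmentResult(name, k_in, k_out, bg_in, bg_out, oratio, float(p),
                             continuity_corrected=corrected)
        )
    qvals = bh_adjust(np.array([r.p_value for r in results]))
    for r, q in zip(results, qvals):
        r.q_value = float(q)
        r.flagged = bool(q < q_flag and r.odds_ratio > 1)
    return results


def band_enrichment(
    regions: Sequence[GenomicInterval],
    annotation: GenomeAnnotation,
    segment_bp: int = 500,
    q_flag: float = 0.01,
) -> List[EnrichmentResult]:
    """Per-cytogenetic-band enrichment on the segment grid.

    Same 2x2 construction as feature enrichment, one test per band;
    bands containing no segments are skipped with a warning.
    """
    region_mask = _segment_mask(annotation.chrom_sizes, segment_bp, regions)
    results: List[EnrichmentResult] = []
    for band in annotation.bands:
        band_mask = _segment_mask(annotation.chrom_sizes, segment_bp,
                                  [band.interval])
        if not band_mask.any():
            logger.warning("band %s contains no segments; skipped", band.name)
            continue
        k_in = int(np.sum(region_mask & band_mask))
        k_out = int(np.sum(region_mask & ~band_mask))
        bg_in = int(np.sum(~region_mask & band_mask))
        bg_out = int(np.sum(~region_mask & ~band_mask))
        oratio, corrected = odds_ratio_2x2(k_in, k_out, bg_in, bg_out)
        _, p = stats.fisher_exact([[k_in, k_out], [bg_in, bg_out]],
                                  alternative="two-sided")
        results.append(
            EnrichmentResult(band.name, k_in, k_out, bg_in, bg_out, oratio,
                             float(p), continuity_corrected=corrected)
        )
    if not results:
        return results
    qvals = bh_adjust(np.array([r.p_value for r in results]))
    for r, q in zip(results, qvals):
        r.q_value = float(q)
        r.flagged = bool(q < q_flag and r.odds_ratio > 1)
    return results


def write_enrichment(results: Sequence[EnrichmentResult], path,
                     header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("feature_class\tk_in\tk_out\tbg_in\tbg_out\todds_ratio\t"
                 "p_value\tq_value\tflagged\n")
        for r in results:
            fh.write(
                f"{r.feature_class}\t{r.k_in}\t{r.k_out}\t{r.bg_in}\t{r.bg_out}\t"
                f"{r.odds_ratio:.6g}\t{r.p_value:.6g}\t{r.q_value:.6g}\t"
                f"{int(r.flagged)}\n"
            )
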