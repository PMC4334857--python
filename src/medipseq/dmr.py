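"""Differential methylation calling between a case and a control sample.

Candidate regions are the coalesced union of the two samples' peaks.
Each candidate is tested with a Yates-corrected chi-square on the 2x2
table of reads inside/outside the region for each sample:

    chi2 = n * (max(0, |ad - bc| - n/2))^2 / ((a+b)(c+d)(a+c)(b+d))

where a/c are in-region reads of control/case, b/d the remaining reads
(so a+b and c+d are the library sizes), and n = a+b+c+d.  Candidates
pass when the Benjamini-Hochberg q-value is at most 5% and the
library-size-corrected fold change of in-region read proportions is at
least 2 in either direction.

Ultra DMRs are the cross-sample consensus: the genome is divided into
500 bp segments and a segment is "ultra" in a direction when a
same-direction DMR overlaps it by more than 250 bp in more than half of
the case samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .intervals import AlignedReadSet, GenomicInterval, merge_intervals
from .peaks import Peak

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable2x2:
    """Reads in/out of a region for the control (a, b) and case (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class DMR:
    interval: GenomicInterval
    table: ContingencyTable2x2
    chi2: float
    p_value: float
    q_value: float
    fold: float
    direction: str  # hyper | hypo, w.r.t. the case sample


@dataclass
class UltraDMR:
    segment: GenomicInterval
    direction: str
    support: int
    n_samples: int


def merge_candidate_regions(
    peaks_control: Sequence[Peak], peaks_case: Sequence[Peak]
) -> List[GenomicInterval]:
    """Union of both samples' peaks with overlapping/adjacent intervals coalesced."""
    ivs = [p.interval for p in peaks_control] + [p.interval for p in peaks_case]
    if not ivs:
        return []
    return merge_intervals(ivs, gap=0)


def chisq_test(table: ContingencyTable2x2) -> Tuple[float, float]:
    """Yates-corrected chi-square for a 2x2 table, 1 df.

    The continuity-corrected numerator is clamped at zero when
    |ad - bc| <= n/2.  A degenerate margin (no reads in the region, or
    no reads outside it, in both samples combined) yields chi2 = 0,
    p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n == 0:
        raise ValueError("empty contingency table")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 0.0, 1.0
    num = abs(a * d - b * c) - n / 2.0
    if num <= 0:
        return 0.0, 1.0
    chi2 = n * num * num / (float(r1) * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, in the original
    order.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_dmrs(
    candidates: Sequence[GenomicInterval],
    reads_control: AlignedReadSet,
    reads_case: AlignedReadSet,
    q_max: float = 0.05,
    min_fold: float = 2.0,
) -> List[DMR]:
    """Test candidate regions and emit significant, >= min_fold DMRs.

    The fold is the ratio of in-region read proportions
    (c/(c+d)) / (a/(a+b)), i.e. corrected for library size.  BH
    adjustment runs across all testable candidates of the comparison.
    Candidates with zero reads in both samples are dropped (logged).
    """
    urc_ctrl = reads_control.urc
    urc_case = reads_case.urc
    rows = []
    n_dropped = 0
    for iv in candidates:
        a = reads_control.count_in(iv.chrom, iv.start, iv.end)
        c = reads_case.count_in(iv.chrom, iv.start, iv.end)
        if a == 0 and c == 0:
            n_dropped += 1
            continue
        table = ContingencyTable2x2(a, urc_ctrl - a, c, urc_case - c)
        chi2, p = chisq_test(table)
        rows.append((iv, table, chi2, p))
    if n_dropped:
        logger.info("dropped %d candidates with zero reads in both samples",
                    n_dropped)
    if not rows:
        return []
    qvals = bh_adjust(np.array([r[3] for r in rows]))
    out: List[DMR] = []
    for (iv, table, chi2, p), q in zip(rows, qvals):
        prop_ctrl = table.a / (table.a + table.b)
        prop_case = table.c / (table.c + table.d)
        if prop_ctrl == 0:
            fold = np.inf
        else:
            fold = prop_case / prop_ctrl
        if q > q_max:
            continue
        if not (fold >= min_fold or fold <= 1.0 / min_fold):
            continue
        direction = "hyper" if fold > 1 else "hypo"
        out.append(DMR(iv, table, chi2, p, float(q), float(fold), direction))
    return out


def ultra_dmrs(
    per_sample_dmrs: Sequence[Sequence[DMR]],
    chrom_sizes: Dict[str, int],
    segment_bp: int = 500,
    min_overlap_bp: int = 250,
    min_support: Optional[int] = None,
) -> List[UltraDMR]:
    """Consensus 500 bp segments supported by same-direction DMRs.

    A sample supports a segment/direction when one of its DMRs of that
    direction overlaps the segment by strictly more than
    ``min_overlap_bp``.  Segments are emitted when the support exceeds
    half the number of samples (or reaches ``min_support`` if given).  A
    segment qualifying in both directions is dropped and logged.
    """
    n_samples = len(per_sample_dmrs)
    if n_samples == 0:
        return []
    threshold = (min_support if min_support is not None
                 else n_samples // 2 + 1)

    support: Dict[Tuple[str, int, str], set] = {}
    for si, dmrs in enumerate(per_sample_dmrs):
        for d in dmrs:
            chrom = d.interval.chrom
            size = chrom_sizes.get(chrom)
            if size is None:
                continue
            first = d.interval.start // segment_bp
            last = (d.interval.end - 1) // segment_bp
            for seg in range(first, last + 1):
                s0 = seg * segment_bp
                s1 = min(s0 + segment_bp, size)
                ov = min(d.interval.end, s1) - max(d.interval.start, s0)
                if ov > min_overlap_bp:
                    support.setdefault((chrom, seg, d.direction), set()).add(si)

    qualified: Dict[Tuple[str, int], List[Tuple[str, int]]] = {}
    for (chrom, seg, direction), samples in support.items():
        if len(samples) >= threshold:
            qualified.setdefault((chrom, seg), []).append(
                (direction, len(samples))
            )
    out: List[UltraDMR] = []
    n_conflicts = 0
    for (chrom, seg), hits in sorted(qualified.items()):
        if len(hits) > 1:
            n_conflicts += 1
            continue
        direction, n_sup = hits[0]
        s0 = seg * segment_bp
        s1 = min(s0 + segment_bp, chrom_sizes[chrom])
        out.append(
            UltraDMR(GenomicInterval(chrom, s0, s1), direction, n_sup, n_samples)
        )
    if n_conflicts:
        logger.info("dropped %d segments supported in both directions",
                    n_conflicts)
    return out


def write_dmrs(dmrs: Sequence[DMR], path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# chrom\tstart\tend\tdirection\ta\tb\tc\td\tchi2\tp\tq\tfold\n")
        for d in dmrs:
            t = d.table
            fh.write(
                f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t"
                f"{d.direction}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                f"{d.chi2:.6g}\t{d.p_value:.6g}\t{d.q_value:.6g}\t{d.fold:.6g}\n"
            )


def write_ultra_dmrs(ultras: Sequence[UltraDMR], path,
                     header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# chrom\tstart\tend\tdirection\tsupport\tn_samples\n")
        for u in ultras:
            fh.write(
                f"{u.segment.chrom}\t{u.segment.start}\t{u.segment.end}\t"
                f"{u.direction}\t{u.support}\t{u.n_samples}\n"
            )
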