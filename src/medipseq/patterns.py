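"""Promoter methylation-pattern taxonomy.

Each (unclipped) 4 kb promoter is divided into forty 100 bp windows,
ordered 5' to 3' in gene orientation.  A window is "methylated" when a
methylation peak overlaps it, and "CGI-covered" when a CpG island does.
The joint layout of the two masks assigns one of five patterns:

* CGI_CONFINED  - methylation mostly confined to the island: the
  methylated/CGI window overlap exceeds half the methylated windows or
  half the CGI windows;
* SHORE_5PRIME  - methylation 5' of the island, not extending past it;
* SHORE_3PRIME  - methylation 3' of the island, not extending past it;
* CGI_OVERLAP   - methylation straddles the island without confinement;
* NO_CGI        - the promoter has no island.

Promoters aberrantly methylated in at least four of the case samples but
not the control are "case-specific"; promoters methylated in the control
and in at most (n_case - 4) cases are "control-specific".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .genome_features import CGI, PromoterAnnotation
from .intervals import GenomicInterval, IntervalIndex
from .peaks import Peak

N_WINDOWS = 40
PATTERNS = ("CGI_CONFINED", "SHORE_5PRIME", "SHORE_3PRIME", "CGI_OVERLAP",
            "NO_CGI")


@dataclass
class PromoterMask:
    """40-window methylation and CGI occupancy masks of one promoter."""

    gene_id: str
    methyl_mask: np.ndarray  # (40,) bool, window 1 most 5' in gene orientation
    cgi_mask: np.ndarray
    clipped: bool = False

    def __post_init__(self) -> None:
        self.methyl_mask = np.asarray(self.methyl_mask, dtype=bool)
        self.cgi_mask = np.asarray(self.cgi_mask, dtype=bool)
        if self.methyl_mask.shape != (N_WINDOWS,) or \
                self.cgi_mask.shape != (N_WINDOWS,):
            raise ValueError(f"masks must have exactly {N_WINDOWS} windows")

    @property
    def methylated(self) -> bool:
        return bool(self.methyl_mask.any())

    def as_strings(self):
        to_s = lambda m: "".join("1" if x else "0" for x in m)
        return to_s(self.methyl_mask), to_s(self.cgi_mask)


@dataclass
class PatternCall:
    gene_id: str
    pattern: str
    specificity: str  # case_specific | control_specific
    n_supporting_samples: int
    mask: Optional[PromoterMask] = None


def _window_occupancy(
    promoter: PromoterAnnotation,
    intervals: Sequence[GenomicInterval],
    window_bp: int,
    min_overlap_bp: int,
) -> np.ndarray:
    """Genomic-order boolean occupancy of the promoter's windows."""
    iv = promoter.interval
    n_geno = iv.length // window_bp + (1 if iv.length % window_bp else 0)
    mask = np.zeros(n_geno, dtype=bool)
    for other in intervals:
        if other.chrom != iv.chrom:
            continue
        lo = max(other.start, iv.start)
        hi = min(other.end, iv.end)
        if hi - lo < min_overlap_bp:
            continue
        first = (lo - iv.start) // window_bp
        last = (hi - 1 - iv.start) // window_bp
        for w in range(first, last + 1):
            ws = iv.start + w * window_bp
            we = min(ws + window_bp, iv.end)
            if min(hi, we) - max(lo, ws) >= min_overlap_bp:
                mask[w] = True
    return mask


def binarize_promoter(
    promoter: PromoterAnnotation,
    peaks: Sequence[Peak],
    cgis: Sequence[CGI],
    window_bp: int = 100,
    min_overlap_bp: int = 1,
) -> PromoterMask:
    """Build the 40-window methylation and CGI masks of one promoter.

    Windows are ordered 5'->3' in gene orientation (minus-strand
    promoters are reversed).  Clipped promoters are padded with
    unmethylated windows on the truncated side and flagged.
    """
    methyl = _window_occupancy(promoter, [p.interval for p in peaks],
                               window_bp, min_overlap_bp)
    cgi = _window_occupancy(promoter, [c.interval for c in cgis],
                            window_bp, min_overlap_bp)
    clipped = len(methyl) < N_WINDOWS
    if clipped:
        # pad on the genomic side that was truncated (the side nearer 0
        # pads on the left; otherwise on the right)
        pad = N_WINDOWS - len(methyl)
        if promoter.interval.start == 0:
            methyl = np.concatenate([np.zeros(pad, bool), methyl])
            cgi = np.concatenate([np.zeros(pad, bool), cgi])
        else:
            methyl = np.concatenate([methyl, np.zeros(pad, bool)])
            cgi = np.concatenate([cgi, np.zeros(pad, bool)])
    methyl = methyl[:N_WINDOWS]
    cgi = cgi[:N_WINDOWS]
    if promoter.interval.strand == "-":
        methyl = methyl[::-1]
        cgi = cgi[::-1]
    return PromoterMask(promoter.gene_id, methyl, cgi, clipped=clipped)


def classify_pattern(mask: PromoterMask) -> str:
    """Assign one of the five promoter methylation patterns.

    Decision order: NO_CGI, CGI_CONFINED, SHORE_5PRIME, SHORE_3PRIME,
    CGI_OVERLAP — from most to least specific, so exactly one pattern
    fires.  Requires at least one methylated window.
    """
    m = mask.methyl_mask
    c = mask.cgi_mask
    if not m.any():
        raise ValueError("cannot classify an unmethylated promoter")
    if not c.any():
        return "NO_CGI"
    overlap = int((m & c).sum())
    if overlap > m.sum() / 2 or overlap > c.sum() / 2:
        return "CGI_CONFINED"
    cgi_windows = np.flatnonzero(c)
    meth_windows = np.flatnonzero(m)
    # flanking patterns: methylation lies to one side of the island and
    # does not extend past it (minor edge overlap is tolerated here --
    # peak boundaries are coarser than the 100 bp windows -- because the
    # confinement rule above has already failed)
    before = bool((meth_windows < cgi_windows.min()).any())
    after = bool((meth_windows > cgi_windows.max()).any())
    if before and not after:
        return "SHORE_5PRIME"
    if after and not before:
        return "SHORE_3PRIME"
    return "CGI_OVERLAP"


def select_specific_promoters(
    case_masks: Dict[str, Dict[str, PromoterMask]],
    control_masks: Dict[str, PromoterMask],
    min_case_support: int = 4,
) -> List[PatternCall]:
    """Case-specific and control-specific promoter pattern calls.

    ``case_masks`` maps sample id -> gene id -> mask.  A promoter is
    case-specific when methylated in at least ``min_case_support`` case
    samples and unmethylated in the control; its pattern is computed on
    the union of the supporting samples' methylation masks.  It is
    control-specific when methylated in the control and methylated in at
    most (n_case - min_case_support) case samples; its pattern uses the
    control mask.
    """
    n_case = len(case_masks)
    sample_ids = sorted(case_masks)
    gene_ids = sorted(control_masks)
    calls: List[PatternCall] = []
    for gid in gene_ids:
        ctrl = control_masks[gid]
        supporting = [
            sid for sid in sample_ids
            if gid in case_masks[sid] and case_masks[sid][gid].methylated
        ]
        n_sup = len(supporting)
        if n_sup >= min_case_support and not ctrl.methylated:
            union = np.zeros(N_WINDOWS, dtype=bool)
            for sid in supporting:
                union |= case_masks[sid][gid].methyl_mask
            mask = PromoterMask(gid, union, ctrl.cgi_mask)
            calls.append(
                PatternCall(gid, classify_pattern(mask), "case_specific",
                            n_sup, mask)
            )
        elif ctrl.methylated and n_sup <= n_case - min_case_support:
            calls.append(
                PatternCall(gid, classify_pattern(ctrl), "control_specific",
                            n_sup, ctrl)
            )
    return calls


def write_pattern_calls(calls: Sequence[PatternCall], path,
                        header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# gene_id\tspecificity\tpattern\tn_supporting_samples\t"
                 "methyl_mask\tcgi_mask\n")
        for call in calls:
            ms, cs = call.mask.as_strings() if call.mask else ("." * 40, "." * 40)
            fh.write(
                f"{call.gene_id}\t{call.specificity}\t{call.pattern}\t"
                f"{call.n_supporting_samples}\t{ms}\t{cs}\n"
            )
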