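"""Per-sample methylation peak calling against a dynamic Poisson background.

Sliding windows are scanned along each chromosome and scored with a
Poisson upper-tail p-value whose expectation is locally adaptive:

    lambda_local = max(lambda_BG, lambda_5k, lambda_10k)

where lambda_BG is the genome-wide rate scaled to the window width and
lambda_5k / lambda_10k come from the read counts in centered 5 kb /
10 kb spans, excluding the scored window itself and rescaled to window
width.  Taking the maximum makes the test conservative inside locally
enriched neighbourhoods, the standard guard against chromatin- and
mappability-driven rate fluctuations; excluding the window keeps the
local estimate free of self-contamination, which would otherwise make
the null rejection rate far below its nominal level.  Windows with
p < 1e-5 are significant; overlapping or near-adjacent significant
windows are merged into peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats

from .intervals import AlignedReadSet, GenomicInterval

DEFAULT_P_THRESHOLD = 1e-5


@dataclass
class PeakParams:
    window_bp: int = 500
    step_bp: int = 100
    fragment_extension_bp: int = 200
    local_scales_bp: Tuple[int, ...] = (5000, 10000)
    p_threshold: float = DEFAULT_P_THRESHOLD
    merge_gap_bp: int = 200

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must be <= window_bp")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")


@dataclass
class Peak:
    interval: GenomicInterval
    read_count: int          # distinct reads in the merged interval
    lambda_local: float      # background expectation of the best window
    p_value: float           # min p over member windows
    window_count: int = 0    # read count of the best (min-p) window

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must be in (0, 1]")
        if self.lambda_local <= 0:
            raise ValueError("lambda_local must be positive")


def poisson_pvalue(k, lam):
    """Upper-tail Poisson probability P(X >= k) at expectation ``lam``.

    Vectorized; ``k = 0`` gives exactly 1.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("lam must be positive")
    k_arr = np.asarray(k)
    if np.any(k_arr < 0):
        raise ValueError("k must be >= 0")
    p = stats.poisson.sf(k_arr - 1, lam_arr)
    if np.isscalar(k) and np.isscalar(lam):
        return float(p)
    return p


def _span_counts(
    mids: np.ndarray, centers: np.ndarray, span: int, chrom_size: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Read counts and actual lengths of spans centered on ``centers``, clipped."""
    lo = np.clip(centers - span // 2, 0, chrom_size)
    hi = np.clip(centers + span // 2, 0, chrom_size)
    counts = np.searchsorted(mids, hi) - np.searchsorted(mids, lo)
    return counts, (hi - lo)


def local_lambda(
    window: GenomicInterval,
    reads: AlignedReadSet,
    genome_background_rate: float,
    params: PeakParams = None,
) -> float:
    """Expected read count of one window under the dynamic background.

    ``genome_background_rate`` is the genome-wide expected count per bp
    (URC / genome length).  Local spans exclude the scored window itself
    and are rescaled to window width; spans clipped at chromosome edges
    use their actual length.
    """
    params = params or PeakParams()
    mids = reads.midpoints(window.chrom)
    wlen = window.length
    lam = genome_background_rate * wlen
    center = np.array([(window.start + window.end) // 2])
    chrom_size = int(mids[-1]) + 1 if len(mids) else window.end
    k_window = int(np.searchsorted(mids, window.end)
                   - np.searchsorted(mids, window.start))
    for span in params.local_scales_bp:
        counts, lens = _span_counts(mids, center, span, max(chrom_size, window.end))
        if lens[0] > wlen:
            lam = max(lam, float(counts[0] - k_window) * wlen
                      / float(lens[0] - wlen))
    return lam


def _extend_fragments(arr: np.ndarray, ext: int, chrom_size: int) -> np.ndarray:
    """Midpoints after extending each read to ``ext`` bp from its start."""
    starts = arr[:, 0]
    ends = np.maximum(arr[:, 1], np.minimum(starts + ext, chrom_size))
    return np.sort((starts + ends) // 2)


def call_peaks(
    sample: AlignedReadSet,
    chrom_sizes: Dict[str, int],
    params: PeakParams = None,
) -> List[Peak]:
    """Scan all chromosomes and return merged significant peaks.

    Each emitted peak has p < ``params.p_threshold``; merged peaks keep
    the minimum member-window p-value and the distinct read count of the
    merged interval.  Output is coordinate-sorted and deterministic.
    """
    params = params or PeakParams()
    genome_len = sum(chrom_sizes.values())
    bg_rate = sample.urc / genome_len
    peaks: List[Peak] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        arr = sample.reads.get(chrom)
        if arr is None or len(arr) == 0:
            continue
        mids = _extend_fragments(arr, params.fragment_extension_bp, size)
        starts = np.arange(0, max(1, size - params.window_bp + 1), params.step_bp,
                           dtype=np.int64)
        ends = np.minimum(starts + params.window_bp, size)
        wlens = ends - starts
        counts = np.searchsorted(mids, ends) - np.searchsorted(mids, starts)
        lam = bg_rate * wlens.astype(float)
        centers = (starts + ends) // 2
        for span in params.local_scales_bp:
            sc, sl = _span_counts(mids, centers, span, size)
            rest_len = sl - wlens
            lam_span = np.where(
                rest_len > 0,
                (sc - counts) * wlens / np.maximum(rest_len, 1), 0.0)
            lam = np.maximum(lam, lam_span)
        pvals = stats.poisson.sf(counts - 1, lam)
        sig = np.flatnonzero(pvals < params.p_threshold)
        if len(sig) == 0:
            continue
        # merge significant windows with gap <= merge_gap_bp
        runs: List[Tuple[int, int, float, float, int]] = []
        cur_s, cur_e = int(starts[sig[0]]), int(ends[sig[0]])
        cur_p, cur_l = float(pvals[sig[0]]), float(lam[sig[0]])
        cur_k = int(counts[sig[0]])
        for i in sig[1:]:
            ws, we = int(starts[i]), int(ends[i])
            if ws <= cur_e + params.merge_gap_bp:
                cur_e = max(cur_e, we)
                if pvals[i] < cur_p:
                    cur_p, cur_l = float(pvals[i]), float(lam[i])
                    cur_k = int(counts[i])
            else:
                runs.append((cur_s, cur_e, cur_p, cur_l, cur_k))
                cur_s, cur_e, cur_p = ws, we, float(pvals[i])
                cur_l, cur_k = float(lam[i]), int(counts[i])
        runs.append((cur_s, cur_e, cur_p, cur_l, cur_k))
        for s, e, p, l, k in runs:
            rc = int(np.searchsorted(mids, e) - np.searchsorted(mids, s))
            peaks.append(
                Peak(GenomicInterval(chrom, s, e), read_count=rc,
                     lambda_local=l, p_value=max(p, 5e-324), window_count=k)
            )
    return peaks


def significant_window_count(
    sample: AlignedReadSet,
    chrom_sizes: Dict[str, int],
    params: PeakParams = None,
) -> Tuple[int, int]:
    """(number of significant windows, total windows) before merging.

    Used for null calibration of the window-level false positive rate.
    """
    params = params or PeakParams()
    genome_len = sum(chrom_sizes.values())
    bg_rate = sample.urc / genome_len
    n_sig = 0
    n_tot = 0
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        arr = sample.reads.get(chrom)
        mids = (_extend_fragments(arr, params.fragment_extension_bp, size)
                if arr is not None and len(arr) else np.empty(0, dtype=np.int64))
        starts = np.arange(0, max(1, size - params.window_bp + 1), params.step_bp,
                           dtype=np.int64)
        ends = np.minimum(starts + params.window_bp, size)
        wlens = ends - starts
        counts = np.searchsorted(mids, ends) - np.searchsorted(mids, starts)
        lam = bg_rate * wlens.astype(float)
        centers = (starts + ends) // 2
        for span in params.local_scales_bp:
            sc, sl = _span_counts(mids, centers, span, size)
            rest_len = sl - wlens
            lam_span = np.where(
                rest_len > 0,
                (sc - counts) * wlens / np.maximum(rest_len, 1), 0.0)
            lam = np.maximum(lam, lam_span)
        pvals = stats.poisson.sf(counts - 1, lam)
        n_sig += int((pvals < params.p_threshold).sum())
        n_tot += len(starts)
    return n_sig, n_tot


def write_peaks(peaks: List[Peak], path) -> None:
    """BED6+ serialization: chrom, start, end, name, -log10 p, strand, rc, lambda."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = -np.log10(p.p_value)
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"peak_{i + 1}\t{score:.3f}\t.\t{p.read_count}\t"
                f"{p.lambda_local:.4f}\n"
            )


def read_peaks(path) -> List[Peak]:
    peaks: List[Peak] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            p_value = 10.0 ** (-float(f[4]))
            peaks.append(
                Peak(GenomicInterval(f[0], int(f[1]), int(f[2])),
                     read_count=int(f[6]), lambda_local=float(f[7]),
                     p_value=min(1.0, max(p_value, 5e-324)))
            )
    return peaks
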