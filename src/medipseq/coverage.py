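"""Genome binning, library-size normalization, and sample correlation.

The genome is tiled into fixed-size bins (10 kb for global methylation
maps, 500 bp for the consensus-segment grid).  Each read is assigned to
exactly one bin by its fragment midpoint, and raw counts are normalized
to reads-per-million:

    AM = RC * 1e6 / URC

where RC is the bin's read count and URC the sample's unique mapped read
count.  Pairwise Pearson correlation of the normalized vectors gives the
global between-sample similarity map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .intervals import AlignedReadSet


@dataclass
class BinnedCoverage:
    """Per-bin raw (RC) and normalized (AM) coverage for one sample."""

    sample_id: str
    bin_size_bp: int
    urc: int
    chrom_sizes: Dict[str, int]
    rc: Dict[str, np.ndarray] = field(default_factory=dict)
    am: Dict[str, np.ndarray] = field(default_factory=dict)
    n_rejected: int = 0

    def n_bins(self, chrom: str) -> int:
        size = self.chrom_sizes[chrom]
        return (size + self.bin_size_bp - 1) // self.bin_size_bp

    def concatenated(self, which: str = "am") -> np.ndarray:
        track = self.am if which == "am" else self.rc
        return np.concatenate([track[c] for c in sorted(self.chrom_sizes)])


def bin_counts(
    reads: AlignedReadSet,
    bin_size_bp: int,
    chrom_sizes: Dict[str, int],
) -> BinnedCoverage:
    """Count reads per bin by fragment midpoint.

    Bins tile each chromosome exactly; the final bin may be ragged.
    Reads whose midpoint lies beyond the chromosome end are rejected and
    counted in ``n_rejected``.
    """
    cov = BinnedCoverage(
        sample_id=reads.sample_id, bin_size_bp=bin_size_bp, urc=reads.urc,
        chrom_sizes=dict(chrom_sizes),
    )
    rejected = 0
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        nb = (size + bin_size_bp - 1) // bin_size_bp
        mids = reads.midpoints(chrom)
        ok = (mids >= 0) & (mids < size)
        rejected += int((~ok).sum())
        idx = mids[ok] // bin_size_bp
        cov.rc[chrom] = np.bincount(idx, minlength=nb).astype(np.int64)
    for chrom in set(reads.reads) - set(chrom_sizes):
        rejected += reads.n_reads(chrom)
    cov.n_rejected = rejected
    return cov


def normalize_am(cov: BinnedCoverage) -> BinnedCoverage:
    """Fill AM = RC * 1e6 / URC for every bin (in place; returns ``cov``)."""
    if cov.urc <= 0:
        raise ValueError("URC must be positive to normalize")
    for chrom, rc in cov.rc.items():
        cov.am[chrom] = rc * 1e6 / cov.urc
    return cov


def correlation_matrix(
    samples: List[BinnedCoverage],
    drop_all_zero: bool = True,
) -> np.ndarray:
    """Pairwise Pearson correlation of normalized coverage vectors.

    Bins that are zero in every sample are excluded (they carry no
    signal and would inflate the correlation).  A sample with constant
    AM has undefined correlation, reported as NaN rather than 0.
    """
    if not samples:
        return np.empty((0, 0))
    ref = samples[0]
    for s in samples[1:]:
        if s.bin_size_bp != ref.bin_size_bp or s.chrom_sizes != ref.chrom_sizes:
            raise ValueError("samples must share binning")
    mat = np.vstack([s.concatenated("am") for s in samples])
    if drop_all_zero:
        keep = mat.sum(axis=0) > 0
        mat = mat[:, keep]
    n = len(samples)
    out = np.full((n, n), np.nan)
    sd = mat.std(axis=1)
    for i in range(n):
        for j in range(i, n):
            if sd[i] == 0 or sd[j] == 0:
                r = np.nan if i != j else 1.0
            else:
                r = float(np.corrcoef(mat[i], mat[j])[0, 1])
            out[i, j] = out[j, i] = r
    np.fill_diagonal(out, 1.0)
    return out


def write_bedgraph(cov: BinnedCoverage, path) -> None:
    """Serialize normalized coverage as bedGraph plus a JSON sidecar."""
    with open(path, "w") as fh:
        for chrom in sorted(cov.chrom_sizes):
            am = cov.am.get(chrom)
            if am is None:
                continue
            size = cov.chrom_sizes[chrom]
            for i, v in enumerate(am):
                start = i * cov.bin_size_bp
                end = min(start + cov.bin_size_bp, size)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")
    with open(str(path) + ".json", "w") as fh:
        json.dump(
            {"sample_id": cov.sample_id, "urc": cov.urc,
             "bin_size_bp": cov.bin_size_bp, "n_rejected": cov.n_rejected},
            fh, sort_keys=True, indent=1,
        )
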