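"""Genomic feature annotation: genes, promoters, CpG islands, shores, bands.

Derives the feature sets the downstream analysis interrogates:

* promoters as TSS +/- 2 kb (strand-aware),
* putative miRNA promoters as the 2 kb upstream of each precursor,
* CpG islands from a UCSC ``cpgIslandExt``-style table (islands on
  ``*_random`` contigs are excluded),
* CGI shores as the 2 kb regions flanking each island, truncated where a
  neighboring island is nearer, so that no base is both shore and island,
* promoter CpG-content classes (LCP / ICP / HCP) by the sliding-window
  CpG-ratio scheme commonly used to stratify mammalian promoters,
* CGI length classes by length tertile.

All parsers are plain-text TSV/BED dialects; comment lines starting with
``#`` are tolerated everywhere.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval, IntervalIndex

logger = logging.getLogger(__name__)

# Sliding-window CpG-class thresholds (high / low CpG-content promoter).
HCP_CPG_RATIO = 0.75
HCP_GC = 0.55
LCP_CPG_RATIO = 0.48
CPG_WINDOW_BP = 500
CPG_WINDOW_STEP = 5


@dataclass
class GeneModel:
    """A gene with its genomic span, strand-resolved TSS, and transcript lengths."""

    gene_id: str
    interval: GenomicInterval
    transcript_lengths: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.transcript_lengths):
            raise ValueError(f"{self.gene_id}: transcript lengths must be positive")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand != "-" else self.interval.end

    @property
    def longest_transcript(self) -> int:
        if self.transcript_lengths:
            return max(self.transcript_lengths)
        return self.interval.length


@dataclass
class CGI:
    """A CpG island with its observed CpG count and (optional) length class."""

    interval: GenomicInterval
    cpg_count: int = 0
    length_class: Optional[str] = None  # short | medium | long

    def __post_init__(self) -> None:
        if self.cpg_count < 0:
            raise ValueError("cpg_count must be >= 0")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class Shore:
    """A CGI shore: up to 2 kb flanking one side of an island.

    ``side`` is 'left'/'right' in genomic coordinates; ``orientation``
    resolves 5'/3' with respect to the associated gene's strand ('+' for
    intergenic islands).
    """

    interval: GenomicInterval
    cgi_index: int
    side: str  # left | right (genomic)
    orientation: str  # 5p | 3p (gene-oriented)


@dataclass
class PromoterAnnotation:
    gene_id: str
    interval: GenomicInterval
    tss: int
    cpg_ratio: Optional[float] = None
    gc_content: Optional[float] = None
    cpg_class: Optional[str] = None  # LCP | ICP | HCP
    overlapping_cgis: List[int] = field(default_factory=list)  # indices into cgis
    clipped: bool = False


@dataclass
class Band:
    interval: GenomicInterval
    name: str  # e.g. "chr1:p11"


@dataclass
class GenomeAnnotation:
    """Aggregate of all annotated feature tracks, indexed for overlap queries."""

    chrom_sizes: Dict[str, int]
    genes: List[GeneModel] = field(default_factory=list)
    promoters: List[PromoterAnnotation] = field(default_factory=list)
    mirna_promoters: List[GenomicInterval] = field(default_factory=list)
    cgis: List[CGI] = field(default_factory=list)
    shores: List[Shore] = field(default_factory=list)
    bands: List[Band] = field(default_factory=list)
    repeats: List[Tuple[GenomicInterval, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._indexes: Dict[str, IntervalIndex] = {}

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def index(self, track: str) -> IntervalIndex:
        """Lazily build and cache an overlap index for a feature track."""
        if track not in self._indexes:
            idx = IntervalIndex()
            if track == "promoter":
                for i, p in enumerate(self.promoters):
                    idx.add(p.interval, i)
            elif track == "cgi":
                for i, c in enumerate(self.cgis):
                    idx.add(c.interval, i)
            elif track == "shore":
                for i, s in enumerate(self.shores):
                    idx.add(s.interval, i)
            elif track == "gene":
                for i, g in enumerate(self.genes):
                    idx.add(g.interval, i)
            elif track == "repeat":
                for i, (iv, fam) in enumerate(self.repeats):
                    idx.add(iv, (i, fam))
            elif track == "mirna_promoter":
                for i, iv in enumerate(self.mirna_promoters):
                    idx.add(iv, i)
            else:
                raise KeyError(f"unknown feature track {track!r}")
            self._indexes[track] = idx
        return self._indexes[track]

    def validate(self) -> None:
        """Check that every feature lies within its chromosome."""
        def check(iv: GenomicInterval, what: str) -> None:
            size = self.chrom_sizes.get(iv.chrom)
            if size is None:
                raise ValueError(f"{what}: unknown chromosome {iv.chrom}")
            if iv.end > size:
                raise ValueError(
                    f"{what}: interval {iv.chrom}:{iv.start}-{iv.end} "
                    f"exceeds chromosome size {size}"
                )

        for g in self.genes:
            check(g.interval, f"gene {g.gene_id}")
        for c in self.cgis:
            check(c.interval, "CGI")
        for s in self.shores:
            check(s.interval, "shore")
        for b in self.bands:
            check(b.interval, f"band {b.name}")
        for iv, fam in self.repeats:
            check(iv, f"repeat {fam}")


# ---------------------------------------------------------------------------
# Parsers


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_chrom_sizes(path) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
        try:
            sizes[fields[0]] = int(fields[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer size") from exc
    return sizes


def read_genes(path) -> List[GeneModel]:
    """Read gene models from a refFlat-style TSV or a GTF file.

    refFlat dialect: geneName, chrom, strand, txStart, txEnd
    [, comma-separated transcript lengths].  GTF is detected by the
    ``.gtf`` extension; only ``transcript`` records are used and 1-based
    inclusive coordinates are converted to 0-based half-open.
    """
    if str(path).endswith(".gtf"):
        return _read_genes_gtf(path)
    genes: List[GeneModel] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(
                f"{path}:{lineno}: expected >=5 refFlat columns, got {len(fields)}"
            )
        name, chrom, strand = fields[0], fields[1], fields[2]
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        lengths: List[int] = []
        if len(fields) >= 6 and fields[5]:
            lengths = [int(x) for x in fields[5].rstrip(",").split(",")]
        try:
            iv = GenomicInterval(chrom, start, end, strand)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        genes.append(GeneModel(name, iv, lengths))
    return genes


def _read_genes_gtf(path) -> List[GeneModel]:
    by_gene: Dict[str, dict] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
        if fields[2] != "transcript":
            continue
        chrom, start1, end, strand, attrs = (
            fields[0],
            fields[3],
            fields[4],
            fields[6],
            fields[8],
        )
        gene_id = None
        for attr in attrs.split(";"):
            attr = attr.strip()
            if attr.startswith("gene_id"):
                gene_id = attr.split(None, 1)[1].strip('"')
        if gene_id is None:
            raise ValueError(f"{path}:{lineno}: transcript without gene_id")
        start = int(start1) - 1  # GTF is 1-based inclusive
        end = int(end)
        rec = by_gene.setdefault(
            gene_id, {"chrom": chrom, "strand": strand, "start": start, "end": end,
                      "lengths": []}
        )
        rec["start"] = min(rec["start"], start)
        rec["end"] = max(rec["end"], end)
        rec["lengths"].append(end - start)
    return [
        GeneModel(
            gid,
            GenomicInterval(r["chrom"], r["start"], r["end"], r["strand"]),
            r["lengths"],
        )
        for gid, r in by_gene.items()
    ]


def read_cgis(path, exclude_random: bool = True) -> List[CGI]:
    """Read CpG islands from a UCSC ``cpgIslandExt``-style table.

    Expected columns: chrom, chromStart, chromEnd, name ("CpG: N"),
    length, cpgNum, ...; whitespace-delimited rows (where the name field
    spans two tokens) are tolerated.
    """
    cgis: List[CGI] = []
    n_random = 0
    for lineno, line in _data_lines(path):
        if "\t" in line:
            fields = line.split("\t")
        else:
            toks = line.split()
            # re-join the two-token "CpG: N" name field
            if len(toks) >= 5 and toks[3] == "CpG:":
                toks[3:5] = [" ".join(toks[3:5])]
            fields = toks
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 cpgIslandExt columns")
        chrom = fields[0]
        if exclude_random and "random" in chrom:
            n_random += 1
            continue
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        cpg_count = 0
        if len(fields) >= 6:
            cpg_count = int(fields[5])
        try:
            iv = GenomicInterval(chrom, start, end)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        cgis.append(CGI(iv, cpg_count))
    if n_random:
        logger.info("excluded %d CGIs on 'random' chromosomes", n_random)
    return cgis


def read_bands(path) -> List[Band]:
    """Read cytogenetic bands from a UCSC cytoBand-style TSV."""
    bands: List[Band] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected >=4 cytoBand columns")
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        bands.append(Band(GenomicInterval(chrom, start, end), f"{chrom}:{name}"))
    return bands


def read_repeats(path) -> List[Tuple[GenomicInterval, str]]:
    """Read repeat intervals from BED; column 4 (if present) is the family."""
    repeats: List[Tuple[GenomicInterval, str]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
        fam = fields[3] if len(fields) >= 4 else "repeat"
        repeats.append(
            (GenomicInterval(fields[0], int(fields[1]), int(fields[2])), fam)
        )
    return repeats


def read_annotation(
    gene_path,
    cgi_path,
    band_path=None,
    repeat_path=None,
    chrom_sizes_path=None,
    mirna_path=None,
    flank_bp: int = 2000,
    shore_bp: int = 2000,
) -> GenomeAnnotation:
    """Parse all annotation inputs and derive promoters, shores, and classes."""
    chrom_sizes = read_chrom_sizes(chrom_sizes_path)
    genes = read_genes(gene_path)
    cgis = read_cgis(cgi_path)
    classify_cgi_length(cgis)
    bands = read_bands(band_path) if band_path else []
    repeats = read_repeats(repeat_path) if repeat_path else []
    mirnas = []
    if mirna_path:
        for lineno, line in _data_lines(mirna_path):
            fields = line.split("\t")
            strand = fields[3] if len(fields) >= 4 else "+"
            mirnas.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    ann = GenomeAnnotation(
        chrom_sizes=chrom_sizes,
        genes=genes,
        cgis=cgis,
        bands=bands,
        repeats=repeats,
    )
    ann.promoters = derive_promoters(genes, flank_bp=flank_bp, chrom_sizes=chrom_sizes)
    ann.mirna_promoters = derive_mirna_promoters(mirnas, chrom_sizes=chrom_sizes)
    ann.shores = derive_shores(cgis, width_bp=shore_bp, chrom_sizes=chrom_sizes,
                               genes=genes)
    _attach_promoter_cgis(ann)
    ann.validate()
    return ann


def write_annotation(ann: GenomeAnnotation, outdir) -> None:
    """Serialize the annotation back to its input dialects (round-trippable)."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
        for chrom in sorted(ann.chrom_sizes):
            fh.write(f"{chrom}\t{ann.chrom_sizes[chrom]}\n")
    with open(os.path.join(outdir, "genes.refflat.tsv"), "w") as fh:
        for g in ann.genes:
            lengths = ",".join(str(l) for l in g.transcript_lengths)
            fh.write(
                f"{g.gene_id}\t{g.interval.chrom}\t{g.strand}\t"
                f"{g.interval.start}\t{g.interval.end}\t{lengths}\n"
            )
    with open(os.path.join(outdir, "cpgislands.tsv"), "w") as fh:
        for c in ann.cgis:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"CpG: {c.cpg_count}\t{c.length}\t{c.cpg_count}\n"
            )
    with open(os.path.join(outdir, "cytobands.tsv"), "w") as fh:
        for b in ann.bands:
            name = b.name.split(":", 1)[1] if ":" in b.name else b.name
            fh.write(
                f"{b.interval.chrom}\t{b.interval.start}\t{b.interval.end}\t"
                f"{name}\tgneg\n"
            )
    with open(os.path.join(outdir, "repeats.bed"), "w") as fh:
        for iv, fam in ann.repeats:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fam}\n")


# ---------------------------------------------------------------------------
# Derivations


def derive_promoters(
    genes: Sequence[GeneModel],
    flank_bp: int = 2000,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> List[PromoterAnnotation]:
    """Promoter = [TSS - flank, TSS + flank), clipped to chromosome bounds."""
    promoters: List[PromoterAnnotation] = []
    for g in genes:
        tss = g.tss
        start = tss - flank_bp
        end = tss + flank_bp
        clipped = False
        if start < 0:
            start = 0
            clipped = True
        if chrom_sizes is not None:
            size = chrom_sizes.get(g.interval.chrom)
            if size is not None and end > size:
                end = size
                clipped = True
        if clipped:
            logger.warning(
                "promoter of %s clipped to %s:%d-%d", g.gene_id,
                g.interval.chrom, start, end,
            )
        promoters.append(
            PromoterAnnotation(
                gene_id=g.gene_id,
                interval=GenomicInterval(g.interval.chrom, start, end, g.strand),
                tss=tss,
                clipped=clipped,
            )
        )
    return promoters


def derive_mirna_promoters(
    precursors: Sequence[GenomicInterval],
    flank_bp: int = 2000,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> List[GenomicInterval]:
    """miRNA promoter = the 2 kb upstream of the precursor, strand-oriented."""
    out: List[GenomicInterval] = []
    for p in precursors:
        if p.strand == "-":
            start, end = p.end, p.end + flank_bp
        else:
            start, end = p.start - flank_bp, p.start
        start = max(0, start)
        if chrom_sizes is not None:
            size = chrom_sizes.get(p.chrom)
            if size is not None:
                end = min(end, size)
        if end > start:
            out.append(GenomicInterval(p.chrom, start, end, p.strand))
    return out


def derive_shores(
    cgis: Sequence[CGI],
    width_bp: int = 2000,
    chrom_sizes: Optional[Dict[str, int]] = None,
    genes: Optional[Sequence[GeneModel]] = None,
) -> List[Shore]:
    """Each CGI yields up to two flanking shores of at most ``width_bp``.

    A shore is truncated where a neighboring CGI is nearer than
    ``width_bp``, so shores never overlap any island.  5'/3' orientation
    follows the strand of the gene whose promoter region contains the
    island's midpoint ('+' when there is none).
    """
    strand_of: Dict[int, str] = {}
    if genes:
        gene_idx = IntervalIndex()
        for g in genes:
            tss = g.tss
            gene_idx.add(
                GenomicInterval(g.interval.chrom, max(0, tss - width_bp),
                                tss + width_bp), g.strand,
            )
        for i, c in enumerate(cgis):
            mid = (c.interval.start + c.interval.end) // 2
            hits = gene_idx.query(c.interval.chrom, mid, mid + 1)
            if hits:
                strand_of[i] = sorted(hits)[0]

    order = sorted(range(len(cgis)),
                   key=lambda i: (cgis[i].interval.chrom, cgis[i].interval.start))
    shores: List[Shore] = []
    for pos, i in enumerate(order):
        c = cgis[i].interval
        prev_end = 0
        next_start = chrom_sizes.get(c.chrom) if chrom_sizes else None
        if pos > 0:
            p = cgis[order[pos - 1]].interval
            if p.chrom == c.chrom:
                prev_end = max(prev_end, p.end)
        if pos + 1 < len(order):
            nxt = cgis[order[pos + 1]].interval
            if nxt.chrom == c.chrom:
                next_start = (nxt.start if next_start is None
                              else min(next_start, nxt.start))
        strand = strand_of.get(i, "+")
        left = (max(prev_end, c.start - width_bp), c.start)
        right_end = c.end + width_bp
        if next_start is not None:
            right_end = min(right_end, next_start)
        right = (c.end, right_end)
        for (s, e), side in ((left, "left"), (right, "right")):
            if e <= s:
                continue
            orientation = "5p" if (side == "left") == (strand != "-") else "3p"
            shores.append(
                Shore(GenomicInterval(c.chrom, s, e), cgi_index=i, side=side,
                      orientation=orientation)
            )
    return shores


def _attach_promoter_cgis(ann: GenomeAnnotation) -> None:
    cgi_idx = ann.index("cgi")
    for p in ann.promoters:
        hits = cgi_idx.query(p.interval.chrom, p.interval.start, p.interval.end)
        p.overlapping_cgis = sorted(hits)


def cpg_stats(sequence: str) -> Tuple[float, float]:
    """Return (cpg_ratio, gc_content) of a sequence.

    cpg_ratio = (#CG dinucleotides * L) / (#C * #G); 0 when #C or #G is 0.
    """
    seq = sequence.upper()
    L = len(seq)
    if L == 0:
        raise ValueError("empty sequence")
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cg = seq.count("CG")
    gc = (n_c + n_g) / L
    ratio = 0.0 if n_c == 0 or n_g == 0 else n_cg * L / (n_c * n_g)
    return ratio, gc


def classify_promoter_cpg(
    sequence: str,
    window_bp: int = CPG_WINDOW_BP,
    step_bp: int = CPG_WINDOW_STEP,
    hcp_ratio: float = HCP_CPG_RATIO,
    hcp_gc: float = HCP_GC,
    lcp_ratio: float = LCP_CPG_RATIO,
) -> Tuple[float, float, str]:
    """Classify a promoter sequence as LCP / ICP / HCP.

    HCP: some ``window_bp`` window has cpg_ratio >= ``hcp_ratio`` and
    GC >= ``hcp_gc``.  LCP: no window reaches cpg_ratio ``lcp_ratio``.
    ICP: everything else.  Sequences shorter than the window are treated
    as a single window.  Returns (whole-sequence cpg_ratio, gc_content,
    class).
    """
    seq = sequence.upper()
    ratio_all, gc_all = cpg_stats(seq)
    L = len(seq)
    w = min(window_bp, L)
    starts = range(0, L - w + 1, step_bp)
    is_hcp = False
    max_ratio = 0.0
    for s in starts:
        r, gc = cpg_stats(seq[s : s + w])
        max_ratio = max(max_ratio, r)
        if r >= hcp_ratio and gc >= hcp_gc:
            is_hcp = True
            break
    if is_hcp:
        cls = "HCP"
    elif max_ratio < lcp_ratio:
        cls = "LCP"
    else:
        cls = "ICP"
    return ratio_all, gc_all, cls


def classify_cgi_length(
    cgis: Sequence[CGI], long_quantile: float = 2.0 / 3.0
) -> Sequence[CGI]:
    """Assign short/medium/long length classes by tertile split (in place).

    Boundary lengths go to the lower class.  With fewer than 3 islands
    every island is 'medium'.
    """
    if len(cgis) < 3:
        if cgis:
            logger.warning("fewer than 3 CGIs: all assigned 'medium'")
        for c in cgis:
            c.length_class = "medium"
        return cgis
    lengths = np.array([c.length for c in cgis])
    lo = float(np.quantile(lengths, long_quantile / 2.0, method="lower"))
    hi = float(np.quantile(lengths, long_quantile, method="lower"))
    for c in cgis:
        if c.length <= lo:
            c.length_class = "short"
        elif c.length <= hi:
            c.length_class = "medium"
        else:
            c.length_class = "long"
    return cgis
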