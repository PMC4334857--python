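"""Expression quantification and methylation-expression integration.

RPKM (reads per kilobase of transcript per million mapped reads, using
each gene's longest transcript) quantifies expression.  Genes are ranked
by the log2 case/control ratio of mean RPKM with a pseudocount, and a
gene set's concentration at either extreme of the ranking is scored with
a weighted Kolmogorov-Smirnov enrichment score (ES):

    hits   contribute  |metric|^p / sum over hits of |metric|^p
    misses contribute  -1 / (N - Nh)

The ES is the running sum's signed maximum deviation; significance comes
from a seeded permutation null of random gene sets of the same size
(gene-set permutation: with a single control sample, phenotype
permutation is not available).  Pathway over-representation uses the
upper-tail hypergeometric test with BH adjustment and a minimum of two
overlapping genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import bh_adjust


@dataclass
class GseaResult:
    gene_set_name: str
    es: float
    perm_p: float
    n_perm: int
    seed: int
    set_size: int


@dataclass
class PathwayResult:
    pathway_id: str
    k_overlap: int
    set_size: int
    universe_size: int
    p_value: float
    q_value: float = np.nan
    flagged: bool = False


def compute_rpkm(
    counts: pd.DataFrame,
    length_col: str = "length",
    gene_col: str = "gene_id",
) -> pd.DataFrame:
    """RPKM = 1e9 * C / (N * L) for every sample column.

    ``counts`` has one row per gene with the gene id, the longest
    transcript length in bp, and one integer column per sample.  Returns
    the input plus ``rpkm_<sample>`` columns.
    """
    lengths = counts[length_col].to_numpy(dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    out = counts.copy()
    sample_cols = [c for c in counts.columns if c not in (gene_col, length_col)]
    for col in sample_cols:
        total = float(counts[col].sum())
        if total <= 0:
            raise ValueError(f"sample {col!r} has no mapped reads")
        out[f"rpkm_{col}"] = 1e9 * counts[col].to_numpy(dtype=float) / (
            total * lengths
        )
    return out


def rank_genes(
    case_rpkm: pd.DataFrame,
    control_rpkm: pd.Series,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Genes ranked by metric = log2((mean case + pc) / (control + pc)).

    Descending by metric; ties broken by gene id for determinism.
    Index of both inputs is the gene id.
    """
    case_mean = case_rpkm.mean(axis=1)
    if not case_mean.index.equals(control_rpkm.index):
        control_rpkm = control_rpkm.reindex(case_mean.index)
    metric = np.log2((case_mean + pseudocount) / (control_rpkm + pseudocount))
    frame = pd.DataFrame({"metric": metric, "_gid": metric.index})
    frame = frame.sort_values(["metric", "_gid"], ascending=[False, True],
                              kind="stable")
    return frame["metric"]


def gsea_es(
    ranked: pd.Series,
    gene_set: Sequence[str],
    weight_p: float = 1.0,
) -> float:
    """Weighted KS enrichment score of ``gene_set`` on the ranked list.

    ``ranked`` is the metric indexed by gene id, sorted descending.
    With ``weight_p = 0`` this reduces to the classical unweighted KS
    statistic.  ES is the signed maximum deviation of the running sum,
    in [-1, 1].
    """
    genes = ranked.index.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    nh = int(in_set.sum())
    N = len(genes)
    if nh == 0 or nh >= N:
        raise ValueError("gene set must be a proper non-empty subset of "
                         "the ranked universe")
    weights = np.abs(ranked.to_numpy()) ** weight_p
    hit_w = np.where(in_set, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit metrics are exactly 0
        hit_w = in_set.astype(float)
        denom = float(nh)
    steps = hit_w / denom - (~in_set) / (N - nh)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_permutation_p(
    ranked: pd.Series,
    gene_set: Sequence[str],
    gene_set_name: str = "gene_set",
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Permutation p-value of the ES under random gene sets of equal size.

    p = (1 + #{|ES_null| >= |ES|}) / (n_perm + 1), so p > 0 always and
    the result is bit-reproducible for a fixed seed.
    """
    es = gsea_es(ranked, gene_set, weight_p=weight_p)
    genes = ranked.index.to_numpy()
    in_universe = np.isin(genes, list(gene_set))
    nh = int(in_universe.sum())
    N = len(genes)
    weights = np.abs(ranked.to_numpy()) ** weight_p
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 17])
    n_extreme = 0
    miss_step = 1.0 / (N - nh)
    for _ in range(n_perm):
        idx = rng.choice(N, size=nh, replace=False)
        mask = np.zeros(N, dtype=bool)
        mask[idx] = True
        hit_w = np.where(mask, weights, 0.0)
        denom = hit_w.sum()
        if denom == 0:
            hit_w = mask.astype(float)
            denom = float(nh)
        running = np.cumsum(hit_w / denom - (~mask) * miss_step)
        es_null = running[np.argmax(np.abs(running))]
        if abs(es_null) >= abs(es):
            n_extreme += 1
    perm_p = (1 + n_extreme) / (n_perm + 1)
    return GseaResult(gene_set_name, es, float(perm_p), n_perm, seed, nh)


def pathway_hypergeom(
    gene_list: Sequence[str],
    gmt_sets: Dict[str, Sequence[str]],
    universe: Sequence[str],
    q_flag: float = 0.05,
    min_overlap: int = 2,
) -> List[PathwayResult]:
    """Upper-tail hypergeometric over-representation per pathway.

    Flagged pathways need BH q < ``q_flag`` and at least ``min_overlap``
    genes from the list.  Pathway genes outside the universe are
    ignored.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    hits = set(gene_list) & uni
    M = len(uni)
    n = len(hits)
    results: List[PathwayResult] = []
    for name in sorted(gmt_sets):
        members = set(gmt_sets[name]) & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if k > 0 else 1.0
        results.append(PathwayResult(name, k, K, M, p))
    if results:
        qvals = bh_adjust(np.array([r.p_value for r in results]))
        for r, q in zip(results, qvals):
            r.q_value = float(q)
            r.flagged = bool(q < q_flag and r.k_overlap >= min_overlap)
    return results


def read_gmt(path) -> Dict[str, List[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gsea_results(results: Sequence[GseaResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("# weighted KS gene-set enrichment, gene-set permutation null\n")
        fh.write("gene_set\tes\tperm_p\tn_perm\tset_size\tseed\n")
        for r in results:
            fh.write(
                f"{r.gene_set_name}\t{r.es:.6g}\t{r.perm_p:.6g}\t{r.n_perm}\t"
                f"{r.set_size}\t{r.seed}\n"
            )


def write_pathway_results(results: Sequence[PathwayResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\tk_overlap\tset_size\tuniverse_size\t"
                 "p_value\tq_value\tflagged\n")
        for r in results:
            fh.write(
                f"{r.pathway_id}\t{r.k_overlap}\t{r.set_size}\t"
                f"{r.universe_size}\t{r.p_value:.6g}\t{r.q_value:.6g}\t"
                f"{int(r.flagged)}\n"
            )
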