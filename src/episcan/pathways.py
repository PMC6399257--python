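"""Gene-set enrichment by sum-of-chi-square scoring with Brown combination.

SNP association p-values are mapped to genes within a +/-20 kb flank
(1-based inclusive); genes sharing a pathway that are also physically
adjacent (overlapping flanked intervals or a shared assigned SNP) are fused
into single units by transitive closure, so stacked neighbours do not count
twice.  Each unit's score is the sum of its member SNPs' chi-square(1)
quantiles, referred to chi-square with df = member count; a pathway's score
sums its fused units' quantiles with df = number of units.  P-values from
several analysis sources (per-cohort scans, meta-analysis) are combined per
pathway with Brown's method for dependent Fisher statistics, using the
empirical inter-source correlation of the -2 ln p vectors.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneScore, PathwayResult

FLANK_DEFAULT = 20_000


def map_and_fuse_genes(
    snp_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    pathways: Dict[str, Sequence[str]],
    flank: int = FLANK_DEFAULT,
    fuse_requires_adjacency: bool = True,
) -> Tuple[Dict[str, List[str]], List[Tuple[str, ...]]]:
    """Assign SNPs to flanked genes and fuse pathway-sharing neighbours.

    ``snp_table`` needs columns snp_id, chrom, pos; ``gene_table`` needs
    gene, chrom, start, end (1-based inclusive).  A SNP belongs to a gene
    iff its position lies in [start - flank, end + flank] on the same
    chromosome.  Two genes fuse iff they share at least one pathway and
    (when ``fuse_requires_adjacency``) share an assigned SNP or have
    overlapping flanked intervals; fusion is the transitive closure.

    Returns (gene -> assigned SNP ids, list of fused-unit tuples covering
    every gene with at least one SNP).
    """
    gene_to_snps: Dict[str, List[str]] = {}
    gt = gene_table.reset_index(drop=True)
    st = snp_table.reset_index(drop=True)
    for _, grow in gt.iterrows():
        lo, hi = int(grow["start"]) - flank, int(grow["end"]) + flank
        mask = (st["chrom"].astype(str) == str(grow["chrom"])) & st["pos"].between(lo, hi)
        snps = st.loc[mask, "snp_id"].tolist()
        if snps:
            gene_to_snps[grow["gene"]] = snps

    gene_sets: Dict[str, set] = {g: set() for g in gene_to_snps}
    for pw, members in pathways.items():
        for g in members:
            if g in gene_sets:
                gene_sets[g].add(pw)

    graph = nx.Graph()
    graph.add_nodes_from(gene_to_snps)
    genes = list(gene_to_snps)
    coords = {
        row["gene"]: (str(row["chrom"]), int(row["start"]) - flank, int(row["end"]) + flank)
        for _, row in gt.iterrows()
    }
    for a_i in range(len(genes)):
        for b_i in range(a_i + 1, len(genes)):
            a, b = genes[a_i], genes[b_i]
            if not (gene_sets[a] & gene_sets[b]):
                continue
            if fuse_requires_adjacency:
                ca, cb = coords[a], coords[b]
                overlap = ca[0] == cb[0] and ca[1] <= cb[2] and cb[1] <= ca[2]
                shared_snp = bool(set(gene_to_snps[a]) & set(gene_to_snps[b]))
                if not (overlap or shared_snp):
                    continue
            graph.add_edge(a, b)
    fused = [tuple(sorted(c)) for c in nx.connected_components(graph)]
    fused.sort()
    return gene_to_snps, fused


def gene_score(snp_p_values: Sequence[float], unit_id: str = "", snp_ids: Sequence[str] = ()) -> GeneScore:
    """Sum-of-chi-square score of one gene (or fused unit)."""
    p = np.asarray(snp_p_values, dtype=float)
    if p.size == 0:
        raise ValueError("gene with empty SNP membership is excluded, not scored")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    total = float(chi.sum())
    df = int(p.size)
    return GeneScore(
        gene_or_fusion_id=unit_id,
        member_snp_ids=tuple(snp_ids),
        chi2_sum=total,
        df=df,
        p_gene=float(stats.chi2.sf(total, df=df)),
    )


def pathway_score(gene_scores: Sequence[GeneScore], pathway_id: str = "") -> PathwayResult:
    """Chi-square enrichment of a pathway over its fused gene units."""
    if len(gene_scores) == 0:
        raise ValueError("pathway with no mapped fused units is excluded")
    p = np.array([gs.p_gene for gs in gene_scores])
    chi = stats.chi2.isf(p, df=1)
    total = float(chi.sum())
    df = len(gene_scores)
    return PathwayResult(
        pathway_id=pathway_id,
        fused_member_ids=tuple(gs.gene_or_fusion_id for gs in gene_scores),
        score=total,
        df=df,
        p_pathway=float(stats.chi2.sf(total, df=df)),
    )


def brown_combine(p_vector: Sequence[float], correlation_matrix: np.ndarray) -> float:
    """Brown's method for combining dependent p-values.

    X = -2 sum(ln p) is referred to a scaled chi-square with moments matched
    to the dependence structure: E = 2k, V = 4k + 2 * sum_{i<j} cov_ij with
    cov_ij = rho_ij (3.263 + 0.710 rho_ij + 0.027 rho_ij^2).  With an
    identity correlation this is exactly Fisher's method.
    """
    p = np.asarray(p_vector, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    rho = np.asarray(correlation_matrix, dtype=float)
    k = p.size
    if rho.shape != (k, k):
        raise ValueError("correlation matrix shape must match the p-vector")
    if not np.allclose(np.diag(rho), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    x = float(-2.0 * np.log(p).sum())
    mean = 2.0 * k
    iu, ju = np.triu_indices(k, 1)
    r = rho[iu, ju]
    cov = r * (3.263 + 0.710 * r + 0.027 * r * r)
    var = 4.0 * k + 2.0 * float(cov.sum())
    c = var / (2.0 * mean)
    f = 2.0 * mean * mean / var
    return float(stats.chi2.sf(x / c, f))


def _score_one_source(
    snp_p: pd.DataFrame,
    gene_table: pd.DataFrame,
    pathways: Dict[str, Sequence[str]],
    flank: int,
) -> Dict[str, PathwayResult]:
    gene_to_snps, fused = map_and_fuse_genes(snp_p, gene_table, pathways, flank)
    pmap = dict(zip(snp_p["snp_id"], snp_p["p"]))
    unit_scores: Dict[Tuple[str, ...], GeneScore] = {}
    for unit in fused:
        snps = sorted({s for g in unit for s in gene_to_snps[g]})
        unit_scores[unit] = gene_score([pmap[s] for s in snps], "+".join(unit), snps)
    out: Dict[str, PathwayResult] = {}
    for pw, members in pathways.items():
        units = [unit_scores[u] for u in fused if set(u) & set(members)]
        if not units:
            continue
        out[pw] = pathway_score(units, pathway_id=pw)
    return out


def enrich(
    sources: Dict[str, pd.DataFrame],
    gene_table: pd.DataFrame,
    pathways: Dict[str, Sequence[str]],
    flank: int = FLANK_DEFAULT,
    correlation: Optional[np.ndarray] = None,
) -> List[PathwayResult]:
    """Score pathways per source and append a Brown-combined column.

    Each source is a DataFrame with columns snp_id, chrom, pos, p.  The
    inter-source correlation is estimated empirically as the correlation of
    the -2 ln p vectors across pathways shared by all sources, unless a
    matrix is supplied.  Output is sorted ascending by the combined p.
    """
    if not sources:
        raise ValueError("need at least one source")
    per_source = {
        name: _score_one_source(tab, gene_table, pathways, flank)
        for name, tab in sources.items()
    }
    names = list(per_source)
    shared = set.intersection(*(set(d) for d in per_source.values()))
    if not shared:
        return []
    shared = sorted(shared)
    logs = np.array(
        [[-2.0 * np.log(per_source[s][pw].p_pathway) for pw in shared] for s in names]
    )
    k = len(names)
    if correlation is None:
        if k == 1 or logs.shape[1] < 3:
            correlation = np.eye(k)
        else:
            correlation = np.corrcoef(logs)
            correlation = np.clip(np.nan_to_num(correlation, nan=0.0), -1.0, 1.0)
            np.fill_diagonal(correlation, 1.0)
    results: List[PathwayResult] = []
    for pw in shared:
        base = per_source[names[0]][pw]
        pvec = [per_source[s][pw].p_pathway for s in names]
        combined = brown_combine(pvec, correlation) if k > 1 else pvec[0]
        results.append(
            PathwayResult(
                pathway_id=pw,
                fused_member_ids=base.fused_member_ids,
                score=base.score,
                df=base.df,
                p_pathway=base.p_pathway,
                p_sources={s: per_source[s][pw].p_pathway for s in names},
                p_combined=combined,
            )
        )
    results.sort(key=lambda r: r.p_combined)
    return results
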