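"""Gene mapping/fusion, sum-of-chi-square scoring and Brown combination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episcan.meta import fisher_combine
from episcan.pathways import (
    brown_combine,
    enrich,
    gene_score,
    map_and_fuse_genes,
    pathway_score,
)


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def _snps(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


def test_snp_assignment_boundary_inclusive_at_20kb():
    genes = _genes([("G1", "1", 100_000, 110_000)])
    snps = _snps([("s_at", "1", 80_000), ("s_out", "1", 79_999), ("s_chr", "2", 100_500)])
    mapping, _ = map_and_fuse_genes(snps, genes, {"P": ["G1"]})
    assert mapping == {"G1": ["s_at"]}


def test_flank_overlap_plus_shared_pathway_fuses():
    # genes 30 kb apart: flanked intervals overlap
    genes = _genes([("G1", "1", 100_000, 110_000), ("G2", "1", 140_001, 150_000)])
    snps = _snps([("s1", "1", 105_000), ("s2", "1", 145_000)])
    _, fused = map_and_fuse_genes(snps, genes, {"P": ["G1", "G2"]})
    assert fused == [("G1", "G2")]
    # same geometry without a shared pathway: not fused
    _, fused2 = map_and_fuse_genes(snps, genes, {"P1": ["G1"], "P2": ["G2"]})
    assert fused2 == [("G1",), ("G2",)]


def test_distant_genes_sharing_pathway_not_fused():
    genes = _genes([("G1", "1", 100_000, 110_000), ("G2", "1", 900_000, 910_000)])
    snps = _snps([("s1", "1", 105_000), ("s2", "1", 905_000)])
    _, fused = map_and_fuse_genes(snps, genes, {"P": ["G1", "G2"]})
    assert fused == [("G1",), ("G2",)]


def test_gene_without_nearby_snp_excluded():
    genes = _genes([("G1", "1", 100_000, 110_000), ("G2", "1", 500_000, 510_000)])
    snps = _snps([("s1", "1", 105_000)])
    mapping, fused = map_and_fuse_genes(snps, genes, {"P": ["G1", "G2"]})
    assert "G2" not in mapping
    assert fused == [("G1",)]


def test_fusion_is_transitive_closure():
    # chain G1-G2-G3 where only consecutive pairs are adjacent
    genes = _genes([
        ("G1", "1", 100_000, 110_000),
        ("G2", "1", 140_000, 150_000),
        ("G3", "1", 180_000, 190_000),
    ])
    snps = _snps([("s1", "1", 105_000), ("s2", "1", 145_000), ("s3", "1", 185_000)])
    _, fused = map_and_fuse_genes(snps, genes, {"P": ["G1", "G2", "G3"]})
    assert fused == [("G1", "G2", "G3")]


def test_gene_score_identity_for_singleton():
    for p in (0.9, 0.2, 1e-4):
        assert gene_score([p]).p_gene == pytest.approx(p, rel=1e-10)


def test_gene_score_two_snp_example():
    gs = gene_score([0.05, 0.05])
    assert gs.chi2_sum == pytest.approx(7.68, abs=0.01)
    assert gs.df == 2
    # chi-square(2) tail closed form e^(-x/2)
    assert gs.p_gene == pytest.approx(np.exp(-gs.chi2_sum / 2), abs=1e-12)
    assert gs.p_gene == pytest.approx(0.0215, abs=5e-4)


def test_gene_score_all_ones():
    gs = gene_score([1.0, 1.0, 1.0])
    assert gs.chi2_sum == 0.0 and gs.p_gene == pytest.approx(1.0)
    with pytest.raises(ValueError):
        gene_score([])


def test_pathway_score_singleton_and_three_member_example():
    g1 = gene_score([0.1], "a")
    assert pathway_score([g1]).p_pathway == pytest.approx(0.1, rel=1e-10)
    members = [gene_score([0.1], c) for c in "abc"]
    res = pathway_score(members)
    assert res.score == pytest.approx(3 * stats.chi2.isf(0.1, 1), rel=1e-10)
    assert res.df == 3
    assert res.p_pathway == pytest.approx(0.0436, abs=5e-4)


def test_brown_identity_correlation_equals_fisher():
    ps = [0.01, 0.2, 0.5, 0.77]
    assert brown_combine(ps, np.eye(4)) == pytest.approx(fisher_combine(ps)[2], abs=1e-12)


def test_brown_rejects_bad_correlation():
    with pytest.raises(ValueError):
        brown_combine([0.1, 0.2], np.array([[2.0, 0.0], [0.0, 1.0]]))


def test_brown_equicorrelated_matches_monte_carlo():
    # k = 3 one-sided normal p-values with pairwise rho = 0.5
    rho = 0.5
    k = 3
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    ps = [0.01, 0.05, 0.2]
    x0 = -2 * np.log(ps).sum()
    p_brown = brown_combine(ps, corr)
    rng = np.random.default_rng(42)
    n = 100_000
    L = np.linalg.cholesky(corr)
    z = rng.normal(size=(n, k)) @ L.T
    x = -2 * np.log(stats.norm.sf(z)).sum(axis=1)
    p_mc = (x > x0).mean()
    mc_sd = np.sqrt(p_mc * (1 - p_mc) / n)
    assert abs(p_brown - p_mc) < 3 * mc_sd + 1e-4


def test_brown_duplicated_source_never_beats_independent_fisher():
    ps = [0.01, 0.01]
    corr = np.ones((2, 2))
    p_dep = brown_combine(ps, corr)
    p_indep = fisher_combine(ps)[2]
    assert p_dep > p_indep
    assert p_dep == pytest.approx(0.01, abs=0.01)  # fully dependent ~ single source


def _toy_enrich_inputs(rng, n_snps=60):
    pos = 50_000 * np.arange(n_snps) + 5_000
    snp = pd.DataFrame({
        "snp_id": [f"s{k}" for k in range(n_snps)],
        "chrom": "1",
        "pos": pos,
        "p": rng.uniform(size=n_snps),
    })
    genes = _genes([(f"G{k}", "1", 50_000 * k + 1, 50_000 * k + 10_000) for k in range(n_snps)])
    sets = {f"SET{j}": [f"G{k}" for k in range(j * 10, j * 10 + 10)] for j in range(4)}
    return snp, genes, sets


def test_enrich_single_source_combined_equals_pathway_p(rng):
    snp, genes, sets = _toy_enrich_inputs(rng)
    res = enrich({"only": snp}, genes, sets)
    assert len(res) == 4
    for r in res:
        assert r.p_combined == pytest.approx(r.p_sources["only"], rel=1e-12)


def test_enrich_two_sources_adds_combined_column(rng):
    snp1, genes, sets = _toy_enrich_inputs(rng)
    snp2 = snp1.copy()
    snp2["p"] = rng.uniform(size=len(snp2))
    res = enrich({"a": snp1, "b": snp2}, genes, sets)
    assert all(set(r.p_sources) == {"a", "b"} for r in res)
    ps = [r.p_combined for r in res]
    assert ps == sorted(ps)


def test_pathway_p_uniform_under_global_null():
    # independent uniform SNP p-values -> pathway p-values uniform (KS at 1%)
    rng = np.random.default_rng(7)
    pvals = []
    for rep in range(200):
        snp, genes, sets = _toy_enrich_inputs(rng)
        res = enrich({"x": snp}, genes, sets)
        pvals += [r.p_pathway for r in res]
    stat = stats.kstest(pvals, "uniform")
    assert stat.pvalue > 0.01
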