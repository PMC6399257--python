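"""Quality-control filters: HWE exact test vs brute-force enumeration,
MAF/call-rate/IBS rules, and the covariate PCA."""

from math import exp, lgamma, log

import numpy as np
import pytest

from episcan.qc import (
    apply_sample_filters,
    apply_snp_filters,
    genotype_pca,
    hwe_exact_test,
    ibs_matrix,
)
from episcan.types import MISSING

from conftest import make_dataset


def hwe_brute_force(n_hom1, n_het, n_hom2):
    """Independent oracle: full enumeration of heterozygote counts that share
    the observed allele totals, exact multinomial probabilities."""
    n = n_hom1 + n_het + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het

    def prob(h):
        r = (rare - h) // 2
        c = n - h - r
        return exp(
            lgamma(n + 1) - lgamma(h + 1) - lgamma(r + 1) - lgamma(c + 1)
            + h * log(2)
            + lgamma(rare + 1) + lgamma(2 * n - rare + 1) - lgamma(2 * n + 1)
        )

    table = {h: prob(h) for h in range(rare % 2, rare + 1, 2) if (rare - h) // 2 + h <= n}
    p_obs = table[n_het]
    return sum(p for p in table.values() if p <= p_obs * (1 + 1e-10))


@pytest.mark.parametrize(
    "counts",
    [(25, 50, 25), (10, 20, 10), (50, 0, 50), (3, 5, 2), (0, 1, 0), (7, 1, 1),
     (40, 10, 50), (1, 98, 1), (0, 0, 7), (33, 33, 34)],
)
def test_hwe_exact_matches_enumeration(counts):
    assert hwe_exact_test(*counts) == pytest.approx(hwe_brute_force(*counts), abs=1e-12)


def test_hwe_modal_table_has_p_one():
    assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)


def test_hwe_extreme_het_deficit_fails_threshold():
    assert hwe_exact_test(50, 0, 50) < 1e-5


def test_hwe_exhaustive_small_tables_match_enumeration():
    # every table with up to 200 alleles in a coarse sweep
    for n in (10, 25, 60, 100):
        for n_hom1 in range(0, n + 1, max(1, n // 5)):
            for n_het in range(0, n - n_hom1 + 1, max(1, n // 5)):
                n_hom2 = n - n_hom1 - n_het
                assert hwe_exact_test(n_hom1, n_het, n_hom2) == pytest.approx(
                    hwe_brute_force(n_hom1, n_het, n_hom2), abs=1e-12
                )


def test_hwe_all_zero_rejected():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


def test_hwe_conservative_under_null(rng):
    # simulated HWE genotype tables: exact-test rejections at alpha=1e-3
    # stay at or below 1.2e-3 (the exact test is conservative)
    n, reps, alpha = 100, 100_000, 1e-3
    p = 0.3
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
    tables = rng.multinomial(n, probs, size=reps)
    rejected = sum(hwe_exact_test(*t) < alpha for t in tables)
    assert rejected / reps <= 1.2e-3


def _qc_dataset():
    rng = np.random.default_rng(0)
    g = rng.binomial(2, 0.3, size=(200, 6)).astype(np.int8)
    g[:, 1] = 0                                      # one het: MAF 1/400 < 0.01
    g[0, 1] = 1
    g[: int(200 * 0.06), 2] = MISSING                # 94% call rate
    g[:, 3] = 0                                      # monomorphic
    g[100:150, 4] = 0                                # controls het-free (50,0,50)
    g[150:, 4] = 2
    phen = np.r_[np.ones(100, int), np.zeros(100, int)]
    return make_dataset(g, phen)


def test_snp_filters_record_primary_reasons():
    ds = _qc_dataset()
    filtered, report = apply_snp_filters(ds)
    reasons = dict(report.removed_snps)
    assert reasons["v1"] == "maf"
    assert reasons["v2"] == "callrate"
    assert reasons["v3"] == "maf"  # monomorphic: MAF 0 < 0.01
    assert reasons["v4"] == "hwe"  # no heterozygotes in controls
    assert "v0" not in reasons and "v5" not in reasons
    assert filtered.n_snps == 2


def test_snp_filters_idempotent():
    ds = _qc_dataset()
    once, _ = apply_snp_filters(ds)
    twice, rep = apply_snp_filters(once)
    assert twice.n_snps == once.n_snps
    assert rep.removed_snps == []


def test_hwe_skipped_without_controls(rng):
    g = rng.binomial(2, 0.3, size=(50, 4)).astype(np.int8)
    ds = make_dataset(g, phenotype=np.ones(50, int))
    _, report = apply_snp_filters(ds)
    assert any("HWE" in w for w in report.warnings)


def test_ibs_hand_computed_value():
    ds = make_dataset([[0, 2, 1], [2, 0, 1]])
    ibs = ibs_matrix(ds)
    assert ibs[0, 1] == pytest.approx(1 / 3)


def test_sample_filters_remove_duplicate_and_low_callrate(rng):
    g = rng.binomial(2, 0.3, size=(6, 40)).astype(np.int8)
    g[1] = g[0]                       # duplicated sample, IBS = 1.0
    g[2, : int(40 * 0.1)] = MISSING   # 90% call rate
    ds = make_dataset(g)
    filtered, report = apply_sample_filters(ds)
    reasons = dict(report.removed_samples)
    assert reasons["s2"] == "callrate"
    assert ("s0" in reasons) ^ ("s1" in reasons)  # exactly one of the pair
    assert filtered.n_samples == 4


def test_related_pair_drops_lower_callrate_member(rng):
    g = rng.binomial(2, 0.3, size=(4, 60)).astype(np.int8)
    g[3] = g[2]
    g[2, 0] = MISSING  # s2 has lower call rate (but still >= 0.95)
    ds = make_dataset(g)
    _, report = apply_sample_filters(ds)
    assert ("s2", "ibs") in report.removed_samples


def test_pca_separates_planted_subpopulations(rng):
    n_half, m = 60, 300
    g1 = rng.binomial(2, 0.15, size=(n_half, m))
    g2 = rng.binomial(2, 0.45, size=(n_half, m))
    ds = make_dataset(np.vstack([g1, g2]).astype(np.int8))
    scores = genotype_pca(ds, 2)
    pc1 = scores[:, 0]
    sign = np.sign(pc1 - np.median(pc1))
    agreement = max((sign[:n_half] > 0).mean() + (sign[n_half:] < 0).mean(),
                    (sign[:n_half] < 0).mean() + (sign[n_half:] > 0).mean()) / 2
    assert agreement > 0.95


def test_pca_scores_orthogonal(rng):
    from conftest import random_dataset

    ds = random_dataset(rng, n=80, m=40)
    scores = genotype_pca(ds, 5)
    corr = np.corrcoef(scores.T)
    assert np.allclose(corr - np.eye(5), 0, atol=1e-8)


def test_pca_k_zero_gives_empty_scores(rng):
    from conftest import random_dataset

    ds = random_dataset(rng, n=10, m=8)
    assert genotype_pca(ds, 0).shape == (10, 0)
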