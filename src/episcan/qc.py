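"""Sample and SNP quality control plus covariate PCA.

Filters mirror standard array-GWAS practice: per-sample call rate >= 0.95,
relatedness removal at identity-by-state (IBS) >= 0.80, per-SNP minor allele
frequency >= 0.01, call rate >= 0.95, and a Hardy-Weinberg exact test in
controls at P >= 1e-5.  The HWE test is the exact conditional test
(enumeration of heterozygote counts given the allele totals, summing the
probabilities of tables no more likely than the observed one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeDataset


@dataclass
class QcReport:
    """Per-entity QC metrics and the removals with their primary reason."""

    snp_maf: Optional[pd.Series] = None
    snp_callrate: Optional[pd.Series] = None
    snp_hwe_p: Optional[pd.Series] = None
    sample_callrate: Optional[pd.Series] = None
    removed_snps: List[Tuple[str, str]] = field(default_factory=list)
    removed_samples: List[Tuple[str, str]] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("snp", sid, reason) for sid, reason in self.removed_snps]
        rows += [("sample", sid, reason) for sid, reason in self.removed_samples]
        return pd.DataFrame(rows, columns=["entity", "id", "reason"])


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Conditional on the observed allele totals, heterozygote counts follow
    the distribution P(n_het) ∝ n! / (n_AA! n_Aa! n_aa!) * 2^n_het; the
    p-value sums the probabilities of all heterozygote counts whose
    probability does not exceed that of the observed count.  Computed by
    the standard ratio recurrence from the modal count, so it is stable for
    large samples.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all-zero genotype table has no HWE p-value")

    rare = 2 * min(n_hom1, n_hom2) + n_het  # rare-allele count
    # heterozygote counts share the parity of the rare-allele total
    probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if (mid % 2) != (rare % 2):
        mid += 1
    probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / (4 (r+1) (c+1))
    curr_rare_hom = (rare - mid) // 2
    curr_common_hom = n - mid - curr_rare_hom
    h = mid
    while h >= 2:
        probs[h - 2] = probs[h] * h * (h - 1) / (
            4.0 * (curr_rare_hom + 1) * (curr_common_hom + 1)
        )
        curr_rare_hom += 1
        curr_common_hom += 1
        h -= 2
    curr_rare_hom = (rare - mid) // 2
    curr_common_hom = n - mid - curr_rare_hom
    h = mid
    while h <= rare - 2:
        probs[h + 2] = probs[h] * 4.0 * curr_rare_hom * curr_common_hom / (
            (h + 2.0) * (h + 1.0)
        )
        curr_rare_hom -= 1
        curr_common_hom -= 1
        h += 2
    total = probs.sum()
    probs /= total
    p_obs = probs[n_het]
    # sum over tables no more probable than the observed (with fp slack)
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-10)].sum()))


def _snp_stats(dataset: GenotypeDataset):
    g = dataset.genotypes
    obs = g != MISSING
    n_obs = obs.sum(axis=0)
    callrate = n_obs / g.shape[0]
    with np.errstate(invalid="ignore"):
        freq1 = np.where(n_obs > 0, np.where(obs, g, 0).sum(axis=0) / (2 * np.maximum(n_obs, 1)), np.nan)
    maf = np.minimum(freq1, 1 - freq1)
    return callrate, maf


def apply_snp_filters(
    dataset: GenotypeDataset,
    maf_min: float = 0.01,
    callrate_min: float = 0.95,
    hwe_alpha: float = 1e-5,
) -> Tuple[GenotypeDataset, QcReport]:
    """Remove SNPs failing MAF, call-rate, or control-HWE rules.

    MAF and call rate use all samples (non-missing genotypes); HWE is tested
    in controls only.  Each removed SNP records exactly one primary reason,
    checked in the order maf, callrate, hwe.
    """
    report = QcReport()
    callrate, maf = _snp_stats(dataset)
    controls = dataset.subset(sample_idx=np.flatnonzero(~dataset.is_case))
    m = dataset.n_snps
    hwe_p = np.ones(m)
    if controls.n_samples == 0:
        report.warnings.append("no controls present; HWE stage skipped")
    else:
        gc = controls.genotypes
        for v in range(m):
            col = gc[:, v]
            col = col[col != MISSING]
            if col.size == 0:
                continue
            n2 = int((col == 2).sum())
            n1 = int((col == 1).sum())
            n0 = int((col == 0).sum())
            hwe_p[v] = hwe_exact_test(n2, n1, n0)

    keep = []
    ids = dataset.snps["snp_id"]
    for v in range(m):
        if not (maf[v] >= maf_min):  # also catches NaN (all-missing columns)
            report.removed_snps.append((ids.iloc[v], "maf"))
        elif callrate[v] < callrate_min:
            report.removed_snps.append((ids.iloc[v], "callrate"))
        elif hwe_p[v] < hwe_alpha:
            report.removed_snps.append((ids.iloc[v], "hwe"))
        else:
            keep.append(v)
    report.snp_maf = pd.Series(maf, index=ids)
    report.snp_callrate = pd.Series(callrate, index=ids)
    report.snp_hwe_p = pd.Series(hwe_p, index=ids)
    return dataset.subset(snp_idx=keep), report


def ibs_matrix(dataset: GenotypeDataset) -> np.ndarray:
    """Pairwise identity-by-state: mean over shared non-missing loci of
    (2 - |g1 - g2|) / 2."""
    g = dataset.genotypes.astype(float)
    g[g == MISSING] = np.nan
    n = g.shape[0]
    out = np.ones((n, n))
    for j in range(n):
        d = np.abs(g - g[j])  # (n, m)
        out[j] = np.nanmean((2.0 - d) / 2.0, axis=1)
    return out


def apply_sample_filters(
    dataset: GenotypeDataset,
    callrate_min: float = 0.95,
    ibs_max: float = 0.80,
) -> Tuple[GenotypeDataset, QcReport]:
    """Remove low-call-rate samples, then one member of each related pair.

    For a pair with IBS >= ``ibs_max`` the member with the lower call rate is
    removed (tie: the later sample index).
    """
    if dataset.n_samples < 2:
        raise ValueError("sample QC needs at least 2 samples")
    report = QcReport()
    obs = dataset.genotypes != MISSING
    callrate = obs.mean(axis=1)
    report.sample_callrate = pd.Series(callrate, index=dataset.samples["sample_id"])
    ids = dataset.samples["sample_id"]

    keep_mask = callrate >= callrate_min
    for j in np.flatnonzero(~keep_mask):
        report.removed_samples.append((ids.iloc[j], "callrate"))

    survivors = np.flatnonzero(keep_mask)
    sub = dataset.subset(sample_idx=survivors)
    ibs = ibs_matrix(sub)
    sub_call = callrate[survivors]
    drop = set()
    ns = len(survivors)
    for a in range(ns):
        if a in drop:
            continue
        for b in range(a + 1, ns):
            if b in drop:
                continue
            if ibs[a, b] >= ibs_max:
                loser = b if sub_call[b] <= sub_call[a] else a
                drop.add(loser)
                report.removed_samples.append((ids.iloc[survivors[loser]], "ibs"))
    final = [survivors[a] for a in range(ns) if a not in drop]
    return dataset.subset(sample_idx=final), report


def genotype_pca(dataset: GenotypeDataset, k: int) -> np.ndarray:
    """Top-``k`` principal-component scores of standardized dosages.

    Missing dosages are imputed to the column mean; columns are standardized
    to mean 0 / unit variance (zero-variance columns are dropped with a
    warning left to the caller's log); scores are ordered by decreasing
    eigenvalue of the sample covariance.
    """
    n = dataset.n_samples
    if k == 0:
        return np.empty((n, 0))
    if k >= min(n, dataset.n_snps):
        raise ValueError("k must be smaller than min(n_samples, n_snps)")
    g = dataset.genotypes.astype(float)
    g[g == MISSING] = np.nan
    mu = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), mu, g)
    sd = g.std(axis=0)
    ok = sd > 0
    z = (g[:, ok] - mu[ok]) / sd[ok]
    # SVD of the centered matrix gives the covariance eigenvectors directly
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    return u[:, :k] * s[:k]
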