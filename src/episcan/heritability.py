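"""SNP-set heritability on the observed 0/1 scale and its liability-scale
conversion under case-control ascertainment.

The genetic relationship matrix (GRM) over a SNP subset is
A_jk = (1/M) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),
with p_i the sample allele frequency (missing dosages mean-imputed).
Observed-scale heritability is estimated by Haseman-Elston regression:
the phenotype is residualized on covariates, standardized, and the
cross-products y_j y_k (j < k) are regressed on A_jk; the slope is
h2_observed, with a block-jackknife standard error over individuals.

The observed-scale estimate is converted to the liability scale with the
standard ascertainment-corrected transformation

    h2_liability = h2_observed * K^2 (1 - K)^2 / (z(t)^2 * P (1 - P)),

where K is the population lifetime risk, P the sample case proportion,
t the upper-K standard-normal quantile and z the normal density at t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import MISSING, GenotypeDataset


@dataclass
class HeritabilityEstimate:
    h2_observed: float
    se_observed: float
    h2_liability: float
    K: float
    P: float
    n_snps_used: int


class SimulationError(RuntimeError):
    pass


def compute_grm(dataset: GenotypeDataset, snp_subset: Optional[Sequence[int]] = None) -> np.ndarray:
    """Standardized-dosage genetic relationship matrix over a SNP subset."""
    if snp_subset is None:
        snp_subset = np.arange(dataset.n_snps)
    snp_subset = np.asarray(snp_subset)
    if snp_subset.size == 0:
        raise ValueError("SNP subset must be non-empty")
    g = dataset.genotypes[:, snp_subset].astype(float)
    g[g == MISSING] = np.nan
    mu = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), mu, g)
    p = mu / 2.0
    denom = 2.0 * p * (1.0 - p)
    if np.any(denom <= 0):
        raise ValueError("monomorphic SNPs in the GRM subset")
    z = (g - 2.0 * p) / np.sqrt(denom)
    return (z @ z.T) / snp_subset.size


def estimate_h2_observed(
    grm: np.ndarray,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    n_jackknife_blocks: int = 20,
) -> Tuple[float, float]:
    """Haseman-Elston slope of phenotype cross-products on relatedness.

    ``covariates`` should include an intercept column; with None, only the
    mean is removed.  Returns (h2_observed, jackknife se); the jackknife
    leaves out blocks of individuals (all pairs touching a block).
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if np.std(y) == 0:
        raise ValueError("phenotype is constant")
    if covariates is None:
        covariates = np.ones((n, 1))
    resid = y - covariates @ np.linalg.lstsq(covariates, y, rcond=None)[0]
    resid = resid / resid.std()

    iu, ju = np.triu_indices(n, k=1)
    a = grm[iu, ju]
    yy = resid[iu] * resid[ju]

    def slope(mask: np.ndarray) -> float:
        am, ym = a[mask], yy[mask]
        va = am.var()
        if va == 0:
            return 0.0
        return float(np.cov(am, ym, bias=True)[0, 1] / va)

    full = slope(np.ones(a.size, dtype=bool))

    blocks = np.array_split(np.arange(n), max(2, n_jackknife_blocks))
    block_of = np.empty(n, dtype=int)
    for b, idx in enumerate(blocks):
        block_of[idx] = b
    est = []
    for b in range(len(blocks)):
        mask = (block_of[iu] != b) & (block_of[ju] != b)
        est.append(slope(mask))
    est = np.asarray(est)
    g = len(blocks)
    se = float(np.sqrt((g - 1) / g * ((est - est.mean()) ** 2).sum()))
    return full, se


def liability_transform(h2_observed: float, K: float, P: float) -> float:
    """Observed 0/1 scale to liability scale under case-control sampling."""
    if not (0 < K < 1 and 0 < P < 1):
        raise ValueError("K and P must lie in (0,1)")
    t = stats.norm.isf(K)
    z = stats.norm.pdf(t)
    factor = K * K * (1 - K) ** 2 / (z * z * P * (1 - P))
    return h2_observed * factor


def estimate_h2(
    dataset: GenotypeDataset,
    snp_subset: Optional[Sequence[int]] = None,
    K: float = 0.007,
    n_pcs: int = 0,
    n_jackknife_blocks: int = 20,
) -> HeritabilityEstimate:
    """GRM + Haseman-Elston + liability conversion in one call."""
    from .qc import genotype_pca

    grm = compute_grm(dataset, snp_subset)
    y = dataset.phenotype.astype(float)
    cov = np.ones((dataset.n_samples, 1))
    if n_pcs > 0:
        cov = np.column_stack([cov, genotype_pca(dataset, n_pcs)])
    h2_obs, se = estimate_h2_observed(grm, y, cov, n_jackknife_blocks)
    P = float(y.mean())
    return HeritabilityEstimate(
        h2_observed=h2_obs,
        se_observed=se,
        h2_liability=liability_transform(h2_obs, K, P),
        K=K,
        P=P,
        n_snps_used=dataset.n_snps if snp_subset is None else len(np.asarray(snp_subset)),
    )


_MAX_BATCHES = 500


def simulate_liability_cohort(
    h2_true: float,
    K: float,
    n_cases: int,
    n_controls: int,
    m_snps: int,
    seed: int,
    maf_range: Tuple[float, float] = (0.1, 0.5),
) -> GenotypeDataset:
    """Case-control cohort under the liability-threshold model.

    Liability = genetic value + environmental noise, where the genetic value
    is a weighted sum of population-standardized causal dosages whose weight
    vector is rescaled so the genetic variance is exactly ``h2_true``; an
    individual is a case iff liability exceeds the upper-K normal quantile.
    Cases are oversampled to quota (case-control ascertainment).
    """
    import pandas as pd

    if not (0 <= h2_true < 1):
        raise ValueError("h2_true must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=m_snps)
    u = rng.normal(size=m_snps)
    if h2_true > 0:
        u *= np.sqrt(h2_true) / np.linalg.norm(u)
    else:
        u[:] = 0.0
    t = stats.norm.isf(K)
    sd_e = np.sqrt(1.0 - h2_true)

    cases, controls = [], []
    n_ca = n_co = 0
    batch = max(2000, int(1.5 * n_cases / max(K, 1e-6) / 10))
    scale = np.sqrt(2 * mafs * (1 - mafs))
    for _ in range(_MAX_BATCHES):
        if n_ca >= n_cases and n_co >= n_controls:
            break
        # Binomial(2, p) as a sum of two Bernoulli draws: much cheaper than
        # per-element binomial sampling at this scale
        g = (
            (rng.random((batch, m_snps)) < mafs).view(np.int8)
            + (rng.random((batch, m_snps)) < mafs).view(np.int8)
        )
        z = (g - 2 * mafs) / scale
        liab = z @ u + sd_e * rng.normal(size=batch)
        is_case = liab > t
        if n_ca < n_cases:
            take = g[is_case][: n_cases - n_ca]
            cases.append(take)
            n_ca += take.shape[0]
        if n_co < n_controls:
            take = g[~is_case][: n_controls - n_co]
            controls.append(take)
            n_co += take.shape[0]
    else:
        raise SimulationError("liability-cohort quotas not reached")

    geno = np.vstack(cases + controls)
    n = n_cases + n_controls
    samples = pd.DataFrame(
        {
            "sample_id": [f"L{k:06d}" for k in range(n)],
            "cohort": "SIM",
            "phenotype": np.r_[np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)],
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{v:06d}" for v in range(m_snps)],
            "chrom": "1",
            "pos": 10_000 * np.arange(m_snps) + 1,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeDataset(genotypes=geno, samples=samples, snps=snps)
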