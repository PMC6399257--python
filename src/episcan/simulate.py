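"""Synthetic case-control cohorts, linked expression data and annotations.

The disease model is logistic in allele dosages with optional pairwise
product terms,

    P(case | x) = expit(alpha + sum_i beta_i x_i + sum_(j,k) gamma_jk x_j x_k),

with the intercept ``alpha`` solved so that the population prevalence equals
the configured lifetime risk ``K``.  SNPs are simulated without linkage
disequilibrium under Hardy-Weinberg equilibrium (genotype ~ Binomial(2, MAF));
an optional Gaussian-copula mode produces correlated blocks for pruning
tests.  Cohorts are ascertained case-control: individuals are drawn from the
population model and assigned by a Bernoulli draw on P(case | x) until the
case and control quotas are met.

Because SNPs carrying no effect are independent of disease status under this
model, rejection sampling operates on the joint genotypes of the
effect-bearing SNPs only; null SNP columns are filled in afterwards from
their Hardy-Weinberg distribution.  This is distributionally identical to
rejection over the full genotype vector and keeps low-prevalence
ascertainment (K ~ 0.007) cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .types import MISSING, ExpressionDataset, GenotypeDataset


class SimulationError(RuntimeError):
    """Raised when a quota cannot be met in a bounded number of draws."""


@dataclass
class SimulationConfig:
    """Generative parameters for a pair of case-control cohorts.

    Effect sizes are log-odds: ``marginal_effects`` maps SNP index -> per-allele
    beta; ``interaction_effects`` maps an (i, j) pair -> gamma multiplying the
    dosage product.  ``prevalence`` is the population lifetime risk K used to
    anchor the intercept.
    """

    n_cases: int = 500
    n_controls: int = 500
    m_snps: int = 1000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    marginal_effects: Dict[int, float] = field(default_factory=dict)
    interaction_effects: Dict[Tuple[int, int], float] = field(default_factory=dict)
    prevalence: float = 0.007
    missing_rate: float = 0.0
    # expression model: y = mu + b * g + eps, eps ~ N(0, sigma^2) except an
    # outlier fraction whose sd is multiplied by outlier_scale
    n_probes: int = 12
    cis_pairs: Dict[Tuple[int, int], float] = field(default_factory=dict)  # (snp, probe) -> b
    expr_mu: float = 7.0
    expr_sigma: float = 1.0
    outlier_frac: float = 0.0
    outlier_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0 or self.m_snps <= 0:
            raise ValueError("sample and SNP quotas must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence K must lie in (0,1)")
        if not (0 <= self.outlier_frac < 0.5):
            raise ValueError("outlier fraction must lie in [0, 0.5)")
        for i in self.marginal_effects:
            if not 0 <= i < self.m_snps:
                raise ValueError(f"marginal effect index {i} out of range")
        for (i, j) in self.interaction_effects:
            if not (0 <= i < self.m_snps and 0 <= j < self.m_snps and i != j):
                raise ValueError(f"interaction pair ({i},{j}) out of range")


def _effect_snp_indices(config: SimulationConfig) -> List[int]:
    idx = set(config.marginal_effects)
    for (i, j) in config.interaction_effects:
        idx.update((i, j))
    return sorted(idx)


def _linear_predictor(g: np.ndarray, cols: Sequence[int], config: SimulationConfig) -> np.ndarray:
    """Risk-score part (without intercept) for genotypes of the effect SNPs.

    ``g`` has one column per entry of ``cols`` (the effect SNP indices).
    """
    pos = {snp: k for k, snp in enumerate(cols)}
    eta = np.zeros(g.shape[0])
    for snp, beta in config.marginal_effects.items():
        eta += beta * g[:, pos[snp]]
    for (i, j), gamma in config.interaction_effects.items():
        eta += gamma * g[:, pos[i]] * g[:, pos[j]]
    return eta


def solve_alpha(config: SimulationConfig, mafs: np.ndarray) -> float:
    """Intercept making the population prevalence equal K.

    Enumerates the joint Hardy-Weinberg genotype distribution of the
    effect-bearing SNPs (all other SNPs contribute nothing to the linear
    predictor) and solves E[expit(alpha + eta(g))] = K by 1-D root finding.
    With no effects this reduces to the closed form alpha = logit(K).
    """
    cols = _effect_snp_indices(config)
    if not cols:
        return float(logit(config.prevalence))

    # joint genotype table over the effect SNPs: 3^len(cols) rows
    states = np.array(list(itertools.product((0, 1, 2), repeat=len(cols))), dtype=float)
    prob = np.ones(states.shape[0])
    for k, snp in enumerate(cols):
        p = mafs[snp]
        hw = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
        prob *= hw[states[:, k].astype(int)]
    eta = _linear_predictor(states, cols, config)

    def prevalence(alpha: float) -> float:
        return float(prob @ expit(alpha + eta)) - config.prevalence

    lo, hi = -50.0, 50.0
    return float(brentq(prevalence, lo, hi, xtol=1e-12))


_MAX_BATCHES = 2000


def simulate_cohort(config: SimulationConfig, cohort_label: str) -> GenotypeDataset:
    """Draw one ascertained case-control cohort under the logistic model."""
    rng = np.random.default_rng(config.seed + _stable_offset(cohort_label))
    m = config.m_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    alpha = solve_alpha(config, mafs)
    cols = _effect_snp_indices(config)

    batch = max(4 * (config.n_cases + config.n_controls), 1000)
    cases: List[np.ndarray] = []
    controls: List[np.ndarray] = []
    n_cases = n_controls = 0
    for _ in range(_MAX_BATCHES):
        if n_cases >= config.n_cases and n_controls >= config.n_controls:
            break
        g_eff = rng.binomial(2, mafs[cols], size=(batch, len(cols))).astype(np.int8) \
            if cols else np.empty((batch, 0), dtype=np.int8)
        p_case = expit(alpha + _linear_predictor(g_eff.astype(float), cols, config))
        is_case = rng.random(batch) < p_case
        if n_cases < config.n_cases:
            take = g_eff[is_case][: config.n_cases - n_cases]
            cases.append(take)
            n_cases += take.shape[0]
        if n_controls < config.n_controls:
            take = g_eff[~is_case][: config.n_controls - n_controls]
            controls.append(take)
            n_controls += take.shape[0]
    else:
        raise SimulationError(
            f"case/control quota not reached after {_MAX_BATCHES} batches "
            f"(K={config.prevalence}, quotas {config.n_cases}/{config.n_controls})"
        )

    n = config.n_cases + config.n_controls
    geno = np.empty((n, m), dtype=np.int8)
    null_cols = np.setdiff1d(np.arange(m), cols)
    # null SNPs are independent of status: fill from Hardy-Weinberg
    geno[:, null_cols] = rng.binomial(2, mafs[null_cols], size=(n, null_cols.size))
    if cols:
        eff = np.vstack(cases + controls)
        geno[:, cols] = eff

    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING

    phenotype = np.r_[np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)]
    samples = pd.DataFrame(
        {
            "sample_id": [f"{cohort_label}_{k:06d}" for k in range(n)],
            "cohort": cohort_label,
            "phenotype": phenotype,
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{v:06d}" for v in range(m)],
            "chrom": np.repeat("1", m),
            # 10 kb spacing keeps the map simple; positions 1-based
            "pos": 10_000 * np.arange(m) + 1,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeDataset(genotypes=geno, samples=samples, snps=snps)


def _stable_offset(label: str) -> int:
    """Small deterministic per-cohort seed offset (independent of PYTHONHASHSEED)."""
    return sum(ord(c) * (31 ** k) for k, c in enumerate(label)) % 100_000


def simulate_expression(genotypes: GenotypeDataset, config: SimulationConfig) -> ExpressionDataset:
    """Expression matrix with planted cis effects and outlier contamination.

    Planted (snp, probe) pairs are positioned at the SNP's coordinate so they
    fall inside a 1 Mb cis window; the last probe is placed on another
    chromosome as a decoy that every cis filter must exclude.
    """
    if config.outlier_frac >= 0.5:
        raise ValueError("outlier fraction must be < 0.5")
    rng = np.random.default_rng(config.seed + 7_777)
    n = genotypes.n_samples
    n_probes = config.n_probes
    for (snp, probe) in config.cis_pairs:
        if not (0 <= snp < genotypes.n_snps and 0 <= probe < n_probes):
            raise ValueError(f"planted pair ({snp},{probe}) out of range")

    sd = np.full((n_probes, n), config.expr_sigma)
    if config.outlier_frac > 0:
        out = rng.random((n_probes, n)) < config.outlier_frac
        sd[out] *= config.outlier_scale
    values = config.expr_mu + rng.normal(0.0, 1.0, size=(n_probes, n)) * sd

    chroms = np.repeat("1", n_probes).astype(object)
    positions = 5_000_000 + 2_000_000 * np.arange(n_probes)  # > 1 Mb apart by default
    genes = [f"GENE{p}" for p in range(n_probes)]
    for (snp, probe), b in config.cis_pairs.items():
        g = genotypes.genotypes[:, snp].astype(float)
        g[g == MISSING] = np.nan
        values[probe] += b * np.nan_to_num(g, nan=np.nanmean(g) if np.isfinite(np.nanmean(g)) else 0.0)
        positions[probe] = int(genotypes.snps["pos"].iloc[snp])
        chroms[probe] = genotypes.snps["chrom"].iloc[snp]
    # decoy probe guaranteed outside any cis window
    chroms[n_probes - 1] = "22"
    positions[n_probes - 1] = 1_000_000

    probes = pd.DataFrame(
        {
            "probe_id": [f"probe{p}" for p in range(n_probes)],
            "gene": genes,
            "chrom": chroms.astype(str),
            "pos": positions,
        }
    )
    return ExpressionDataset(values=values, probes=probes,
                             samples=list(genotypes.samples["sample_id"]))


def simulate_ld_block(
    n_samples: int,
    block_size: int,
    maf: float,
    latent_corr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Correlated genotype block via a latent Gaussian copula.

    Each SNP's latent variable shares a common factor with loading
    sqrt(latent_corr), so every latent pair has correlation ``latent_corr``;
    latents are cut at the Hardy-Weinberg genotype-class quantiles for the
    given MAF.  Discretization attenuates the dosage correlation, so very
    high latent correlations are needed for dosage r^2 above ~0.9.
    """
    load = np.sqrt(latent_corr)
    shared = rng.normal(size=n_samples)
    latent = load * shared[:, None] + np.sqrt(1 - load * load) * rng.normal(
        size=(n_samples, block_size)
    )
    p = maf
    cuts = norm.ppf([(1 - p) ** 2, (1 - p) ** 2 + 2 * p * (1 - p)])
    return np.digitize(latent, cuts).astype(np.int8)


def simulate_annotation(
    config: SimulationConfig,
    n_genes: int = 30,
    genes_per_set: int = 5,
    n_sets: int = 6,
) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Toy gene table and GMT gene sets tiling the simulated chromosome.

    Genes are 10 kb long, spaced 50 kb start-to-start, so consecutive genes
    are 40 kb apart end-to-start and their +/-20 kb flanked intervals
    touch exactly at the midpoint; the first two genes are placed 30 kb
    apart and share the first set, so flank-overlap fusion is exercised.
    """
    rng = np.random.default_rng(config.seed + 13_131)
    starts = 1 + 50_000 * np.arange(n_genes)
    ends = starts + 10_000 - 1
    starts[1] = ends[0] + 30_001  # gene0/gene1 separated by 30 kb
    ends[1] = starts[1] + 10_000 - 1
    gene_table = pd.DataFrame(
        {
            "gene": [f"G{k}" for k in range(n_genes)],
            "chrom": "1",
            "start": starts,
            "end": ends,
        }
    )
    gene_sets: Dict[str, List[str]] = {"SET0": ["G0", "G1"]}
    names = gene_table["gene"].tolist()
    for s in range(1, n_sets):
        members = sorted(rng.choice(names, size=genes_per_set, replace=False))
        gene_sets[f"SET{s}"] = members
    return gene_table, gene_sets
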