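"""Calibration and parameter-recovery studies run on synthetic cohorts.

These routines exercise the pipeline end to end at desk scale and return
the summary numbers (type-I error rates, recovery fractions, estimator
means) used by the validation suite and the reproduction script.  Every
routine takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .heritability import (
    compute_grm,
    estimate_h2_observed,
    liability_transform,
    simulate_liability_cohort,
)
from .interaction import interaction_odds_ratio, pairwise_scan, wz_interaction_test
from .meta import meta_scan
from .simulate import SimulationConfig, simulate_cohort
from .types import GenotypeDataset
from .eqtl import huber_fit


def _raw_dataset(genotypes: np.ndarray, phenotype: np.ndarray) -> GenotypeDataset:
    n, m = genotypes.shape
    samples = pd.DataFrame(
        {"sample_id": [f"s{k}" for k in range(n)], "cohort": "SIM", "phenotype": phenotype}
    )
    snps = pd.DataFrame(
        {"snp_id": [f"v{k}" for k in range(m)], "chrom": "1",
         "pos": 10_000 * np.arange(m) + 1, "a1": "A", "a2": "G"}
    )
    return GenotypeDataset(genotypes=genotypes, samples=samples, snps=snps)


def wz_null_calibration(
    n_pairs: int = 10_000,
    n_cases: int = 1000,
    n_controls: int = 1000,
    seed: int = 0,
) -> Dict[str, float]:
    """Type-I error and uniformity of the interaction test under the null.

    Simulates ``n_pairs`` disjoint pairs of independent Hardy-Weinberg SNPs
    with case/control labels carrying no genetic signal, runs the
    correlation-contrast test on each pair, and reports the rejection rate
    at alpha = 0.05 plus the Kolmogorov-Smirnov p-value against
    Uniform(0, 1).
    """
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    m = 2 * n_pairs
    mafs = rng.uniform(0.05, 0.5, size=m)
    g = (
        (rng.random((n, m)) < mafs).view(np.int8)
        + (rng.random((n, m)) < mafs).view(np.int8)
    )
    phen = np.r_[np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)]
    ds = _raw_dataset(g, phen)
    pvals = np.empty(n_pairs)
    for k in range(n_pairs):
        res = wz_interaction_test(ds, 2 * k, 2 * k + 1)
        pvals[k] = res.p_wz if not res.skipped else 1.0
    ks = stats.kstest(pvals, "uniform")
    return {
        "type1_at_005": float((pvals < 0.05).mean()),
        "ks_pvalue": float(ks.pvalue),
        "n_pairs": n_pairs,
    }


def planted_pair_recovery(
    n_seeds: int = 20,
    gamma: float = math.log(3.0),
    beta: float = math.log(1.5),
    n_cases: int = 500,
    n_controls: int = 500,
    m_snps: int = 1000,
    seed: int = 0,
) -> Dict[str, float]:
    """Fraction of simulated studies whose planted pair tops the meta table.

    Two cohorts per study with one interacting pair (dosage-product
    log-odds ``gamma``; per-allele marginal ``beta`` on both members so the
    pair survives the marginal pre-filter); success means the planted pair
    ranks first by combined p-value in the two-cohort meta-analysis.
    """
    hits = 0
    for s in range(n_seeds):
        cfg = SimulationConfig(
            n_cases=n_cases, n_controls=n_controls, m_snps=m_snps,
            marginal_effects={0: beta, 1: beta},
            interaction_effects={(0, 1): gamma},
            seed=seed + 1000 * s,
        )
        scans = [
            pairwise_scan(
                simulate_cohort(cfg, label), marginal_alpha=1e-3, with_logistic=False
            )
            for label in ("UK", "DE")
        ]
        res = meta_scan(scans[0], scans[1])
        if res and {res[0].snp1_id, res[0].snp2_id} == {"snp000000", "snp000001"}:
            hits += 1
    return {"rank1_fraction": hits / n_seeds, "n_seeds": n_seeds}


def interaction_or_recovery(
    n_reps: int = 200,
    gamma: float = math.log(1.5),
    n_cases: int = 2000,
    n_controls: int = 2000,
    seed: int = 0,
) -> Dict[str, float]:
    """Mean interaction OR estimate and 95% Wald CI coverage.

    Cohorts are generated with a single interacting pair and no marginal
    effects; the logistic product-term model is refit each replicate.
    """
    ors, covered = [], 0
    used = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_cases=n_cases, n_controls=n_controls, m_snps=2,
            interaction_effects={(0, 1): gamma},
            seed=seed + 1000 * rep,
        )
        ds = simulate_cohort(cfg, "SIM")
        or_, lo, hi, _, flag = interaction_odds_ratio(ds, 0, 1)
        if flag:
            continue
        used += 1
        ors.append(or_)
        covered += lo <= math.exp(gamma) <= hi
    return {
        "mean_or": float(np.mean(ors)),
        "coverage": covered / used,
        "n_reps": used,
    }


def huber_vs_ols(
    n_reps: int = 200,
    b: float = 0.5,
    n: int = 600,
    outlier_frac: float = 0.1,
    outlier_scale: float = 10.0,
    seed: int = 0,
) -> Dict[str, float]:
    """Paired comparison of Huber and ordinary least squares under
    contamination: median absolute slope error on identical data."""
    err_h, err_o = [], []
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        x = rng.binomial(2, 0.3, size=n).astype(float)
        sd = np.where(rng.random(n) < outlier_frac, outlier_scale, 1.0)
        y = 7.0 + b * x + rng.normal(0, 1, n) * sd
        err_h.append(abs(huber_fit(x, y)[0] - b))
        err_o.append(abs(np.polyfit(x, y, 1)[0] - b))
    return {
        "huber_median_abs_error": float(np.median(err_h)),
        "ols_median_abs_error": float(np.median(err_o)),
        "n_reps": n_reps,
    }


def h2_liability_recovery(
    n_reps: int = 50,
    h2_true: float = 0.2,
    K: float = 0.01,
    n_cases: int = 500,
    n_controls: int = 500,
    m_snps: int = 2000,
    seed: int = 0,
) -> Dict[str, float]:
    """Mean liability-scale heritability estimate across replicate cohorts.

    Each replicate draws a liability-threshold case-control cohort, builds
    the GRM over all (causal-tagging) SNPs, estimates the observed-scale
    variance fraction by Haseman-Elston regression and converts it to the
    liability scale with the ascertainment correction.
    """
    ests = []
    for rep in range(n_reps):
        ds = simulate_liability_cohort(
            h2_true, K, n_cases, n_controls, m_snps, seed=seed + 1000 * rep
        )
        grm = compute_grm(ds)
        y = ds.phenotype.astype(float)
        h2_obs, _ = estimate_h2_observed(grm, y, n_jackknife_blocks=2)
        ests.append(liability_transform(h2_obs, K, float(y.mean())))
    arr = np.asarray(ests)
    return {
        "mean_h2_liability": float(arr.mean()),
        "sd_h2_liability": float(arr.std()),
        "n_reps": n_reps,
    }
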