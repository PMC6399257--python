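"""Marginal pre-filter and the correlation-contrast SNP-SNP interaction test.

The interaction statistic contrasts the Pearson correlation of two SNPs'
dosages between cases and controls,

    T = (r_cases - r_controls)^2 / (Var(r_cases) + Var(r_controls)),

with Var(r) = (1 - r^2)^2 / (n - 3) (delta-method variance of the sample
correlation) and the p-value taken from the upper tail of chi-square with
1 df.  Under the null of equal genotype correlation in the two groups this
is asymptotically chi-square(1); its calibration is verified empirically in
the test suite.

The pre-filter excludes SNPs with weak single-marker association
(Cochran-Armitage trend P above ``marginal_alpha``, default 1e-3), which
deflates the pair-scan space; interaction odds ratios come from an
unconditional logistic regression with a dosage product term.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import MISSING, GenotypeDataset, PairResult

MIN_GROUP_N = 5


def _trend_pvalue_from_vectors(g: np.ndarray, y: np.ndarray) -> Tuple[float, bool]:
    """Cochran-Armitage trend test with additive scores 0/1/2.

    Uses the identity T = N * corr(score, outcome)^2 ~ chi-square(1).
    Returns (p, monomorphic_flag); a monomorphic SNP yields p = 1 flagged.
    """
    ok = g != MISSING
    g = g[ok].astype(float)
    y = y[ok].astype(float)
    n = g.size
    if n == 0 or g.std() == 0 or y.std() == 0:
        return 1.0, True
    r = np.corrcoef(g, y)[0, 1]
    return float(stats.chi2.sf(n * r * r, df=1)), False


def marginal_trend_test(dataset: GenotypeDataset, snp: int) -> float:
    """Single-marker additive trend-test p-value for one SNP."""
    p, _ = _trend_pvalue_from_vectors(dataset.genotypes[:, snp], dataset.phenotype)
    return p


def marginal_trend_pvalues(dataset: GenotypeDataset) -> np.ndarray:
    """Vectorized trend p-values for every SNP (pairwise-complete samples)."""
    g = dataset.genotypes.astype(float)
    g[g == MISSING] = np.nan
    y = dataset.phenotype.astype(float)
    obs = ~np.isnan(g)
    n = obs.sum(axis=0)
    gz = np.nan_to_num(g)
    sum_g = gz.sum(axis=0)
    sum_g2 = (gz * gz).sum(axis=0)
    sum_y = obs.T @ y
    sum_y2 = obs.T @ (y * y)
    sum_gy = gz.T @ y
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sum_gy / n - (sum_g / n) * (sum_y / n)
        var_g = sum_g2 / n - (sum_g / n) ** 2
        var_y = sum_y2 / n - (sum_y / n) ** 2
        t = n * cov * cov / (var_g * var_y)
    p = np.where((var_g > 0) & (var_y > 0) & (n > 0), stats.chi2.sf(t, df=1), 1.0)
    return p


def correlation_variance(r: float, n: int) -> float:
    """Delta-method variance of a sample Pearson correlation, (1-r^2)^2/(n-3).

    Kept as a single swappable function: it is the one modelling choice in
    the contrast statistic, and its adequacy is established empirically by
    the null-calibration tests rather than asserted.
    """
    return (1.0 - r * r) ** 2 / (n - 3)


def wz_statistic(r_cases: float, n_cases: int, r_controls: float, n_controls: int) -> Tuple[float, float]:
    """Correlation-contrast statistic and its chi-square(1) p-value."""
    t = (r_cases - r_controls) ** 2 / (
        correlation_variance(r_cases, n_cases) + correlation_variance(r_controls, n_controls)
    )
    return float(t), float(stats.chi2.sf(t, df=1))


def wz_interaction_test(
    dataset: GenotypeDataset, snp_i: int, snp_j: int
) -> PairResult:
    """Correlation-contrast interaction test for one SNP pair."""
    ids = dataset.snps["snp_id"]
    res = PairResult(snp1_id=ids.iloc[snp_i], snp2_id=ids.iloc[snp_j])
    gi = dataset.genotypes[:, snp_i]
    gj = dataset.genotypes[:, snp_j]
    case = dataset.is_case
    complete = (gi != MISSING) & (gj != MISSING)

    stats_by_group = {}
    for label, mask in (("cases", complete & case), ("controls", complete & ~case)):
        a = gi[mask].astype(float)
        b = gj[mask].astype(float)
        n = a.size
        if n < MIN_GROUP_N:
            res.skipped, res.skip_reason = True, f"n_{label}<{MIN_GROUP_N}"
            return res
        if a.std() == 0 or b.std() == 0:
            res.skipped, res.skip_reason = True, f"zero_variance_{label}"
            return res
        r = float(np.corrcoef(a, b)[0, 1])
        stats_by_group[label] = (r, correlation_variance(r, n), n)

    r_a, var_a, n_a = stats_by_group["cases"]
    r_n, var_n, n_n = stats_by_group["controls"]
    res.r_cases, res.r_controls = r_a, r_n
    res.var_r_cases, res.var_r_controls = var_a, var_n
    res.n_cases_used, res.n_controls_used = n_a, n_n
    res.t_wz, res.p_wz = wz_statistic(r_a, n_a, r_n, n_n)
    return res


def interaction_odds_ratio(
    dataset: GenotypeDataset, snp_i: int, snp_j: int, maxiter: int = 50
) -> Tuple[float, float, float, float, str]:
    """Interaction odds ratio exp(b3) from the product-term logistic model.

    Fits logit P(case) = b0 + b1 x_i + b2 x_j + b3 x_i x_j by Newton
    iteration (iteratively reweighted least squares) on pairwise-complete
    samples.  Returns (or_int, ci_low, ci_high, p_wald, flag); the flag is
    empty on success, else "nonconvergence" or "separation".
    """
    gi = dataset.genotypes[:, snp_i].astype(float)
    gj = dataset.genotypes[:, snp_j].astype(float)
    ok = (gi != MISSING) & (gj != MISSING)
    x1, x2 = gi[ok], gj[ok]
    y = dataset.phenotype[ok]
    X = np.column_stack([np.ones(x1.size), x1, x2, x1 * x2])
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=maxiter, warn_convergence=False)
    except Exception:
        return np.nan, np.nan, np.nan, np.nan, "separation"
    if not fit.mle_retvals.get("converged", False):
        return np.nan, np.nan, np.nan, np.nan, "nonconvergence"
    b3 = fit.params[3]
    se = fit.bse[3]
    if abs(b3) > 15 or not np.isfinite(se):
        return np.nan, np.nan, np.nan, np.nan, "separation"
    z = b3 / se
    p = 2 * stats.norm.sf(abs(z))
    return (
        float(np.exp(b3)),
        float(np.exp(b3 - 1.96 * se)),
        float(np.exp(b3 + 1.96 * se)),
        float(p),
        "",
    )


def pairwise_scan(
    dataset: GenotypeDataset,
    marginal_alpha: float = 1e-3,
    with_logistic: bool = True,
    min_group_n: int = MIN_GROUP_N,
) -> List[PairResult]:
    """Test all unordered pairs among SNPs passing the marginal filter.

    SNPs with trend p-value above ``marginal_alpha`` are excluded before
    pairing; results (tested plus skipped, ``m*(m-1)/2`` records for ``m``
    passing SNPs) are sorted ascending by the interaction p-value.
    """
    p_marg = marginal_trend_pvalues(dataset)
    passing = np.flatnonzero(p_marg <= marginal_alpha)
    results: List[PairResult] = []
    for a in range(passing.size):
        for b in range(a + 1, passing.size):
            i, j = int(passing[a]), int(passing[b])
            res = wz_interaction_test(dataset, i, j)
            if not res.skipped and with_logistic:
                or_, lo, hi, p_log, flag = interaction_odds_ratio(dataset, i, j)
                res.or_int, res.ci_low, res.ci_high, res.p_logistic = or_, lo, hi, p_log
                if flag:
                    res.skip_reason = flag
            results.append(res)
    results.sort(key=lambda r: (r.skipped, r.p_wz if np.isfinite(r.p_wz) else np.inf))
    return results
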