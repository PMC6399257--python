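"""Two-cohort combination of per-pair interaction results.

P-values are combined with Fisher's statistic X = -2 * sum(ln p), referred
to chi-square with 2k degrees of freedom (equivalently the upper tail of a
Gamma(k, 2)); four degrees of freedom for two cohorts.  With non-unit
weights a Satterthwaite-matched gamma reference is used.  Interaction odds
ratios are combined by fixed-effect inverse-variance weighting on the log
scale, with per-cohort standard errors recovered from the 95% Wald limits.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import MetaPairResult, PairResult


def fisher_combine(
    p_values: Sequence[float], weights: Optional[Sequence[float]] = None
) -> Tuple[float, int, float]:
    """Combine independent p-values; returns (X, df, combined p).

    Unit weights give the classic Fisher chi-square reference with
    df = 2k exactly; supplied weights use the gamma approximation with
    moment-matched scale and shape.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    k = p.size
    df = 2 * k
    if weights is None:
        x = float(-2.0 * np.log(p).sum())
        return x, df, float(stats.chi2.sf(x, df))
    w = np.asarray(weights, dtype=float)
    if w.shape != p.shape or np.any(w <= 0):
        raise ValueError("weights must be positive, one per p-value")
    x = float(-2.0 * (w * np.log(p)).sum())
    mean, var = 2.0 * w.sum(), 4.0 * (w * w).sum()
    scale = var / (2.0 * mean)
    f = 2.0 * mean * mean / var
    return x, df, float(stats.chi2.sf(x / scale, f))


def fixed_effect_or_meta(
    or_list: Sequence[float], ci_list: Sequence[Tuple[float, float]]
) -> Tuple[float, float, float]:
    """Inverse-variance fixed-effect meta-analysis of odds ratios.

    Per-cohort standard errors are recovered from the 95% Wald confidence
    limits as (ln high - ln low) / (2 * 1.96).
    """
    ors = np.asarray(or_list, dtype=float)
    if np.any(ors <= 0):
        raise ValueError("odds ratios must be positive")
    los = np.array([c[0] for c in ci_list], dtype=float)
    his = np.array([c[1] for c in ci_list], dtype=float)
    if np.any(his <= los):
        raise ValueError("degenerate CI (high <= low)")
    se = (np.log(his) - np.log(los)) / (2 * 1.96)
    w = 1.0 / (se * se)
    log_or = float((w * np.log(ors)).sum() / w.sum())
    se_meta = float(1.0 / np.sqrt(w.sum()))
    return (
        float(np.exp(log_or)),
        float(np.exp(log_or - 1.96 * se_meta)),
        float(np.exp(log_or + 1.96 * se_meta)),
    )


def _pair_key(r: PairResult) -> Tuple[str, str]:
    return tuple(sorted((r.snp1_id, r.snp2_id)))


def meta_scan(
    results_a: Sequence[PairResult],
    results_b: Sequence[PairResult],
    gw_alpha: float = 5e-10,
) -> List[MetaPairResult]:
    """Combine two cohorts' scans over the pairs tested (unskipped) in both.

    The correlation-contrast p-values are Fisher-combined (df = 4); odds
    ratios are meta-analyzed by fixed effect when both cohorts report one.
    Pairs are flagged significant at ``gw_alpha`` and sorted ascending by
    the combined p-value.
    """
    index_a: Dict[Tuple[str, str], PairResult] = {
        _pair_key(r): r for r in results_a if not r.skipped
    }
    out: List[MetaPairResult] = []
    for rb in results_b:
        if rb.skipped:
            continue
        ra = index_a.get(_pair_key(rb))
        if ra is None:
            continue
        x, df, p_meta = fisher_combine([ra.p_wz, rb.p_wz])
        m = MetaPairResult(
            snp1_id=ra.snp1_id,
            snp2_id=ra.snp2_id,
            p_per_cohort=(ra.p_wz, rb.p_wz),
            x_comb=x,
            df=df,
            p_meta=p_meta,
            significant=bool(p_meta < gw_alpha),
        )
        if all(np.isfinite([ra.or_int, rb.or_int, ra.ci_low, rb.ci_low, ra.ci_high, rb.ci_high])):
            m.or_meta, m.ci_low, m.ci_high = fixed_effect_or_meta(
                [ra.or_int, rb.or_int],
                [(ra.ci_low, ra.ci_high), (rb.ci_low, rb.ci_high)],
            )
        out.append(m)
    out.sort(key=lambda r: r.p_meta)
    return out
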