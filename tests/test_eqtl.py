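"""Probe filtering, Huber robust regression, LD pruning and the SMR test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from episcan.eqtl import (
    WindowError,
    cis_eqtl_huber,
    filter_expression_probes,
    holm_sidak_alpha,
    huber_fit,
    ld_prune,
    smr_test,
)
from episcan.types import ExpressionDataset

from conftest import make_dataset


def _expr(values, chroms, positions, samples):
    n_probes = values.shape[0]
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{k}" for k in range(n_probes)],
            "gene": [f"g{k}" for k in range(n_probes)],
            "chrom": chroms,
            "pos": positions,
        }
    )
    return ExpressionDataset(values=values, probes=probes, samples=samples)


def test_probe_filter_low_signal_and_autosome_rules():
    n = 100
    vals = np.vstack(
        [
            np.full(n, 3.4),                             # all below 3.5 -> removed
            np.r_[np.full(94, 3.4), np.full(6, 8.0)],    # 94% below -> kept
            np.full(n, 9.0),                             # autosomal, strong -> kept
            np.full(n, 9.0),                             # chrX -> removed
        ]
    )
    expr = _expr(vals, ["1", "1", "2", "X"], [100, 200, 300, 400], [f"s{k}" for k in range(n)])
    out = filter_expression_probes(expr)
    assert list(out.probes["probe_id"]) == ["p1", "p2"]


def test_probe_filter_boundary_is_at_least_95_percent():
    n = 100
    vals = np.r_[np.full(95, 3.4), np.full(5, 8.0)][None, :]
    expr = _expr(vals, ["1"], [100], [f"s{k}" for k in range(n)])
    assert filter_expression_probes(expr).n_probes == 0  # exactly 95% low -> removed


def test_huber_matches_ols_on_clean_data(rng):
    x = rng.binomial(2, 0.4, size=500).astype(float)
    y = 1.0 + 0.3 * x + rng.normal(0, 1, 500)
    slope, se, p, icpt = huber_fit(x, y)
    ols = np.polyfit(x, y, 1)[0]
    assert slope == pytest.approx(ols, abs=0.02)


def test_huber_beats_ols_under_contamination():
    errs_h, errs_o = [], []
    for k in range(40):
        rng = np.random.default_rng(k)
        x = rng.binomial(2, 0.3, size=600).astype(float)
        sd = np.where(rng.random(600) < 0.1, 10.0, 1.0)
        y = 2.0 + 0.5 * x + rng.normal(0, 1, 600) * sd
        errs_h.append(abs(huber_fit(x, y)[0] - 0.5))
        errs_o.append(abs(np.polyfit(x, y, 1)[0] - 0.5))
    assert np.median(errs_h) < np.median(errs_o)


def test_huber_type_one_error_calibrated():
    hits = 0
    reps = 400
    for k in range(reps):
        rng = np.random.default_rng(10_000 + k)
        x = rng.binomial(2, 0.3, size=300).astype(float)
        y = rng.normal(0, 1, 300)
        hits += huber_fit(x, y)[2] < 0.05
    assert 0.03 <= hits / reps <= 0.07


def _cis_setup(rng, offset, n=200):
    g = rng.binomial(2, 0.3, size=(n, 1)).astype(np.int8)
    ds = make_dataset(g, positions=[5_000_000])
    y = 7.0 + 0.5 * g[:, 0] + rng.normal(0, 1, n)
    expr = _expr(y[None, :], ["1"], [5_000_000 + offset], list(ds.samples["sample_id"]))
    return ds, expr


def test_cis_window_boundary_inclusive(rng):
    ds, expr = _cis_setup(rng, 1_000_000)
    rec = cis_eqtl_huber(expr, ds, 0, 0)
    assert rec is not None and rec.n_used == 200


def test_cis_window_excludes_pair_one_bp_beyond(rng):
    ds, expr = _cis_setup(rng, 1_000_001)
    with pytest.raises(WindowError):
        cis_eqtl_huber(expr, ds, 0, 0)


def test_cis_eqtl_recovers_planted_effect(rng):
    ds, expr = _cis_setup(rng, 0, n=600)
    rec = cis_eqtl_huber(expr, ds, 0, 0)
    assert rec.beta_zx == pytest.approx(0.5, abs=3 * rec.se_zx)
    assert rec.p_eqtl < 1e-6


@pytest.mark.parametrize(
    "m,expected",
    [(1, 0.05), (2, 1 - np.sqrt(0.95)), (239, 1 - 0.95 ** (1 / 239))],
)
def test_holm_sidak_alpha_values(m, expected):
    assert holm_sidak_alpha(m) == pytest.approx(expected, rel=1e-12)


def test_holm_sidak_published_rounding():
    assert round(holm_sidak_alpha(239), 4) == 0.0002


def test_holm_sidak_decreasing_in_m():
    alphas = [holm_sidak_alpha(m) for m in (1, 5, 50, 500)]
    assert all(a <= 0.05 + 1e-12 for a in alphas)
    assert alphas == sorted(alphas, reverse=True)
    with pytest.raises(ValueError):
        holm_sidak_alpha(0)


def test_ld_prune_drops_duplicated_column(rng):
    g = rng.binomial(2, 0.3, size=(100, 3)).astype(np.int8)
    g[:, 1] = g[:, 0]
    ds = make_dataset(g, positions=[1000, 2000, 3000])
    pruned = ld_prune(ds)
    assert list(pruned.snps["snp_id"]) == ["v0", "v2"]


def test_ld_prune_keeps_independent_snps(rng):
    g = rng.binomial(2, 0.3, size=(300, 40)).astype(np.int8)
    ds = make_dataset(g)
    assert ld_prune(ds).n_snps == 40


def test_ld_prune_correlated_block_keeps_one(rng):
    from episcan.simulate import simulate_ld_block

    # copula block whose dosage pairwise r^2 lands around 0.95
    g = simulate_ld_block(500, 5, maf=0.3, latent_corr=0.9998, rng=rng)
    corr = np.corrcoef(g.T)
    assert (corr[np.triu_indices(5, 1)] ** 2).min() > 0.9
    ds = make_dataset(g, positions=1000 * np.arange(5) + 1)
    pruned = ld_prune(ds, r2_max=0.9)
    assert pruned.n_snps == 1


def test_smr_arithmetic_example():
    rec = smr_test(0.2, 0.05, 0.5, 0.1)
    assert rec.beta_xy == pytest.approx(0.4, rel=1e-12)
    assert rec.t_smr == pytest.approx(16 * 25 / 41, rel=1e-12)
    assert rec.p_smr == pytest.approx(1.79e-3, rel=0.01)


def test_smr_zero_gwas_effect():
    rec = smr_test(0.0, 0.1, 0.5, 0.1)
    assert rec.beta_xy == 0.0 and rec.p_smr == pytest.approx(1.0)
    with pytest.raises(ValueError):
        smr_test(0.1, -1.0, 0.5, 0.1)


@settings(max_examples=200, deadline=None)
@given(
    bzy=st.floats(-3, 3), sezy=st.floats(0.01, 1),
    bzx=st.floats(-3, 3), sezx=st.floats(0.01, 1),
)
def test_smr_p_never_beats_either_input(bzy, sezy, bzx, sezx):
    rec = smr_test(bzy, sezy, bzx, sezx)
    p_gwas = stats.chi2.sf((bzy / sezy) ** 2, 1)
    p_eqtl = stats.chi2.sf((bzx / sezx) ** 2, 1)
    assert rec.p_smr >= max(p_gwas, p_eqtl) - 1e-12
    assert rec.t_smr <= min((bzy / sezy) ** 2, (bzx / sezx) ** 2) + 1e-12


def test_smr_antisymmetric_in_eqtl_sign():
    a = smr_test(0.3, 0.1, 0.6, 0.2)
    b = smr_test(0.3, 0.1, -0.6, 0.2)
    assert b.beta_xy == pytest.approx(-a.beta_xy, rel=1e-12)
    assert b.t_smr == pytest.approx(a.t_smr, rel=1e-12)
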