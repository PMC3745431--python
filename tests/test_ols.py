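"""The least-squares engine against exact and library oracles."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from interpower import (
    RankDeficientDesignError,
    ReplicateDataset,
    ScenarioSpec,
    SimulationSettings,
    draw_predictors,
    fit_interaction_model,
    generate_replicate,
    simulate_pvalues,
)
from interpower.ols import batch_interaction_pvalues


def _dataset(x1, x2, y):
    x1, x2, y = map(np.asarray, (x1, x2, y))
    return ReplicateDataset(x1=x1, x2=x2, x1x2=x1 * x2, y=y)


def _random_dataset(rng, kind="cont_cont", n=60, beta3=0.3):
    spec = ScenarioSpec(pair_kind=kind, n=n, beta3=beta3, alpha=0.05)
    return generate_replicate(spec, draw_predictors(kind, n, rng), rng)


def test_noise_free_data_is_interpolated_exactly(rng):
    spec = ScenarioSpec(pair_kind="cont_cont", n=80, beta3=0.39, alpha=0.05, sigma=1e-14)
    data = generate_replicate(spec, draw_predictors("cont_cont", 80, rng), rng)
    fit = fit_interaction_model(data)
    assert np.allclose(fit.beta_hat, [1.0, 1.0, 1.0, 0.39], atol=1e-6)
    assert fit.p_interaction < 1e-10
    assert fit.df_resid == 76


def test_matches_exact_rational_normal_equations():
    # 8-row integer fixture: solve (X'X) b = X'y in exact rational arithmetic.
    x1 = [1, 2, -1, 0, 3, -2, 1, 2]
    x2 = [0, 1, 1, -1, 2, 0, -2, 1]
    y = [2, 7, -1, 1, 17, -3, 3, 8]
    data = _dataset(x1, x2, y)

    Xf = [[Fraction(1), Fraction(a), Fraction(b), Fraction(a * b)] for a, b in zip(x1, x2)]
    yf = [Fraction(v) for v in y]
    ata = [[sum(r[i] * r[j] for r in Xf) for j in range(4)] for i in range(4)]
    aty = [sum(r[i] * v for r, v in zip(Xf, yf)) for i in range(4)]
    # Gaussian elimination over the rationals
    M = [row[:] + [rhs] for row, rhs in zip(ata, aty)]
    for col in range(4):
        piv = next(r for r in range(col, 4) if M[r][col] != 0)
        M[col], M[piv] = M[piv], M[col]
        M[col] = [v / M[col][col] for v in M[col]]
        for r in range(4):
            if r != col and M[r][col] != 0:
                M[r] = [a - M[r][col] * b for a, b in zip(M[r], M[col])]
    exact_beta = [float(M[r][4]) for r in range(4)]

    fit = fit_interaction_model(data)
    assert np.allclose(fit.beta_hat, exact_beta, rtol=0, atol=1e-10)

    # exact residual variance -> exact interaction standard error
    bvec = [M[r][4] for r in range(4)]
    resid = [v - sum(b * xi for b, xi in zip(bvec, row)) for row, v in zip(Xf, yf)]
    rss = sum(r * r for r in resid)
    # (X'X)^{-1}[3,3] via rational inversion of the 4x4
    I4 = [[Fraction(int(i == j)) for j in range(4)] for i in range(4)]
    M2 = [row[:] + I4[i][:] for i, row in enumerate(ata)]
    for col in range(4):
        piv = next(r for r in range(col, 4) if M2[r][col] != 0)
        M2[col], M2[piv] = M2[piv], M2[col]
        M2[col] = [v / M2[col][col] for v in M2[col]]
        for r in range(4):
            if r != col and M2[r][col] != 0:
                M2[r] = [a - M2[r][col] * b for a, b in zip(M2[r], M2[col])]
    inv33 = M2[3][4 + 3]
    exact_se = np.sqrt(float(rss * inv33) / 4)  # df = 8 - 4
    assert fit.se_interaction == pytest.approx(exact_se, rel=1e-10)


def test_agrees_with_statsmodels_to_ten_digits(rng):
    sm = pytest.importorskip("statsmodels.api")
    for kind in ("cont_cont", "cont_dich", "dich_dich"):
        data = _random_dataset(rng, kind=kind, n=75)
        fit = fit_interaction_model(data)
        ref = sm.OLS(data.y, data.design_matrix()).fit()
        assert np.allclose(fit.beta_hat, ref.params, rtol=1e-10, atol=0)
        assert fit.t_interaction == pytest.approx(ref.tvalues[3], rel=1e-10)
        assert fit.p_interaction == pytest.approx(ref.pvalues[3], rel=1e-8, abs=1e-14)
        assert fit.se_interaction == pytest.approx(ref.bse[3], rel=1e-10)


def test_batch_path_matches_single_fit_path(rng):
    n_rep, n = 40, 64
    x1 = rng.standard_normal((n_rep, n))
    x2 = (rng.standard_normal((n_rep, n)) >= 0).astype(float)
    y = 1 + x1 + x2 + 0.3 * x1 * x2 + rng.standard_normal((n_rep, n))
    batch_p = batch_interaction_pvalues(x1, x2, y)
    single_p = [
        fit_interaction_model(_dataset(x1[i], x2[i], y[i])).p_interaction
        for i in range(n_rep)
    ]
    assert np.allclose(batch_p, single_p, rtol=1e-9, atol=1e-12)


def test_residuals_orthogonal_to_design(rng):
    data = _random_dataset(rng, n=120)
    fit = fit_interaction_model(data)
    X = data.design_matrix()
    resid = data.y - X @ fit.beta_hat
    assert np.max(np.abs(X.T @ resid)) < 1e-8 * data.n


@given(shift=st.floats(-50, 50), scale=st.floats(0.01, 100))
def test_p_value_invariant_under_affine_response_changes(shift, scale):
    rng = np.random.default_rng(99)
    data = _random_dataset(rng, n=40)
    base = fit_interaction_model(data)
    moved = fit_interaction_model(_dataset(data.x1, data.x2, scale * data.y + shift))
    assert moved.p_interaction == pytest.approx(base.p_interaction, rel=1e-9, abs=1e-12)
    assert moved.t_interaction == pytest.approx(base.t_interaction, rel=1e-9)


def test_null_p_values_are_uniform():
    # With beta3 = 0 the interaction p-value is exactly U(0,1); a KS test
    # on 4000 simulated replicates should not reject at the 1% level.
    spec = ScenarioSpec(pair_kind="cont_cont", n=40, beta3=0.0, alpha=0.05)
    pvals, _ = simulate_pvalues(spec, SimulationSettings(n_reps=4000, seed=2024))
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_rank_deficient_design_is_reported():
    n = 20
    x1 = np.arange(n, dtype=float)
    x2 = np.zeros(n)  # constant column -> x1x2 also degenerate
    with pytest.raises(RankDeficientDesignError):
        fit_interaction_model(_dataset(x1, x2, np.ones(n)))
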