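"""Regression fits, parameter accounting, and nested tests.

Fits are cross-checked against statsmodels (an independent maximizer of
the same likelihoods) and against closed forms / normal equations.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize

from mixedpc import regression as reg
from mixedpc.variables import VariableSpec, dof


def spec_cont(name="c"):
    return VariableSpec(name, "continuous")


def spec_cat(d, name="g", vtype="nominal"):
    levels = tuple("abcdef"[:d]) if vtype == "nominal" else tuple(
        str(i) for i in range(d))
    return VariableSpec(name, vtype, levels)


# ---------------------------------------------------------------------------
# dummy coding and degrees of freedom


def test_dummy_encoding_reference_and_shape():
    s2 = spec_cat(2)
    assert reg.encode_dummies(["a", "b", "a"], s2).T.tolist() == [[0, 1, 0]]
    s4 = spec_cat(4)
    block = reg.encode_dummies(list("abcdd"), s4)
    assert block.shape == (5, 3)
    # reference level -> all-zero row
    assert block[0].tolist() == [0, 0, 0]
    assert block[1].tolist() == [1, 0, 0]


def test_dummy_encoding_rejects_unseen_level():
    with pytest.raises(reg.UnknownLevelError, match="z"):
        reg.encode_dummies(["a", "z"], spec_cat(3))


@pytest.mark.parametrize("specs,expected", [
    ([spec_cont()], 1),
    ([spec_cat(4)], 3),
    ([spec_cont(), spec_cat(3)], 3),
    ([], 0),
])
def test_dof_summation(specs, expected):
    assert dof(specs) == expected


def test_parameter_count_formulas_on_grid(rng):
    """Par(M) = (d_Y - 1)(Dof + 1) for every multi-equation family, and
    Dof + 1 for linear, over a grid of outcome levels and predictor mixes."""
    n = 400
    for d_y in range(2, 6):
        for dof_z in range(0, 5):
            for dof_x in range(1, 5):
                k = 1 + dof_z + dof_x
                X = np.column_stack(
                    [np.ones(n)] + [rng.standard_normal(n)
                                    for _ in range(dof_z + dof_x)])
                y_codes = rng.integers(0, d_y, size=n)
                fit = reg.fit_multinomial(y_codes, d_y, X)
                assert fit.n_params == (d_y - 1) * k
                spec = spec_cat(d_y, vtype="ordinal")
                levels = np.array(spec.levels, dtype=object)
                ofit = reg.fit_ordered_logit(levels[y_codes], spec, X)
                assert ofit.n_params == (d_y - 1) * k
                assert len(ofit.cut_models) == d_y - 1
                lin = reg.fit_linear(rng.standard_normal(n), X)
                assert lin.n_params == k


# ---------------------------------------------------------------------------
# linear family


def test_linear_fit_matches_normal_equations(rng):
    X = np.column_stack([np.ones(20), rng.standard_normal((20, 2))])
    y = rng.standard_normal(20)
    fit = reg.fit_linear(y, X)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(fit.coef, beta, atol=1e-8)
    assert np.isclose(fit.rss, np.sum((y - X @ beta) ** 2))
    # statsmodels agreement on the Gaussian log-likelihood
    ols = sm.OLS(y, X).fit()
    assert np.isclose(fit.loglik, ols.llf, atol=1e-6)


def test_linear_intercept_only_and_perfect_fit(rng):
    y = rng.standard_normal(50)
    fit = reg.fit_linear(y, np.ones((50, 1)))
    assert np.isclose(fit.rss, np.sum((y - y.mean()) ** 2))
    x = rng.standard_normal(30)
    perfect = reg.fit_linear(x, np.column_stack([np.ones(30), x]))
    assert perfect.rss < 1e-18


def test_linear_rank_deficiency_flagged(rng):
    x = rng.standard_normal(40)
    X = np.column_stack([np.ones(40), x, 2 * x])
    fit = reg.fit_linear(rng.standard_normal(40), X)
    assert not fit.converged
    assert "rank" in fit.message


def test_f_statistic_printed_formula():
    """RSS0=10, RSS1=5, n=20, Par1=3, Par0=2 -> F = (10-5)*17/(5*1) = 17."""
    f0 = reg.FitResult(loglik=0, n_params=2, n_obs=20, converged=True,
                       family="linear", rss=10.0)
    f1 = reg.FitResult(loglik=0, n_params=3, n_obs=20, converged=True,
                       family="linear", rss=5.0)
    F, p = reg.f_test(f0, f1)
    assert np.isclose(F, 17.0)
    assert np.isclose(p, stats.f.sf(17.0, 1, 17))


def test_f_test_no_improvement_gives_p_one():
    f0 = reg.FitResult(loglik=0, n_params=2, n_obs=20, converged=True,
                       family="linear", rss=7.0)
    f1 = reg.FitResult(loglik=0, n_params=3, n_obs=20, converged=True,
                       family="linear", rss=7.0)
    F, p = reg.f_test(f0, f1)
    assert F == 0.0 and p == 1.0
    with pytest.raises(reg.NotNestedError):
        reg.f_test(f1, f0)


def test_f_test_approaches_chi2_tail_at_large_n(rng):
    """The F reference tends to the chi2/df limit as n grows."""
    n = 10_000
    x = rng.standard_normal(n)
    y = 0.03 * x + rng.standard_normal(n)
    fit0 = reg.fit_linear(y, np.ones((n, 1)))
    fit1 = reg.fit_linear(y, np.column_stack([np.ones(n), x]))
    F, p = reg.f_test(fit0, fit1)
    p_chi2 = stats.chi2.sf(F, 1)
    assert np.isclose(p, p_chi2, rtol=0.02)


# ---------------------------------------------------------------------------
# logistic families


def test_binary_intercept_only_closed_form(rng):
    n, k = 80, 27
    y = np.zeros(n)
    y[:k] = 1.0
    fit = reg.fit_binary_logit(y, np.ones((n, 1)))
    expected = k * np.log(k / n) + (n - k) * np.log(1 - k / n)
    assert np.isclose(fit.loglik, expected, atol=1e-8)


def test_binary_logit_matches_statsmodels(rng):
    n = 300
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    eta = X @ np.array([0.3, 0.8, -0.5])
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = reg.fit_binary_logit(y, X)
    smf = sm.Logit(y, X).fit(disp=0)
    assert fit.converged
    assert np.isclose(fit.loglik, smf.llf, atol=1e-6)
    assert np.allclose(fit.coef, smf.params, atol=1e-5)


def test_multinomial_matches_statsmodels_and_numeric_oracle(rng):
    n = 250
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    codes = rng.integers(0, 3, size=n)
    fit = reg.fit_multinomial(codes, 3, X)
    smf = sm.MNLogit(codes, X).fit(disp=0)
    assert np.isclose(fit.loglik, smf.llf, atol=1e-6)

    # small instance against a generic gradient-free maximizer
    n2 = 40
    X2 = np.column_stack([np.ones(n2), rng.standard_normal(n2)])
    c2 = rng.integers(0, 3, size=n2)
    small = reg.fit_multinomial(c2, 3, X2)

    def negll(vec):
        B = vec.reshape(2, 2)
        eta = X2 @ B.T
        full = np.column_stack([np.zeros(n2), eta])
        lse = np.log(np.exp(full).sum(axis=1))
        return -(full[np.arange(n2), c2] - lse).sum()

    res = minimize(negll, np.zeros(4), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000})
    assert np.isclose(small.loglik, -res.fun, atol=1e-6)


def test_binary_parameter_recovery_large_n(rng):
    """Estimates recover the generating coefficients within 3 SE."""
    n = 20_000
    truth = np.array([0.4, -0.7, 0.25])
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-X @ truth))).astype(float)
    fit = reg.fit_binary_logit(y, X)
    smf = sm.Logit(y, X).fit(disp=0)
    assert np.all(np.abs(fit.coef - truth) < 3 * smf.bse)


def test_degenerate_outcome_flagged():
    fit = reg.fit_binary_logit(np.ones(30), np.ones((30, 1)))
    assert not fit.converged


def test_multinomial_param_count_example(rng):
    """d_Y=3, Dof(Z)=2, Dof(X)=1: Par(M0)=6, Par(M1)=8."""
    n = 200
    codes = rng.integers(0, 3, size=n)
    X0 = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    X1 = np.column_stack([X0, rng.standard_normal(n)])
    assert reg.fit_multinomial(codes, 3, X0).n_params == 6
    assert reg.fit_multinomial(codes, 3, X1).n_params == 8


# ---------------------------------------------------------------------------
# generalized ordered logit


def test_ordered_logit_cut_structure(rng):
    n = 300
    spec = spec_cat(4, vtype="ordinal")
    levels = np.array(spec.levels, dtype=object)
    codes = rng.integers(0, 4, size=n)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    fit = reg.fit_ordered_logit(levels[codes], spec, X)
    assert len(fit.cut_models) == 3
    # split j contrasts levels <= j with levels > j; refit each cut
    from scipy.special import expit
    greater = []
    for j, cut in enumerate(fit.cut_models):
        z = (codes > j).astype(float)
        refit = reg.fit_binary_logit(z, X)
        assert np.isclose(cut.loglik, refit.loglik, atol=1e-8)
        greater.append(expit(X @ refit.coef))
    # model log-likelihood: reconstructed category probabilities
    bounds = np.column_stack([np.ones(n), *greater, np.zeros(n)])
    probs = bounds[:, :-1] - bounds[:, 1:]
    expected = np.log(np.clip(probs[np.arange(n), codes], 1e-12, None)).sum()
    assert np.isclose(fit.loglik, expected, atol=1e-8)


def test_ordered_logit_binary_equals_logistic(rng):
    n = 150
    spec = VariableSpec("o", "ordinal", ("0", "1"))
    codes = rng.integers(0, 2, size=n)
    levels = np.array(spec.levels, dtype=object)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    ofit = reg.fit_ordered_logit(levels[codes], spec, X)
    bfit = reg.fit_binary_logit(codes.astype(float), X)
    assert np.isclose(ofit.loglik, bfit.loglik, atol=1e-10)


def test_ordered_logit_empty_cut_flagged(rng):
    spec = spec_cat(3, vtype="ordinal")
    levels = np.array(spec.levels, dtype=object)
    codes = np.concatenate([np.zeros(20, dtype=int), np.ones(20, dtype=int)])
    X = np.ones((40, 1))
    fit = reg.fit_ordered_logit(levels[codes], spec, X)  # level 2 unseen
    assert not fit.converged


# ---------------------------------------------------------------------------
# likelihood-ratio test


def test_lr_test_chi2_oracle_values():
    def mk(ll, k, fam="binary_logit"):
        return reg.FitResult(loglik=ll, n_params=k, n_obs=100, converged=True,
                             family=fam)
    T, df, p, ok = reg.lr_test(mk(-50.0, 1), mk(-50.0 + 3.8415 / 2, 2))
    assert df == 1 and ok
    assert np.isclose(p, stats.chi2.sf(3.8415, 1), atol=1e-12)
    assert np.isclose(p, 0.05, atol=5e-4)
    T, df, p, _ = reg.lr_test(mk(-50.0, 1), mk(-50.0 + 5.9915 / 2, 3))
    assert df == 2
    assert np.isclose(p, 0.05, atol=5e-4)
    # identical likelihoods -> T = 0, p = 1
    T, _, p, _ = reg.lr_test(mk(-50.0, 1), mk(-50.0, 2))
    assert T == 0.0 and p == 1.0


def test_lr_test_rejects_bad_nesting():
    f1 = reg.FitResult(loglik=-10, n_params=3, n_obs=50, converged=True,
                       family="binary_logit")
    f0 = reg.FitResult(loglik=-12, n_params=3, n_obs=50, converged=True,
                       family="binary_logit")
    with pytest.raises(reg.NotNestedError):
        reg.lr_test(f0, f1)
    f_lin = reg.FitResult(loglik=-12, n_params=2, n_obs=50, converged=True,
                          family="linear", rss=1.0)
    with pytest.raises(reg.NotNestedError):
        reg.lr_test(f_lin, f1)


def test_monotone_likelihood_nested_designs(rng):
    """Adding predictors never decreases the maximized log-likelihood."""
    n = 200
    X_full = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
    for family in ("linear", "binary", "multinomial", "ordinal"):
        if family == "linear":
            y = rng.standard_normal(n)
            lls = [reg.fit_linear(y, X_full[:, :k]).loglik for k in (1, 2, 4)]
        elif family == "binary":
            y = (rng.uniform(size=n) < 0.4).astype(float)
            lls = [reg.fit_binary_logit(y, X_full[:, :k]).loglik
                   for k in (1, 2, 4)]
        elif family == "multinomial":
            c = rng.integers(0, 3, size=n)
            lls = [reg.fit_multinomial(c, 3, X_full[:, :k]).loglik
                   for k in (1, 2, 4)]
        else:
            spec = spec_cat(3, vtype="ordinal")
            levels = np.array(spec.levels, dtype=object)
            c = rng.integers(0, 3, size=n)
            lls = [reg.fit_ordered_logit(levels[c], spec, X_full[:, :k]).loglik
                   for k in (1, 2, 4)]
        # the ordered-logit likelihood is scored on the category scale but
        # maximized split-wise, so its monotonicity is only approximate
        slack = 0.05 if family == "ordinal" else 1e-6
        assert lls[0] <= lls[1] + slack <= lls[2] + 2 * slack, family
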