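"""Regression fits and nested tests underlying the CI tests.

Four model families are supported, chosen by outcome type:

* continuous outcome  -> ordinary least squares, compared with an F test;
* binary outcome      -> binary logistic regression;
* nominal outcome     -> multinomial (softmax) logistic regression;
* ordinal outcome     -> generalized ordered logit fit as d-1 cumulative
  binary splits (no proportional-odds constraint), scored by the sum of
  the per-split binomial log-likelihoods.

Likelihood models are fit by Newton's method with step halving
(equivalent to iteratively reweighted least squares at full steps),
stopping when the log-likelihood improves by less than ``tol`` or after
``max_iter`` iterations.  Separation or collinearity is never patched by
regularization: the fit is flagged ``converged=False`` and the caller
decides what to do with it.

Parameter counts follow the dummy-coding accounting: a categorical
variable with d levels contributes d - 1 indicator columns (reference =
first declared level), a continuous variable one column; multi-equation
families multiply the per-equation count by d_Y - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .variables import MixedDataError, VariableSpec, dof

MAX_ITER = 100
LL_TOL = 1e-8
# negative T smaller than this (in magnitude) is rounding noise and clamped
NEG_STAT_TOL = 1e-6


class UnknownLevelError(MixedDataError):
    """A categorical value not present in the variable's declared levels."""


class NotNestedError(ValueError):
    """The two fits handed to a nested test are not a reduced/full pair."""


@dataclass
class FitResult:
    """Summary of one fitted regression model."""

    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    family: str
    rss: Optional[float] = None  # linear fits only
    coef: Optional[np.ndarray] = None
    message: str = ""


@dataclass
class OrderedLogitFit(FitResult):
    """Generalized ordered logit: d_Y - 1 binary splits over the level order.

    ``cut_models`` holds the split fits in order (level_1 split first);
    ``loglik`` is their sum and ``n_params`` the total over splits.
    """

    cut_models: list = field(default_factory=list)


def encode_dummies(values, spec: VariableSpec) -> np.ndarray:
    """Indicator (dummy) encoding of a categorical column.

    Returns an ``n x (d - 1)`` 0/1 array; the first declared level is the
    reference and maps to an all-zero row.
    """
    if not spec.is_categorical:
        raise MixedDataError(f"{spec.name!r} is continuous, nothing to encode")
    arr = np.asarray(values)
    index = {lev: i for i, lev in enumerate(spec.levels)}
    codes = np.empty(arr.shape[0], dtype=np.intp)
    for i, v in enumerate(arr):
        try:
            codes[i] = index[v]
        except KeyError:
            raise UnknownLevelError(
                f"value {v!r} is not a declared level of {spec.name!r} "
                f"(levels: {list(spec.levels)})"
            ) from None
    out = np.zeros((arr.shape[0], spec.n_levels - 1))
    rows = np.nonzero(codes > 0)[0]
    out[rows, codes[rows] - 1] = 1.0
    return out


def level_codes(values, spec: VariableSpec) -> np.ndarray:
    """Integer codes 0..d-1 of a categorical column, in declared level order."""
    if not spec.is_categorical:
        raise MixedDataError(f"{spec.name!r} is continuous")
    index = {lev: i for i, lev in enumerate(spec.levels)}
    try:
        return np.array([index[v] for v in np.asarray(values)], dtype=np.intp)
    except KeyError as e:
        raise UnknownLevelError(
            f"value {e.args[0]!r} is not a declared level of {spec.name!r}"
        ) from None


def design_matrix(data: pd.DataFrame, specs: Sequence[VariableSpec]) -> np.ndarray:
    """Stack an intercept column and the encoded predictor blocks.

    Continuous predictors enter as a single column; nominal and ordinal
    predictors are both dummy-encoded (ordinal order is irrelevant on the
    predictor side of a test).  Column count is 1 + Dof(specs).
    """
    n = len(data)
    blocks = [np.ones((n, 1))]
    for s in specs:
        col = data[s.name].to_numpy()
        if s.is_categorical:
            blocks.append(encode_dummies(col, s))
        else:
            blocks.append(np.asarray(col, dtype=float).reshape(n, 1))
    return np.concatenate(blocks, axis=1)


# ---------------------------------------------------------------------------
# linear family


def fit_linear(y: np.ndarray, X: np.ndarray) -> FitResult:
    """Least-squares fit with Gaussian log-likelihood at the MLE variance."""
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 <= 0.0:
        # perfect fit: the Gaussian likelihood is unbounded
        loglik = np.inf
    else:
        loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    ok = rank == k
    return FitResult(
        loglik=loglik,
        n_params=k,
        n_obs=n,
        converged=ok,
        family="linear",
        rss=rss,
        coef=coef,
        message="" if ok else f"rank-deficient design (rank {rank} < {k})",
    )


def f_test(fit0: FitResult, fit1: FitResult):
    """F test between two nested linear fits on the same data.

    F = (RSS0 - RSS1)(n - Par(M1)) / (RSS1 (Par(M1) - Par(M0))), referred
    to an F(Par(M1) - Par(M0), n - Par(M1)) distribution.
    """
    if fit0.family != "linear" or fit1.family != "linear":
        raise NotNestedError("f_test requires two linear fits")
    if fit0.n_obs != fit1.n_obs:
        raise NotNestedError("fits are on different data (n differs)")
    df1 = fit1.n_params - fit0.n_params
    if df1 <= 0:
        raise NotNestedError(
            f"fit0 (Par={fit0.n_params}) is not nested in fit1 (Par={fit1.n_params})"
        )
    n = fit1.n_obs
    df2 = n - fit1.n_params
    if df2 <= 0:
        raise NotNestedError("no residual degrees of freedom in the full model")
    if fit1.rss == 0.0:
        warnings.warn("full model has zero RSS; p value set to 0", stacklevel=2)
        return np.inf, 0.0
    num = max(fit0.rss - fit1.rss, 0.0)
    F = num * df2 / (fit1.rss * df1)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), p


# ---------------------------------------------------------------------------
# logistic families


def _newton(ll_grad_hess, beta0, max_iter=MAX_ITER, tol=LL_TOL):
    """Maximize a concave log-likelihood by damped Newton steps.

    ``ll_grad_hess(beta)`` returns (ll, grad, hess).  Returns
    (beta, ll, converged, message).
    """
    beta = beta0.copy()
    ll, grad, hess = ll_grad_hess(beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, ll, False, "singular Hessian (collinear or separated data)"
        # step halving: Newton direction, backtrack until the ll improves
        new_ll = -np.inf
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            new_ll, new_grad, new_hess = ll_grad_hess(cand)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            return beta, ll, False, "line search failed"
        delta = new_ll - ll
        beta, ll, grad, hess = cand, new_ll, new_grad, new_hess
        if abs(delta) < tol:
            return beta, ll, True, ""
    return beta, ll, False, f"no convergence in {max_iter} iterations"


def fit_binary_logit(y: np.ndarray, X: np.ndarray) -> FitResult:
    """Binary logistic regression of a 0/1 outcome on a design matrix."""
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if y.min() == y.max():
        return FitResult(
            loglik=0.0, n_params=k, n_obs=n, converged=False,
            family="binary_logit", message="outcome has a single observed class",
        )

    def llgh(beta):
        eta = X @ beta
        # log p = log_expit(eta), log(1-p) = log_expit(-eta): overflow-safe
        ll = float(np.sum(y * special.log_expit(eta)
                          + (1.0 - y) * special.log_expit(-eta)))
        p = special.expit(eta)
        grad = X.T @ (y - p)
        w = p * (1.0 - p)
        hess = -(X.T * w) @ X
        return ll, grad, -hess  # hand Newton the negated Hessian (PSD)

    def solve_form(beta):
        ll, grad, neg_hess = llgh(beta)
        return ll, grad, neg_hess

    beta, ll, ok, msg = _newton(solve_form, np.zeros(k))
    return FitResult(
        loglik=ll, n_params=k, n_obs=n, converged=ok,
        family="binary_logit", coef=beta, message=msg,
    )


def fit_multinomial(codes: np.ndarray, n_classes: int, X: np.ndarray) -> FitResult:
    """Multinomial (softmax) logistic regression.

    ``codes`` are integer class labels 0..n_classes-1; class 0 is the
    reference with a zero linear predictor.  Parameters form a
    (n_classes - 1) x k matrix, counted as (d_Y - 1)(Dof + 1).
    """
    codes = np.asarray(codes, dtype=np.intp)
    n, k = X.shape
    K = n_classes
    if K == 2:
        fit = fit_binary_logit((codes == 1).astype(float), X)
        fit.family = "multinomial"
        return fit
    observed = np.unique(codes)
    if observed.size < 2:
        return FitResult(
            loglik=0.0, n_params=(K - 1) * k, n_obs=n, converged=False,
            family="multinomial", message="outcome has a single observed class",
        )
    # one-hot of the non-reference classes
    Y = np.zeros((n, K - 1))
    pos = codes > 0
    Y[np.nonzero(pos)[0], codes[pos] - 1] = 1.0
    dim = (K - 1) * k

    def llgh(vec):
        B = vec.reshape(K - 1, k)
        eta = X @ B.T  # n x (K-1); reference class has eta 0
        m = np.maximum(eta.max(axis=1), 0.0)
        lse = m + np.log(np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1))
        ll = float((eta * Y).sum() - lse.sum())
        P = np.exp(eta - lse[:, None])  # n x (K-1)
        G = X.T @ (Y - P)  # k x (K-1)
        grad = G.T.ravel()
        hess = np.empty((dim, dim))
        for a in range(K - 1):
            for b in range(a, K - 1):
                w = P[:, a] * ((1.0 if a == b else 0.0) - P[:, b])
                blk = (X.T * w) @ X
                hess[a * k:(a + 1) * k, b * k:(b + 1) * k] = blk
                if b != a:
                    hess[b * k:(b + 1) * k, a * k:(a + 1) * k] = blk
        return ll, grad, hess

    vec, ll, ok, msg = _newton(llgh, np.zeros(dim))
    return FitResult(
        loglik=ll, n_params=dim, n_obs=n, converged=ok,
        family="multinomial", coef=vec.reshape(K - 1, k), message=msg,
    )


def fit_logistic(y, spec: VariableSpec, X: np.ndarray) -> FitResult:
    """Binary or multinomial logistic fit of a nominal outcome, by level count."""
    codes = level_codes(y, spec)
    if spec.n_levels == 2:
        fit = fit_binary_logit((codes == 1).astype(float), X)
        return fit
    return fit_multinomial(codes, spec.n_levels, X)


# reconstructed category probabilities can be incoherent (negative) away
# from the optimum; clamp before taking logs
PROB_FLOOR = 1e-12


def fit_ordered_logit(y, spec: VariableSpec, X: np.ndarray) -> OrderedLogitFit:
    """Generalized ordered logit of an ordinal outcome (Williams fit).

    For each split point j = 1..d-1 a binary logistic regression of
    1{Y > level_j} on the same design is fit.  The model log-likelihood
    is then evaluated on the *category* scale: with G_j = P(Y > level_j)
    from the split fits, P(Y = level_j) = G_{j-1} - G_j, clamped below at
    a tiny floor where the unconstrained splits cross.  Scoring the
    reconstructed categorical likelihood (rather than, say, summing the
    split likelihoods) is what makes the nested test comparable across
    regression directions: it estimates the same KL discrepancy a
    multinomial fit of the outcome would, so the two directional tests
    agree asymptotically.  A split with an empty side cannot be fit and
    flags the whole model as not converged.
    """
    codes = level_codes(y, spec)
    n, k = X.shape
    d = spec.n_levels
    cuts = []
    ok = True
    msgs = []
    greater = np.empty((n, d - 1))  # column j: fitted P(Y > level_{j+1})
    for j in range(d - 1):
        z = (codes > j).astype(float)
        if z.min() == z.max():
            cut = FitResult(
                loglik=0.0, n_params=k, n_obs=n, converged=False,
                family="binary_logit",
                message=f"split {j + 1}: one side of the cut is empty",
            )
            ok = False
            greater[:, j] = np.clip(z.mean(), PROB_FLOOR, 1 - PROB_FLOOR)
        else:
            cut = fit_binary_logit(z, X)
            ok = ok and cut.converged
            greater[:, j] = special.expit(X @ cut.coef)
        if cut.message:
            msgs.append(cut.message)
        cuts.append(cut)
    bounds = np.column_stack([np.ones(n), greater, np.zeros(n)])
    cat_probs = bounds[:, :-1] - bounds[:, 1:]
    picked = cat_probs[np.arange(n), codes]
    incoherent = int((picked <= PROB_FLOOR).sum())
    if incoherent:
        # the unconstrained splits crossed at observed cells: the
        # reconstructed likelihood is not trustworthy here
        ok = False
        msgs.append(f"{incoherent} observation(s) with incoherent "
                    "reconstructed category probability")
    loglik = float(np.log(np.clip(picked, PROB_FLOOR, None)).sum())
    return OrderedLogitFit(
        loglik=loglik, n_params=(d - 1) * k, n_obs=n, converged=ok,
        family="gen_ordered_logit", cut_models=cuts, message="; ".join(msgs),
    )


# ---------------------------------------------------------------------------
# nested tests


def lr_test(fit0: FitResult, fit1: FitResult):
    """Likelihood-ratio test of a reduced against a full fit.

    T = 2 (LL(M1) - LL(M0)) referred to chi^2 with Par(M1) - Par(M0)
    degrees of freedom.  Returns (T, df, p, reliable); ``reliable`` is
    False if either fit did not converge.
    """
    if fit0.family != fit1.family:
        raise NotNestedError(
            f"families differ: {fit0.family} vs {fit1.family}"
        )
    if fit0.n_obs != fit1.n_obs:
        raise NotNestedError("fits are on different data (n differs)")
    df = fit1.n_params - fit0.n_params
    if df <= 0:
        raise NotNestedError(
            f"fit0 (Par={fit0.n_params}) is not nested in fit1 (Par={fit1.n_params})"
        )
    T = 2.0 * (fit1.loglik - fit0.loglik)
    if T < 0.0:
        if T < -NEG_STAT_TOL and fit0.converged and fit1.converged:
            warnings.warn(
                f"negative LR statistic {T:.3g} clamped to 0 "
                "(full fit worse than reduced: optimizer trouble)",
                stacklevel=2,
            )
        T = 0.0
    p = float(stats.chi2.sf(T, df))
    reliable = fit0.converged and fit1.converged
    return float(T), df, p, reliable
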