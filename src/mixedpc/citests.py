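"""Conditional-independence tests for mixed variables.

The directional ("asymmetric") test of X and Y given Z regresses one of
the two variables on the conditioning set with and without the other
variable and compares the nested fits: an F test when the outcome is
continuous, a likelihood-ratio chi-square test otherwise.  Because the
two possible directions need not agree at finite n, four symmetric
wrappers are provided:

* ``mm``   — run both directions and combine the dependent p values as
             min{2 min(p1, p2), max(p1, p2)};
* ``min`` / ``max`` — run both directions and take the smaller / larger
             p value (disjunction / conjunction of the two rejections);
* ``fast`` — run a single direction chosen by a fixed type-priority rule
             (continuous > nominal > ordinal, fewer levels first), made
             deterministic by a name tie-break so the result never
             depends on argument order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from . import regression as reg
from .variables import MixedDataset, VariableSpec

log = logging.getLogger(__name__)

METHODS = ("mm", "min", "max", "fast")


@dataclass
class AsymTestResult:
    """One directional nested test; ``outcome_var`` was regressed on."""

    outcome_var: str
    statistic: float
    df: int
    pvalue: float
    reliable: bool


@dataclass
class SymTestResult:
    """Symmetric p value with its combination method and components.

    ``p2`` is None when only one direction was computed (fast method, or
    the continuous-continuous shortcut where both directions coincide).
    """

    pvalue: float
    method: str
    p1: float
    p2: Optional[float]
    chosen_outcome: str


def combine_mm(p1: float, p2: float) -> float:
    """min{2 min(p1,p2), max(p1,p2)} — dependent p-value combination."""
    return min(max(min(2.0 * min(p1, p2), max(p1, p2)), 0.0), 1.0)


def combine_min(p1: float, p2: float) -> float:
    return min(p1, p2)


def combine_max(p1: float, p2: float) -> float:
    return max(p1, p2)


_PRIORITY = {"continuous": 0, "nominal": 1, "ordinal": 2}


def fast_select(x: VariableSpec, y: VariableSpec) -> VariableSpec:
    """Pick the variable to regress on for the single-direction strategy.

    Continuous beats nominal beats ordinal (the preferred outcome needs
    the smaller model); between two categoricals of the same kind the one
    with fewer levels wins; exact ties fall back to the lexicographically
    smaller name, which keeps the choice invariant to argument order.
    """
    key = lambda s: (_PRIORITY[s.vtype], s.n_levels, s.name)
    return min((x, y), key=key)


def asym_test(
    outcome: str,
    other: str,
    z: Sequence[str],
    data: MixedDataset,
) -> AsymTestResult:
    """Directional test: does ``other`` improve the regression of ``outcome`` on ``z``?

    The model family follows the outcome's type.  Z may be empty, in
    which case the reduced model is intercept-only.  If the fits cannot
    be trusted (non-convergence, empty ordinal split, ...) the result is
    flagged ``reliable=False``.
    """
    z = sorted(z)
    if outcome == other or outcome in z or other in z:
        raise ValueError(
            f"test variables must be distinct from the conditioning set "
            f"(outcome={outcome!r}, other={other!r}, z={z!r})"
        )
    spec_out = data.spec(outcome)
    spec_oth = data.spec(other)
    z_specs = [data.spec(v) for v in z]

    # full design = [intercept | Z block | other block]; the reduced design
    # is its leading columns, so encode once and slice.
    X_full = reg.design_matrix(data.samples, z_specs + [spec_oth])
    n_red = 1 + reg.dof(z_specs)
    X_red = X_full[:, :n_red]
    y = data.column(outcome).to_numpy()

    if spec_out.vtype == "continuous":
        fit0 = reg.fit_linear(y, X_red)
        fit1 = reg.fit_linear(y, X_full)
        if fit1.rss == 0.0:
            log.warning("perfect linear fit for %s; p value 0", outcome)
            return AsymTestResult(outcome, float("inf"), spec_oth.dof, 0.0,
                                  fit0.converged and fit1.converged)
        stat, p = reg.f_test(fit0, fit1)
        return AsymTestResult(outcome, stat, spec_oth.dof, p,
                              fit0.converged and fit1.converged)
    if spec_out.vtype == "nominal":
        fit0 = reg.fit_logistic(y, spec_out, X_red)
        fit1 = reg.fit_logistic(y, spec_out, X_full)
    else:  # ordinal
        fit0 = reg.fit_ordered_logit(y, spec_out, X_red)
        fit1 = reg.fit_ordered_logit(y, spec_out, X_full)
    stat, df, p, reliable = reg.lr_test(fit0, fit1)
    return AsymTestResult(outcome, stat, df, p, reliable)


def symmetric_test(
    x: str,
    y: str,
    z: Sequence[str],
    data: MixedDataset,
    method: str = "mm",
) -> SymTestResult:
    """Symmetric CI test of x and y given z; invariant to swapping x and y."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    sx, sy = data.spec(x), data.spec(y)
    # canonical order so that floating-point results are bit-identical
    # under argument swap
    first, second = sorted((x, y))

    if sx.vtype == "continuous" and sy.vtype == "continuous":
        # both directions provably give the same p value: compute one
        r = asym_test(first, second, z, data)
        return SymTestResult(r.pvalue, method, r.pvalue, None, r.outcome_var)

    if method == "fast":
        chosen = fast_select(sx, sy)
        other = sy if chosen is sx else sx
        r = asym_test(chosen.name, other.name, z, data)
        if not r.reliable:
            alt = asym_test(other.name, chosen.name, z, data)
            if alt.reliable:
                log.warning(
                    "fast direction (%s) unreliable for (%s,%s|%s); "
                    "used the opposite direction", chosen.name, x, y, list(z))
                return SymTestResult(alt.pvalue, method, alt.pvalue, None,
                                     alt.outcome_var)
            log.warning(
                "both directions unreliable for (%s,%s|%s); p=1", x, y, list(z))
            return SymTestResult(1.0, method, r.pvalue, None, r.outcome_var)
        return SymTestResult(r.pvalue, method, r.pvalue, None, r.outcome_var)

    r1 = asym_test(first, second, z, data)
    r2 = asym_test(second, first, z, data)
    if not (r1.reliable and r2.reliable):
        if r1.reliable or r2.reliable:
            ok = r1 if r1.reliable else r2
            log.warning(
                "one direction unreliable for (%s,%s|%s); using the "
                "reliable one (outcome %s)", x, y, list(z), ok.outcome_var)
            return SymTestResult(ok.pvalue, method, ok.pvalue, None,
                                 ok.outcome_var)
        log.warning(
            "both directions unreliable for (%s,%s|%s); p=1", x, y, list(z))
        return SymTestResult(1.0, method, r1.pvalue, r2.pvalue, r1.outcome_var)
    combine = {"mm": combine_mm, "min": combine_min, "max": combine_max}[method]
    p = combine(r1.pvalue, r2.pvalue)
    return SymTestResult(p, method, r1.pvalue, r2.pvalue, r1.outcome_var)
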