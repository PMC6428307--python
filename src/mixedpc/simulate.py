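"""Synthetic mixed-type Bayesian networks and data.

The generator draws a random DAG, attaches linear / generalized-linear
structural equations, and samples data in topological order:

* root continuous variables are standard normal, root categoricals
  uniform over their levels;
* a continuous child is ``b0 + sum_i b_i Pa_i + eps`` with
  ``eps ~ N(0, 1)`` and every coefficient drawn uniformly from
  ``[-1, -0.1] U [0.1, 1]`` (no near-zero effects);
* a nominal child is sampled from a multinomial-logit link whose
  per-category linear predictors use coefficients from the same law;
* an ordinal child is a continuous latent variable discretized into
  2-4 ordered categories, each guaranteed at least 15% of the mass with
  the remainder split at random, so no category is ever rare.

Nominal parents enter the equations through their dummy columns (one
coefficient per non-reference level); ordinal parents enter as integer
scores 0..d-1 with a single coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .graphs import Dag
from .variables import MixedDataset, VariableSpec

COEF_LOW, COEF_HIGH = 0.1, 1.0
ORDINAL_FLOOR = 0.15
NOMINAL_ALPHABET = "abcdefghij"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _make_levels(vtype: str, d: int) -> Tuple[str, ...]:
    if vtype == "ordinal":
        return tuple(str(i + 1) for i in range(d))
    return tuple(NOMINAL_ALPHABET[:d])


@dataclass
class StructuralEquation:
    """Parameters of one child's generating equation.

    For continuous and ordinal children there is a single linear
    predictor (``intercepts`` has length 1); a nominal child with d
    levels carries d - 1 predictors, one per non-reference category.
    ``coefs[parent]`` has one row per predictor and one column per
    parent input column (dummies for nominal parents, a single score
    column for continuous/ordinal parents).
    """

    child: str
    parents: Tuple[str, ...]
    intercepts: np.ndarray
    coefs: Dict[str, np.ndarray]
    noise_scale: float = 1.0


def _parent_columns(spec: VariableSpec) -> int:
    """Input columns a parent contributes: dummies for nominal, score otherwise."""
    if spec.vtype == "nominal":
        return spec.n_levels - 1
    return 1


def _draw_coefs(rng, size) -> np.ndarray:
    """Uniform on [-1, -0.1] U [0.1, 1]: magnitudes bounded away from zero."""
    mag = rng.uniform(COEF_LOW, COEF_HIGH, size=size)
    sign = rng.choice([-1.0, 1.0], size=size)
    return mag * sign


def sample_dag(
    p: int,
    avg_degree: float,
    type_probs: Optional[Dict[str, float]] = None,
    seed=None,
    level_counts: Sequence[int] = (2, 3, 4),
) -> Dag:
    """Random DAG over a random variable order with mixed variable types.

    Each of the p(p-1)/2 order-respecting pairs becomes an edge
    independently with probability ``avg_degree / (p - 1)``, giving the
    requested expected average degree.  Types are drawn from
    ``type_probs`` (default: half continuous, half ordinal); categorical
    level counts are uniform over ``level_counts``.
    """
    if p < 2:
        raise ValueError("need at least two nodes")
    if not 0 <= avg_degree < p:
        raise ValueError(f"avg_degree must be in [0, p), got {avg_degree}")
    rng = _rng(seed)
    if type_probs is None:
        type_probs = {"continuous": 0.5, "ordinal": 0.5}
    kinds = sorted(type_probs)
    weights = np.array([type_probs[k] for k in kinds], dtype=float)
    if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
        raise ValueError(f"type probabilities must be a distribution: {type_probs}")

    width = len(str(p))
    names = [f"V{i + 1:0{width}d}" for i in range(p)]
    order = rng.permutation(p)
    edge_p = avg_degree / (p - 1)
    edges = []
    for i in range(p):
        for j in range(i + 1, p):
            if rng.uniform() < edge_p:
                edges.append((names[order[i]], names[order[j]]))
    specs = []
    for name in names:
        vtype = kinds[rng.choice(len(kinds), p=weights)]
        if vtype == "continuous":
            specs.append(VariableSpec(name, "continuous"))
        else:
            d = int(rng.choice(level_counts))
            specs.append(VariableSpec(name, vtype, _make_levels(vtype, d)))
    return Dag(names, edges, specs={s.name: s for s in specs})


def sample_parameters(dag: Dag, seed=None) -> Dict[str, StructuralEquation]:
    """Draw structural-equation coefficients for every non-root node."""
    rng = _rng(seed)
    eqs: Dict[str, StructuralEquation] = {}
    for node in dag.nodes:
        parents = tuple(dag.parents(node))
        if not parents:
            continue
        spec = dag.specs[node]
        n_pred = spec.n_levels - 1 if spec.vtype == "nominal" else 1
        intercepts = _draw_coefs(rng, n_pred)
        coefs = {
            par: _draw_coefs(rng, (n_pred, _parent_columns(dag.specs[par])))
            for par in parents
        }
        eqs[node] = StructuralEquation(node, parents, intercepts, coefs)
    return eqs


def discretize_ordinal(latent: np.ndarray, n_levels: int, seed=None) -> np.ndarray:
    """Discretize a continuous column into ordered categories 0..n_levels-1.

    Category proportions are 15% plus a uniform (flat-Dirichlet) split of
    the remaining mass; observations are assigned by rank of the latent
    value, so larger latent values never land in a smaller category.
    Returns integer codes.
    """
    latent = np.asarray(latent, dtype=float)
    n = latent.shape[0]
    if n_levels < 2:
        raise ValueError("need at least two categories")
    if int(np.floor(ORDINAL_FLOOR * n)) < 1 or n < n_levels:
        raise ValueError(
            f"n={n} too small to give each of {n_levels} categories "
            f"at least {ORDINAL_FLOOR:.0%} of the observations"
        )
    rng = _rng(seed)
    extra = 1.0 - ORDINAL_FLOOR * n_levels
    props = ORDINAL_FLOOR + extra * rng.dirichlet(np.ones(n_levels))
    # largest-remainder rounding to integer counts summing to n
    raw = props * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    codes = np.empty(n, dtype=np.intp)
    ranks = np.argsort(latent, kind="stable")
    bounds = np.concatenate([[0], np.cumsum(counts)])
    for cat in range(n_levels):
        codes[ranks[bounds[cat]:bounds[cat + 1]]] = cat
    return codes


def _linear_predictors(eq, spec, columns, dag, n):
    """n x n_pred matrix of linear predictors from parent columns."""
    n_pred = eq.intercepts.shape[0]
    eta = np.tile(eq.intercepts, (n, 1))
    for par in eq.parents:
        pspec = dag.specs[par]
        vals = columns[par]
        if pspec.vtype == "nominal":
            codes = vals  # stored as integer codes during generation
            block = np.zeros((n, pspec.n_levels - 1))
            rows = np.nonzero(codes > 0)[0]
            block[rows, codes[rows] - 1] = 1.0
        else:
            block = np.asarray(vals, dtype=float).reshape(n, 1)
        eta += block @ eq.coefs[par].T
    return eta


def sample_data(
    dag: Dag,
    eqs: Dict[str, StructuralEquation],
    n: int,
    seed=None,
) -> MixedDataset:
    """Sample n rows from the structural equations in topological order."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = _rng(seed)
    columns: Dict[str, np.ndarray] = {}
    for node in dag.topological_order():
        spec = dag.specs[node]
        eq = eqs.get(node)
        if eq is None:  # root
            if spec.vtype == "continuous":
                columns[node] = rng.standard_normal(n)
            elif spec.vtype == "nominal":
                columns[node] = rng.integers(0, spec.n_levels, size=n)
            else:
                latent = rng.standard_normal(n)
                columns[node] = discretize_ordinal(latent, spec.n_levels, rng)
            continue
        eta = _linear_predictors(eq, spec, columns, dag, n)
        if spec.vtype == "continuous":
            columns[node] = eta[:, 0] + eq.noise_scale * rng.standard_normal(n)
        elif spec.vtype == "nominal":
            # softmax with an implicit zero predictor for the reference level
            full = np.concatenate([np.zeros((n, 1)), eta], axis=1)
            full -= full.max(axis=1, keepdims=True)
            probs = np.exp(full)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.uniform(size=n)
            columns[node] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        else:
            latent = eta[:, 0] + eq.noise_scale * rng.standard_normal(n)
            columns[node] = discretize_ordinal(latent, spec.n_levels, rng)

    frame = {}
    specs = []
    for node in dag.nodes:
        spec = dag.specs[node]
        specs.append(spec)
        if spec.vtype == "continuous":
            frame[node] = columns[node]
        else:
            levels = np.array(spec.levels, dtype=object)
            frame[node] = levels[np.asarray(columns[node], dtype=np.intp)]
    return MixedDataset(pd.DataFrame(frame), specs)


# ---------------------------------------------------------------------------
# fixed small structures for the test calibration studies

PAIR_TAGS = ("L-B", "L-M", "L-O", "B-O", "M-O")
PAIR_CASES = ("indep", "dep_xy", "dep_yx", "collider", "common_cause")

# L = continuous, B = binary, M = multinomial (4 levels), O = ordinal
# (4 levels: the hardest, most parameter-hungry setting)
_TAG_TYPES = {
    "L": ("continuous", 0),
    "B": ("nominal", 2),
    "M": ("nominal", 4),
    "O": ("ordinal", 4),
}


def _pair_specs(pair: str):
    try:
        tx, ty = pair.split("-")
        (vtx, dx), (vty, dy) = _TAG_TYPES[tx], _TAG_TYPES[ty]
    except (ValueError, KeyError):
        raise ValueError(
            f"unknown pair tag {pair!r}; expected one of {PAIR_TAGS}"
        ) from None
    sx = VariableSpec("X", vtx, _make_levels(vtx, dx) if dx else ())
    sy = VariableSpec("Y", vty, _make_levels(vty, dy) if dy else ())
    return sx, sy


def make_pair_structure(case: str, pair: str, n: int, seed=None) -> MixedDataset:
    """Data from one of the two/three-variable benchmark structures.

    Cases: ``indep`` (X and Y unrelated), ``dep_xy`` / ``dep_yx``
    (X -> Y / Y -> X), ``collider`` (X -> Z <- Y) and ``common_cause``
    (X <- Z -> Y); Z is always continuous.
    """
    if case not in PAIR_CASES:
        raise ValueError(f"unknown case {case!r}; expected one of {PAIR_CASES}")
    rng = _rng(seed)
    sx, sy = _pair_specs(pair)
    nodes = ["X", "Y"]
    specs = {"X": sx, "Y": sy}
    edges = {
        "indep": [],
        "dep_xy": [("X", "Y")],
        "dep_yx": [("Y", "X")],
        "collider": [("X", "Z"), ("Y", "Z")],
        "common_cause": [("Z", "X"), ("Z", "Y")],
    }[case]
    if case in ("collider", "common_cause"):
        nodes.append("Z")
        specs["Z"] = VariableSpec("Z", "continuous")
    dag = Dag(nodes, edges, specs=specs)
    eqs = sample_parameters(dag, rng)
    return sample_data(dag, eqs, n, rng)


def make_linear_blindspot_example(n: int, seed=None) -> MixedDataset:
    """A three-variable network on which linear tests are provably blind.

    Y is uniform over three levels; with Y1, Y2 its dummy indicators,
    X = -Y1 + Y2 + 0.1 eps and Z = Y1 + Y2 + 0.1 eps'.  X and Z are both
    strongly dependent on Y (and hence on each other), yet their
    population correlation is exactly zero, so any test built on linear
    regressions of X on Z cannot see the dependence.
    """
    if n < 3:
        raise ValueError("need at least 3 samples")
    rng = _rng(seed)
    spec_y = VariableSpec("Y", "nominal", ("a", "b", "c"))
    codes = rng.integers(0, 3, size=n)
    y1 = (codes == 1).astype(float)
    y2 = (codes == 2).astype(float)
    x = -y1 + y2 + 0.1 * rng.standard_normal(n)
    z = y1 + y2 + 0.1 * rng.standard_normal(n)
    levels = np.array(spec_y.levels, dtype=object)
    frame = pd.DataFrame({"X": x, "Z": z, "Y": levels[codes]})
    specs = [VariableSpec("X", "continuous"), VariableSpec("Z", "continuous"),
             spec_y]
    return MixedDataset(frame, specs)
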