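"""Graph-recovery metrics and Monte-Carlo harnesses.

Learned networks are scored against the Markov equivalence class of the
generating DAG (its CPDAG), via skeleton and orientation precision /
recall and the structural Hamming distance between PDAGs.  The two
harnesses rerun the full pipeline many times: ``run_calibration``
measures type-I error, power, and the agreement between the two
directional tests on the small fixed structures; ``run_bn_benchmark``
scores PC-stable on random mixed networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .citests import asym_test, combine_mm, fast_select
from .graphs import Dag, GraphError, Pdag
from .pc import apply_meek_rules, pc
from .simulate import make_pair_structure, sample_dag, sample_data, sample_parameters


def spawn_rng(seed) -> np.random.Generator:
    """Accept ints, SeedSequences, Generators or None uniformly."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)

log = logging.getLogger(__name__)


@dataclass
class GraphMetrics:
    skeleton_precision: float
    skeleton_recall: float
    orientation_precision: float
    orientation_recall: float
    shd: int


@dataclass
class CalibrationSummary:
    """One condition (pair x structure x n) of the calibration study."""

    pair: str
    case: str
    n: int
    reps: int
    alpha: float
    rejection: Dict[str, float]   # method -> rejection rate at alpha
    agreement: float              # share of matching 5%-level decisions
    p_correlation: float          # Pearson correlation of p1 and p2
    seed: Optional[int] = None


def dag_to_cpdag(dag: Dag) -> Pdag:
    """The CPDAG of a DAG: v-structure arrows plus Meek propagation.

    Two DAGs are Markov equivalent iff they share skeleton and unshielded
    colliders, so starting from the undirected skeleton, restoring the
    collider arrowheads, and closing under Meek's rules yields exactly
    the compelled-edge representative of the equivalence class.
    """
    undirected = set()
    for a, b in dag.edges:
        undirected.add(frozenset((a, b)))
    pdag = Pdag(dag.nodes, undirected=[tuple(e) for e in undirected])
    for z in dag.nodes:
        parents = dag.parents(z)
        for x, y in combinations(parents, 2):
            if not dag.adjacent(x, y):
                for a in (x, y):
                    if pdag.has_undirected(a, z):
                        pdag.orient(a, z)
    return apply_meek_rules(pdag)


def _edge_marks(pdag: Pdag):
    """Map unordered pair -> mark ('>' tail-head tuple or '-')."""
    marks = {}
    for a, b in pdag.directed:
        marks[frozenset((a, b))] = (a, b)
    for e in pdag.undirected:
        marks[e] = "-"
    return marks


def graph_metrics(estimated: Pdag, truth: Pdag,
                  orientation: str = "exact") -> GraphMetrics:
    """Score an estimated PDAG against the true one.

    Skeleton precision/recall ignore marks.  Orientation precision/recall
    count an estimated edge as correct when the true graph carries the
    same pair with the identical mark (``orientation="exact"``, default)
    or — under ``orientation="arrowhead"`` — when every arrowhead of the
    estimated edge is present in the truth.  SHD charges one unit per
    pair that is missing, extra, or carries the wrong mark.
    """
    if set(estimated.nodes) != set(truth.nodes):
        raise GraphError("estimated and true graphs have different node sets")
    if orientation not in ("exact", "arrowhead"):
        raise ValueError(f"unknown orientation convention {orientation!r}")
    est_skel = estimated.skeleton_pairs()
    true_skel = truth.skeleton_pairs()
    tp = len(est_skel & true_skel)
    if est_skel:
        skel_prec = tp / len(est_skel)
    else:
        skel_prec = 1.0
        log.info("no edges estimated; skeleton precision defined as 1")
    skel_rec = tp / len(true_skel) if true_skel else 1.0

    est_marks = _edge_marks(estimated)
    true_marks = _edge_marks(truth)
    if orientation == "exact":
        ok = sum(1 for e, m in est_marks.items() if true_marks.get(e) == m)
        orient_prec = ok / len(est_marks) if est_marks else 1.0
        orient_rec = ok / len(true_marks) if true_marks else 1.0
    else:
        # arrowhead-wise: an edge is credited when every arrowhead it
        # asserts is also asserted by the other graph (an undirected edge
        # asserts none, so it only needs the adjacency)
        def _credit(claims, reference):
            ok = 0
            for e, m in claims.items():
                if e not in reference:
                    continue
                if m == "-" or reference[e] == m:
                    ok += 1
            return ok
        orient_prec = (_credit(est_marks, true_marks) / len(est_marks)
                       if est_marks else 1.0)
        orient_rec = (_credit(true_marks, est_marks) / len(true_marks)
                      if true_marks else 1.0)

    shd = 0
    for e in est_skel | true_skel:
        if e not in est_skel or e not in true_skel:
            shd += 1
        elif est_marks[e] != true_marks[e]:
            shd += 1
    return GraphMetrics(skel_prec, skel_rec, orient_prec, orient_rec, shd)


# ---------------------------------------------------------------------------
# Monte-Carlo harnesses

_CASE_Z = {"indep": [], "dep_xy": [], "dep_yx": [],
           "collider": ["Z"], "common_cause": ["Z"]}
AGREEMENT_ALPHA = 0.05


def _one_replicate(pair, case, n, rng):
    """p values of the two directional tests on one simulated dataset."""
    data = make_pair_structure(case, pair, n, rng)
    z = _CASE_Z[case]
    r1 = asym_test("X", "Y", z, data)
    r2 = asym_test("Y", "X", z, data)
    return data, r1, r2


def run_calibration(
    pair: str,
    case: str,
    n_grid: Sequence[int],
    reps: int,
    alpha: float = 0.05,
    methods: Sequence[str] = ("mm", "min", "max", "fast"),
    seed=None,
):
    """Monte-Carlo calibration of the symmetric tests on one structure.

    ``case="dep"`` runs both causal directions (X -> Y and Y -> X) for
    ``reps`` replicates each and averages their summaries.  Returns one
    :class:`CalibrationSummary` per entry of ``n_grid``.
    """
    if case == "dep":
        out = []
        ss = seed if isinstance(seed, np.random.SeedSequence) \
            else np.random.SeedSequence(seed)
        for sub_seed, sub_case in zip(ss.spawn(2), ("dep_xy", "dep_yx")):
            out.append(run_calibration(pair, sub_case, n_grid, reps, alpha,
                                       methods, sub_seed))
        merged = []
        for s1, s2 in zip(*out):
            merged.append(CalibrationSummary(
                pair=pair, case="dep", n=s1.n, reps=2 * reps, alpha=alpha,
                rejection={m: (s1.rejection[m] + s2.rejection[m]) / 2
                           for m in methods},
                agreement=(s1.agreement + s2.agreement) / 2,
                p_correlation=(s1.p_correlation + s2.p_correlation) / 2,
                seed=seed if isinstance(seed, int) else None,
            ))
        return merged

    rng = spawn_rng(seed)
    data0 = make_pair_structure(case, pair, max(50, min(n_grid)), rng)
    fast_outcome = fast_select(data0.spec("X"), data0.spec("Y")).name
    summaries = []
    for n in n_grid:
        p1 = np.empty(reps)
        p2 = np.empty(reps)
        for r in range(reps):
            _, r1, r2 = _one_replicate(pair, case, n, rng)
            p1[r], p2[r] = r1.pvalue, r2.pvalue
        combined = {
            "mm": np.array([combine_mm(a, b) for a, b in zip(p1, p2)]),
            "min": np.minimum(p1, p2),
            "max": np.maximum(p1, p2),
            "fast": p1 if fast_outcome == "X" else p2,
        }
        rejection = {m: float(np.mean(combined[m] <= alpha))
                     for m in methods}
        d1 = p1 <= AGREEMENT_ALPHA
        d2 = p2 <= AGREEMENT_ALPHA
        agreement = float(np.mean(d1 == d2))
        if np.std(p1) == 0.0 or np.std(p2) == 0.0:
            corr = 1.0 if np.allclose(p1, p2) else 0.0
        else:
            corr = float(np.corrcoef(p1, p2)[0, 1])
        summaries.append(CalibrationSummary(
            pair=pair, case=case, n=n, reps=reps, alpha=alpha,
            rejection=rejection, agreement=agreement, p_correlation=corr,
            seed=seed if isinstance(seed, int) else None,
        ))
    return summaries


def run_bn_benchmark(
    p: int,
    avg_degree: float,
    n_values: Sequence[int],
    n_networks: int,
    methods: Sequence[str] = ("mm",),
    alpha: float = 0.01,
    seed=None,
    type_probs=None,
    max_k: Optional[int] = None,
) -> pd.DataFrame:
    """PC-stable recovery of random mixed networks, one tidy row per run.

    For every network a fresh DAG and parameter set are drawn, a dataset
    of each requested size is sampled, and each test method's PC output
    is scored against the true CPDAG.  Columns: network, n, method, the
    four precision/recall metrics, shd, plus the edge counts.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(n_networks)
    rows = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        dag = sample_dag(p, avg_degree, type_probs=type_probs, seed=rng)
        eqs = sample_parameters(dag, rng)
        truth = dag_to_cpdag(dag)
        for n in n_values:
            data = sample_data(dag, eqs, n, rng)
            for method in methods:
                res = pc(data, alpha=alpha, method=method, max_k=max_k)
                m = graph_metrics(res.pdag, truth)
                rows.append({
                    "network": i, "n": n, "method": method,
                    "skeleton_precision": m.skeleton_precision,
                    "skeleton_recall": m.skeleton_recall,
                    "orientation_precision": m.orientation_precision,
                    "orientation_recall": m.orientation_recall,
                    "shd": m.shd,
                    "true_edges": truth.n_edges,
                    "estimated_edges": res.pdag.n_edges,
                })
    return pd.DataFrame(rows)


def summarize_benchmark(raw: pd.DataFrame) -> pd.DataFrame:
    """Average the per-network rows into one row per (method, n)."""
    metrics = ["skeleton_precision", "skeleton_recall",
               "orientation_precision", "orientation_recall", "shd"]
    return (raw.groupby(["method", "n"])[metrics]
            .mean().reset_index())
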