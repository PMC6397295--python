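"""Node activity computation and signal propagation on module graphs.

A reaction node's catalytic activity ``n_i`` is computed from the [0,1]
expression of its genes: a complex group scores the min of its genes,
alternative groups (isoenzymes) combine by probabilistic OR.  Activities
then propagate along edges:

    S_i = n_i * (1 - prod_{a in preds(i)} (1 - S_a))

with every entry node receiving one virtual incoming signal of 1, so that
S_entry = n_entry.  Acyclic graphs are evaluated in a single topological
pass; cyclic graphs by least-fixed-point iteration from all-zero S.

All arithmetic is elementwise, so ``n`` values may be scalars or numpy
arrays (one entry per sample) — the vectorized path is what
:func:`activity_matrix` uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConvergenceError, ModactError
from .expression import ExpressionMatrix
from .graph import ModuleGraph, ModuleSet, ReactionNode, initial_nodes, terminal_nodes, topological_order

__all__ = [
    "PropagationState",
    "ActivityMatrix",
    "node_activity",
    "node_activities",
    "propagate",
    "module_activity",
    "activity_matrix",
    "DEFAULT_TOL",
    "DEFAULT_MAX_ITER",
]

log = logging.getLogger(__name__)

DEFAULT_TOL = 1e-9
DEFAULT_MAX_ITER = 1000


@dataclass
class PropagationState:
    """Per-node propagated activities S_i for one sample (or sample vector)."""

    activities: dict[str, np.ndarray | float]
    iterations: int
    converged: bool

    def __getitem__(self, node_id: str):
        return self.activities[node_id]


class ActivityMatrix:
    """Modules x samples matrix of propagated module activities."""

    def __init__(self, data: pd.DataFrame, coverage: dict | None = None):
        self.data = data.astype(float)
        self.coverage = coverage or {}

    @property
    def modules(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, samples) -> "ActivityMatrix":
        return ActivityMatrix(self.data.loc[:, list(samples)], self.coverage)

    def copy(self) -> "ActivityMatrix":
        return ActivityMatrix(self.data.copy(), dict(self.coverage))


def node_activity(node: ReactionNode, expr_column: Mapping[str, float]) -> float:
    """Catalytic activity n_i of one node from [0,1] expression values.

    Complex groups score min over their measured genes; ``single`` groups
    contribute each gene as an independent isoenzyme alternative.  All
    alternatives combine by probabilistic OR.  Genes absent from the
    expression mapping are dropped; a node with nothing measurable is
    permissive (returns 1) with a warning.
    """
    alternatives = []
    for group in node.groups:
        measured = [expr_column[g] for g in group.genes if g in expr_column]
        if not measured:
            continue
        if group.semantics == "complex":
            score = measured[0]
            for m in measured[1:]:
                score = np.minimum(score, m)
            alternatives.append(score)
        else:
            alternatives.extend(measured)
    if not alternatives:
        if node.groups:
            log.warning("node %s: no measured genes, treated as permissive (n=1)", node.node_id)
        return 1.0
    miss = 1.0
    for a in alternatives:
        miss = miss * (1.0 - np.asarray(a, dtype=float))
    return 1.0 - miss


def node_activities(graph: ModuleGraph, expr_column: Mapping[str, float]) -> dict[str, float]:
    """n_i for every node of a module."""
    return {n.node_id: node_activity(n, expr_column) for n in graph.nodes}


def _step(graph: ModuleGraph, n, s, entry: set[str]):
    """One synchronous update of all S_i given current signals ``s``."""
    new = {}
    for node_id in graph.node_ids():
        miss = 1.0
        for p in graph.predecessors(node_id):
            miss = miss * (1.0 - s[p])
        if node_id in entry:
            miss = miss * 0.0  # virtual unit input
        new[node_id] = n[node_id] * (1.0 - miss)
    return new


def propagate(
    graph: ModuleGraph,
    n: Mapping[str, float],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PropagationState:
    """Propagate node activities through the module graph.

    Acyclic graphs are solved exactly in one topological pass; cyclic
    graphs by synchronous fixed-point iteration from all-zero S (which is
    monotone non-decreasing and bounded, hence convergent to the least
    fixed point).
    """
    missing = [i for i in graph.node_ids() if i not in n]
    if missing:
        raise ModactError(f"module {graph.module_id}: node activity missing for {missing}")
    entry = set(initial_nodes(graph))
    order, cycle_nodes = topological_order(graph)
    if order is not None:
        s: dict = {}
        for node_id in order:
            miss = 1.0
            for p in graph.predecessors(node_id):
                miss = miss * (1.0 - s[p])
            if node_id in entry:
                miss = miss * 0.0
            s[node_id] = n[node_id] * (1.0 - miss)
        return PropagationState(activities=s, iterations=1, converged=True)

    zero = np.zeros_like(np.asarray(next(iter(n.values()))) * 0.0)
    s = {i: zero for i in graph.node_ids()}
    for it in range(1, max_iter + 1):
        new = _step(graph, n, s, entry)
        delta = max(float(np.max(np.abs(np.asarray(new[i]) - np.asarray(s[i])))) for i in new)
        s = new
        if delta < tol:
            return PropagationState(activities=s, iterations=it, converged=True)
    raise ConvergenceError(
        f"module {graph.module_id}: propagation did not converge within {max_iter} iterations"
    )


def module_activity(graph: ModuleGraph, state: PropagationState, terminal_rule: str = "mean"):
    """Summarize a propagation state into one module activity value.

    Single terminal: its S.  Multiple terminals: arithmetic mean by
    default, elementwise min with ``terminal_rule="min"``.
    """
    terms = terminal_nodes(graph)
    vals = [np.asarray(state[t], dtype=float) for t in terms]
    if len(vals) == 1:
        return vals[0] if vals[0].ndim else float(vals[0])
    if terminal_rule == "mean":
        out = np.mean(np.stack(vals), axis=0)
    elif terminal_rule == "min":
        out = np.min(np.stack(vals), axis=0)
    else:
        raise ModactError(f"unknown terminal rule {terminal_rule!r} (expected 'mean' or 'min')")
    return out if out.ndim else float(out)


def activity_matrix(
    modules: ModuleSet,
    expr: ExpressionMatrix,
    terminal_rule: str = "mean",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ActivityMatrix:
    """Compute the modules x samples activity matrix.

    Columns are independent: sample s depends only on sample s of the
    expression matrix.  A per-module coverage report (measured-gene
    fraction, permissive nodes, terminal rule) is attached to the result.
    """
    sample_ids = expr.samples
    expr_vec = {g: expr.data.loc[g].to_numpy() for g in expr.genes}
    rows = np.empty((len(modules), len(sample_ids)))
    coverage: dict[str, dict] = {}
    for mi, graph in enumerate(modules):
        n = {}
        permissive = []
        for node in graph.nodes:
            act = node_activity(node, expr_vec)
            if np.isscalar(act) and act == 1.0 and node.groups and not any(
                g in expr_vec for grp in node.groups for g in grp.genes
            ):
                permissive.append(node.node_id)
            if np.isscalar(act):
                act = np.full(len(sample_ids), float(act))
            n[node.node_id] = act
        state = propagate(graph, n, tol=tol, max_iter=max_iter)
        rows[mi] = np.asarray(module_activity(graph, state, terminal_rule))
        mod_genes = graph.genes
        measured = sum(1 for g in mod_genes if g in expr_vec)
        coverage[graph.module_id] = {
            "n_genes": len(mod_genes),
            "measured_gene_fraction": measured / len(mod_genes) if mod_genes else 1.0,
            "permissive_nodes": permissive,
            "terminal_rule": terminal_rule,
        }
        if mod_genes and measured == 0:
            log.warning("module %s: no genes measured; activity computed under permissive policy",
                        graph.module_id)
    df = pd.DataFrame(rows, index=list(modules.module_ids), columns=sample_ids)
    return ActivityMatrix(df, coverage)
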