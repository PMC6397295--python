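"""Seeded generators for module graphs, expression, designs, and survival.

Everything every other module needs to be tested end-to-end with known
ground truth, with no external data.  Also hosts the deliberately naive
propagation oracle used to cross-check the production implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .expression import Design, ExpressionMatrix
from .graph import GeneGroup, ModuleGraph, ModuleSet, ReactionNode, terminal_nodes
from .propagation import ActivityMatrix, DEFAULT_MAX_ITER, DEFAULT_TOL, PropagationState
from .graph import initial_nodes
from .survival import SurvivalRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_module_set",
    "generate_expression",
    "generate_survival",
    "oracle_propagate",
]


@dataclass
class SimulationConfig:
    n_modules: int = 5
    nodes_per_module: tuple[int, int] = (3, 8)
    branching_probability: float = 0.3
    cycle_probability: float = 0.0
    genes_per_node: tuple[int, int] = (1, 3)
    complex_probability: float = 0.3
    n_samples_per_class: int = 20
    class_labels: tuple[str, str] = ("A", "B")
    effect_genes: dict[str, float] = field(default_factory=dict)  # gene -> shift in class 2
    noise_sd: float = 0.1
    censor_rate: float = 0.2
    base_hazard: float = 0.1
    hazard_coefficient: float = 0.0
    hazard_module: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules < 1 or self.n_samples_per_class < 1:
            raise DataError("counts must be positive")
        lo, hi = self.nodes_per_module
        if lo < 1 or hi < lo:
            raise DataError(f"invalid nodes_per_module range {self.nodes_per_module}")
        glo, ghi = self.genes_per_node
        if glo < 0 or ghi < glo:
            raise DataError(f"invalid genes_per_node range {self.genes_per_node}")
        for p in (self.branching_probability, self.cycle_probability,
                  self.complex_probability, self.censor_rate):
            if not (0.0 <= p <= 1.0):
                raise DataError(f"probability out of [0,1]: {p}")
        if self.cycle_probability > 0 and hi < 3:
            raise DataError("cycles need modules of >= 3 nodes")


@dataclass
class GroundTruth:
    """What the generators planted, for assertions downstream."""

    effect_genes: dict[str, float] = field(default_factory=dict)
    affected_modules: dict[str, str] = field(default_factory=dict)  # module_id -> direction
    hazard_module: str | None = None
    hazard_coefficient: float = 0.0


def generate_module_set(config: SimulationConfig) -> ModuleSet:
    """Random module graphs honoring every structural invariant.

    Each module is a forward chain with extra forward edges (branching)
    and, with ``cycle_probability``, one back edge; cyclic modules
    declare entry and terminal nodes explicitly.  Gene ids are unique
    across the set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_counter = 0
    graphs = []
    for mi in range(config.n_modules):
        module_id = f"M{mi:03d}"
        lo, hi = config.nodes_per_module
        n_nodes = int(rng.integers(lo, hi + 1))
        make_cycle = bool(rng.random() < config.cycle_probability) and n_nodes >= 3
        node_ids = [f"{module_id}_n{i}" for i in range(n_nodes)]
        edges: list[tuple[str, str]] = [(node_ids[i], node_ids[i + 1]) for i in range(n_nodes - 1)]
        for j in range(2, n_nodes):
            if rng.random() < config.branching_probability:
                i = int(rng.integers(0, j - 1))
                e = (node_ids[i], node_ids[j])
                if e not in edges:
                    edges.append(e)
        entry_ids = terminal_ids = None
        if make_cycle:
            back_target = int(rng.integers(1, n_nodes - 1))
            e = (node_ids[n_nodes - 1], node_ids[back_target])
            if e not in edges:
                edges.append(e)
            entry_ids = (node_ids[0],)
            terminal_ids = (node_ids[n_nodes - 1],)
        nodes = []
        for node_id in node_ids:
            glo, ghi = config.genes_per_node
            n_genes = int(rng.integers(glo, ghi + 1))
            genes = [f"g{gene_counter + k:05d}" for k in range(n_genes)]
            gene_counter += n_genes
            if n_genes == 0:
                groups: tuple[GeneGroup, ...] = ()
            elif n_genes >= 2 and rng.random() < config.complex_probability:
                groups = (GeneGroup(genes=tuple(genes), semantics="complex"),)
            else:
                groups = tuple(GeneGroup(genes=(g,), semantics="single") for g in genes)
            nodes.append(ReactionNode(node_id=node_id, groups=groups))
        graphs.append(
            ModuleGraph(
                module_id=module_id,
                name=f"synthetic module {mi}",
                species="syn",
                nodes=tuple(nodes),
                edges=tuple(edges),
                entry_ids=entry_ids,
                terminal_ids=terminal_ids,
            )
        )
    return ModuleSet(graphs=tuple(graphs))


def _modules_downstream_of_gene(modules: ModuleSet, gene: str) -> list[str]:
    """Modules where the gene's node reaches a terminal (where a shift in
    the gene can move the module activity)."""
    import networkx as nx

    hits = []
    for graph in modules:
        carrier = [n.node_id for n in graph.nodes if gene in n.genes]
        if not carrier:
            continue
        g = graph.to_networkx()
        terms = set(terminal_nodes(graph))
        for node_id in carrier:
            reach = {node_id} | nx.descendants(g, node_id)
            if reach & terms:
                hits.append(graph.module_id)
                break
    return hits


def generate_expression(
    modules: ModuleSet, config: SimulationConfig
) -> tuple[ExpressionMatrix, Design, GroundTruth]:
    """Two-class expression over the module gene universe.

    Per gene: baseline mean ~ Uniform(0.3, 0.7); per sample, Gaussian
    noise (sd from config) is added and values are clipped to [0,1].
    Effect genes are shifted by their effect size in the second class.
    Ground truth lists the modules whose terminal is reachable from an
    effect gene's node.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    genes = list(modules.gene_universe)
    for gene in config.effect_genes:
        if gene not in genes:
            raise DataError(f"effect gene {gene!r} is not in any module")
    label1, label2 = config.class_labels
    n = config.n_samples_per_class
    samples = [f"s{label1}{i:03d}" for i in range(n)] + [f"s{label2}{i:03d}" for i in range(n)]
    labels = {s: (label1 if i < n else label2) for i, s in enumerate(samples)}
    baseline = rng.uniform(0.3, 0.7, size=len(genes))
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), 2 * n))
    for gene, effect in config.effect_genes.items():
        gi = genes.index(gene)
        values[gi, n:] += effect
    values = np.clip(values, 0.0, 1.0)
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    truth = GroundTruth(effect_genes=dict(config.effect_genes))
    for gene, effect in config.effect_genes.items():
        direction = "up" if effect > 0 else "down"
        for module_id in _modules_downstream_of_gene(modules, gene):
            truth.affected_modules[module_id] = direction
    return expr, Design(labels=labels), truth


def generate_survival(
    act: ActivityMatrix,
    module_id: str,
    coefficient: float,
    seed: int = 0,
    base_hazard: float = 0.1,
    censor_rate: float = 0.2,
) -> list[SurvivalRecord]:
    """Exponential survival times with hazard proportional to
    exp(coefficient * module activity); uniform censoring at the given rate."""
    if module_id not in act.data.index:
        raise DataError(f"module {module_id!r} not in activity matrix")
    rng = np.random.default_rng(seed)
    records = []
    for sample in act.samples:
        a = float(act.data.loc[module_id, sample])
        hazard = base_hazard * np.exp(coefficient * a)
        t = float(rng.exponential(1.0 / hazard))
        if rng.random() < censor_rate:
            records.append(SurvivalRecord(sample=sample, time=float(rng.uniform(0.0, t)), event=0))
        else:
            records.append(SurvivalRecord(sample=sample, time=t, event=1))
    return records


def oracle_propagate(
    graph: ModuleGraph,
    n,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PropagationState:
    """Independent, deliberately naive propagation reference.

    Dense synchronous sweeps from all-zero S with no topological
    shortcut, written from the recurrence directly (shares no code with
    the production implementation).  Test-only.
    """
    entry = set(initial_nodes(graph))
    ids = list(graph.node_ids())
    preds = {v: [] for v in ids}
    for u, v in graph.edges:
        preds[v].append(u)
    s = {i: np.asarray(n[i]) * 0.0 for i in ids}
    iterations = 0
    converged = False
    for _ in range(10 * max_iter):
        new = {}
        for i in ids:
            signals = [s[p] for p in preds[i]]
            if i in entry:
                signals.append(np.asarray(1.0))
            prod_miss = np.asarray(1.0)
            for sig in signals:
                prod_miss = prod_miss * (1.0 - sig)
            new[i] = np.asarray(n[i]) * (1.0 - prod_miss)
        iterations += 1
        delta = max(float(np.max(np.abs(np.asarray(new[i]) - np.asarray(s[i])))) for i in ids)
        s = new
        if delta < tol:
            converged = True
            break
    return PropagationState(activities=s, iterations=iterations, converged=converged)
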