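"""Metabolic module graphs: reaction nodes, gene groups, and their validation.

A module is a small directed graph of reaction nodes.  Each node carries
gene groups: a ``complex`` group requires all of its genes (AND logic),
while several groups on one node act as interchangeable isoenzymes
(OR logic).  Edges point from the simpler toward the more complex
metabolite, so activity flows along edge direction.

Graphs are loaded from a minimal JSON dialect (see :func:`load_module_set`)
instead of any external pathway database.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .errors import GraphValidationError, SchemaError

__all__ = [
    "GeneGroup",
    "ReactionNode",
    "ModuleGraph",
    "ModuleSet",
    "load_module_set",
    "save_module_set",
    "module_set_to_dict",
    "initial_nodes",
    "terminal_nodes",
    "topological_order",
]

_SEMANTICS = ("complex", "single")


@dataclass(frozen=True)
class GeneGroup:
    """One alternative way to carry out a reaction.

    ``complex`` groups need every gene (scored by min); ``single`` groups
    carry independent isoenzymes (each gene is an alternative on its own).
    """

    genes: tuple[str, ...]
    semantics: str = "single"

    def __post_init__(self) -> None:
        if self.semantics not in _SEMANTICS:
            raise SchemaError(
                f"gene group semantics must be one of {_SEMANTICS}, got {self.semantics!r}"
            )
        if not self.genes:
            raise SchemaError("gene group must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise SchemaError(f"duplicate gene identifiers in group: {self.genes}")


@dataclass(frozen=True)
class ReactionNode:
    """A reaction step; ``groups`` may be empty (spontaneous reaction)."""

    node_id: str
    groups: tuple[GeneGroup, ...] = ()
    label: str = ""

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.groups:
            for gene in g.genes:
                seen.setdefault(gene, None)
        return tuple(seen)


@dataclass
class ModuleGraph:
    """Directed reaction graph of one metabolic module."""

    module_id: str
    name: str = ""
    species: str = ""
    nodes: tuple[ReactionNode, ...] = ()
    edges: tuple[tuple[str, str], ...] = ()
    entry_ids: tuple[str, ...] | None = None
    terminal_ids: tuple[str, ...] | None = None

    _by_id: dict[str, ReactionNode] = field(init=False, repr=False, compare=False)
    _preds: dict[str, tuple[str, ...]] = field(init=False, repr=False, compare=False)
    _succs: dict[str, tuple[str, ...]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.edges = tuple((str(u), str(v)) for u, v in self.edges)
        if self.entry_ids is not None:
            self.entry_ids = tuple(self.entry_ids)
        if self.terminal_ids is not None:
            self.terminal_ids = tuple(self.terminal_ids)
        self.validate()

    def validate(self) -> None:
        mid = self.module_id
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GraphValidationError(f"module {mid}: duplicate node_id(s) {dup}")
        self._by_id = {n.node_id: n for n in self.nodes}
        if not self.nodes:
            raise GraphValidationError(f"module {mid}: no nodes")
        for u, v in self.edges:
            for endpoint in (u, v):
                if endpoint not in self._by_id:
                    raise GraphValidationError(
                        f"module {mid}: edge ({u!r}, {v!r}) references undeclared node {endpoint!r}"
                    )
        if len(set(self.edges)) != len(self.edges):
            dup_e = sorted({e for e in self.edges if self.edges.count(e) > 1})
            raise GraphValidationError(f"module {mid}: duplicate edge(s) {dup_e}")
        preds: dict[str, list[str]] = {i: [] for i in ids}
        succs: dict[str, list[str]] = {i: [] for i in ids}
        for u, v in self.edges:
            preds[v].append(u)
            succs[u].append(v)
        self._preds = {k: tuple(v) for k, v in preds.items()}
        self._succs = {k: tuple(v) for k, v in succs.items()}
        for declared, kind in ((self.entry_ids, "entry"), (self.terminal_ids, "terminal")):
            if declared is not None:
                for i in declared:
                    if i not in self._by_id:
                        raise GraphValidationError(
                            f"module {mid}: declared {kind} node {i!r} does not exist"
                        )
        has_source = any(not self._preds[i] for i in ids)
        if not has_source and not self.entry_ids:
            raise GraphValidationError(
                f"module {mid}: no entry point (no in-degree-0 node and no entry_ids declared)"
            )
        has_sink = any(not self._succs[i] for i in ids)
        if not has_sink and not self.terminal_ids:
            raise GraphValidationError(
                f"module {mid}: no terminal node (no out-degree-0 node and no terminal_ids declared)"
            )

    # -- structural queries -------------------------------------------------

    def node(self, node_id: str) -> ReactionNode:
        return self._by_id[node_id]

    def node_ids(self) -> tuple[str, ...]:
        return tuple(n.node_id for n in self.nodes)

    def predecessors(self, node_id: str) -> tuple[str, ...]:
        return self._preds[node_id]

    def successors(self, node_id: str) -> tuple[str, ...]:
        return self._succs[node_id]

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for n in self.nodes:
            for g in n.genes:
                seen.setdefault(g, None)
        return tuple(seen)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids())
        g.add_edges_from(self.edges)
        return g


@dataclass
class ModuleSet:
    """An ordered collection of module graphs sharing one gene namespace."""

    graphs: tuple[ModuleGraph, ...]

    def __post_init__(self) -> None:
        self.graphs = tuple(self.graphs)
        ids = [g.module_id for g in self.graphs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GraphValidationError(f"duplicate module_id(s): {dup}")

    @property
    def gene_universe(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.graphs:
            for gene in g.genes:
                seen.setdefault(gene, None)
        return tuple(seen)

    @property
    def module_ids(self) -> tuple[str, ...]:
        return tuple(g.module_id for g in self.graphs)

    def __iter__(self):
        return iter(self.graphs)

    def __len__(self) -> int:
        return len(self.graphs)

    def get(self, module_id: str) -> ModuleGraph:
        for g in self.graphs:
            if g.module_id == module_id:
                return g
        raise KeyError(module_id)

    def modules_with_gene(self, gene: str) -> tuple[str, ...]:
        return tuple(g.module_id for g in self.graphs if gene in g.genes)


# -- traversal helpers ------------------------------------------------------


def initial_nodes(graph: ModuleGraph) -> list[str]:
    """Nodes that receive the virtual unit input.

    In-degree-0 nodes when any exist; otherwise the declared ``entry_ids``.
    Declared entry_ids are always included (a cyclic graph may declare an
    entry that also has real incoming edges).
    """
    sources = [i for i in graph.node_ids() if not graph.predecessors(i)]
    declared = list(graph.entry_ids or ())
    out = sources + [d for d in declared if d not in sources]
    if not out:
        raise GraphValidationError(f"module {graph.module_id}: no entry point")
    return out


def terminal_nodes(graph: ModuleGraph) -> list[str]:
    """Declared ``terminal_ids`` if present, else all out-degree-0 nodes."""
    if graph.terminal_ids:
        return list(graph.terminal_ids)
    sinks = [i for i in graph.node_ids() if not graph.successors(i)]
    if not sinks:
        raise GraphValidationError(f"module {graph.module_id}: no terminal node")
    return sinks


def topological_order(graph: ModuleGraph) -> tuple[list[str] | None, set[str]]:
    """Return ``(order, cycle_nodes)``.

    ``order`` is a total order with every edge pointing forward when the
    graph is acyclic (then ``cycle_nodes`` is empty); otherwise ``order``
    is None and ``cycle_nodes`` holds every node on some cycle.
    """
    g = graph.to_networkx()
    try:
        order = list(nx.lexicographical_topological_sort(g))
        return order, set()
    except nx.NetworkXUnfeasible:
        cyc: set[str] = set()
        for comp in nx.strongly_connected_components(g):
            if len(comp) > 1 or any(g.has_edge(n, n) for n in comp):
                cyc.update(comp)
        return None, cyc


# -- JSON loading / saving --------------------------------------------------


def _require(d: dict, key: str, ctx: str):
    if key not in d:
        raise SchemaError(f"{ctx}: missing required field {key!r}")
    return d[key]


def _parse_group(raw: dict, ctx: str) -> GeneGroup:
    if not isinstance(raw, dict):
        raise SchemaError(f"{ctx}: group must be an object")
    genes = _require(raw, "genes", ctx)
    if not isinstance(genes, list) or not all(isinstance(g, str) for g in genes):
        raise SchemaError(f"{ctx}: field 'genes' must be a list of strings")
    semantics = raw.get("semantics", "single")
    try:
        return GeneGroup(genes=tuple(genes), semantics=semantics)
    except SchemaError as e:
        raise SchemaError(f"{ctx}: {e}") from None


def _parse_module(raw: dict, index: int) -> ModuleGraph:
    if not isinstance(raw, dict):
        raise SchemaError(f"modules[{index}]: must be an object")
    module_id = _require(raw, "module_id", f"modules[{index}]")
    ctx = f"module {module_id}"
    nodes_raw = _require(raw, "nodes", ctx)
    if not isinstance(nodes_raw, list):
        raise SchemaError(f"{ctx}: field 'nodes' must be a list")
    nodes = []
    for nraw in nodes_raw:
        node_id = _require(nraw, "node_id", ctx)
        nctx = f"{ctx}, node {node_id}"
        groups = tuple(
            _parse_group(graw, nctx) for graw in nraw.get("groups", [])
        )
        nodes.append(ReactionNode(node_id=node_id, groups=groups, label=nraw.get("label", "")))
    edges_raw = raw.get("edges", [])
    if not isinstance(edges_raw, list):
        raise SchemaError(f"{ctx}: field 'edges' must be a list")
    edges = []
    for e in edges_raw:
        if not (isinstance(e, (list, tuple)) and len(e) == 2):
            raise SchemaError(f"{ctx}: edge {e!r} must be a [src, dst] pair")
        edges.append((e[0], e[1]))
    entry = raw.get("entry_ids")
    terminal = raw.get("terminal_ids")
    return ModuleGraph(
        module_id=module_id,
        name=raw.get("name", ""),
        species=raw.get("species", ""),
        nodes=tuple(nodes),
        edges=tuple(edges),
        entry_ids=tuple(entry) if entry is not None else None,
        terminal_ids=tuple(terminal) if terminal is not None else None,
    )


def load_module_set(path) -> ModuleSet:
    """Load and validate a ModuleSet from the documented JSON dialect.

    Order of modules and nodes is preserved from the file.  Raises
    :class:`SchemaError` or :class:`GraphValidationError` naming the
    offending module/node/edge.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as e:
            raise SchemaError(f"{path}: not valid JSON ({e})") from None
    if not isinstance(data, dict) or "modules" not in data:
        raise SchemaError(f"{path}: top level must be an object with a 'modules' list")
    mods = data["modules"]
    if not isinstance(mods, list):
        raise SchemaError(f"{path}: 'modules' must be a list")
    return ModuleSet(graphs=tuple(_parse_module(m, i) for i, m in enumerate(mods)))


def module_set_to_dict(modules: ModuleSet) -> dict:
    out = []
    for g in modules:
        mod: dict = {
            "module_id": g.module_id,
            "name": g.name,
            "species": g.species,
            "nodes": [
                {
                    "node_id": n.node_id,
                    "label": n.label,
                    "groups": [
                        {"semantics": gr.semantics, "genes": list(gr.genes)}
                        for gr in n.groups
                    ],
                }
                for n in g.nodes
            ],
            "edges": [list(e) for e in g.edges],
        }
        if g.entry_ids is not None:
            mod["entry_ids"] = list(g.entry_ids)
        if g.terminal_ids is not None:
            mod["terminal_ids"] = list(g.terminal_ids)
        out.append(mod)
    return {"modules": out}


def save_module_set(modules: ModuleSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(module_set_to_dict(modules), fh, indent=1)
        fh.write("\n")
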