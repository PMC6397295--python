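import json

import numpy as np
import pytest

from modact.graph import GeneGroup, ModuleGraph, ModuleSet, ReactionNode
from modact.synthetic import SimulationConfig, generate_module_set


def single(gene: str) -> GeneGroup:
    return GeneGroup(genes=(gene,), semantics="single")


def make_chain(module_id="chain", genes=("g1", "g2", "g3")) -> ModuleGraph:
    nodes = tuple(
        ReactionNode(node_id=f"n{i}", groups=(single(g),)) for i, g in enumerate(genes)
    )
    edges = tuple((f"n{i}", f"n{i + 1}") for i in range(len(genes) - 1))
    return ModuleGraph(module_id=module_id, nodes=nodes, edges=edges)


@pytest.fixture
def chain_graph():
    return make_chain()


@pytest.fixture
def chain_set(chain_graph):
    return ModuleSet(graphs=(chain_graph,))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dag_set(n_modules, seed, cycle_probability=0.0, nodes=(3, 15)):
    cfg = SimulationConfig(
        n_modules=n_modules,
        nodes_per_module=nodes,
        branching_probability=0.4,
        cycle_probability=cycle_probability,
        genes_per_node=(0, 3),
        complex_probability=0.3,
        seed=seed,
    )
    return generate_module_set(cfg)


def random_node_activities(graph, rng):
    return {i: float(rng.uniform(0, 1)) for i in graph.node_ids()}


def write_modules_json(path, payload: dict) -> str:
    path.write_text(json.dumps(payload))
    return str(path)


def iso_node(node_id: str, *genes: str) -> ReactionNode:
    """Redundant node: interchangeable isoenzymes, robust to single-gene KO."""
    return ReactionNode(node_id=node_id, groups=tuple(single(g) for g in genes))


def planted_auto_ko_case(seed, n_per_class=15, noise_sd=0.05, effect=0.5):
    """Two-class data where KO of one bridge gene ('gstar') is the unique
    best reversion of class B toward class A.

    'gstar' is the only gene on its node; every other node carries three
    interchangeable isoenzymes, so their single-gene KOs barely move the
    module activity.
    """
    from modact.synthetic import SimulationConfig, generate_expression

    m0 = ModuleGraph(
        "M_causal",
        nodes=(iso_node("n0", "a1", "a2", "a3"),
               ReactionNode("n1", groups=(single("gstar"),)),
               iso_node("n2", "b1", "b2", "b3")),
        edges=(("n0", "n1"), ("n1", "n2")),
    )

    def bystander(mid, prefix):
        return ModuleGraph(
            mid,
            nodes=(iso_node("n0", f"{prefix}1", f"{prefix}2", f"{prefix}3"),
                   iso_node("n1", f"{prefix}4", f"{prefix}5", f"{prefix}6"),
                   iso_node("n2", f"{prefix}7", f"{prefix}8", f"{prefix}9")),
            edges=(("n0", "n1"), ("n1", "n2")),
        )

    modules = ModuleSet(graphs=(m0, bystander("M_by1", "c"), bystander("M_by2", "d")))
    cfg = SimulationConfig(
        n_samples_per_class=n_per_class,
        noise_sd=noise_sd,
        effect_genes={"gstar": effect},
        seed=seed,
    )
    expr, design, truth = generate_expression(modules, cfg)
    return modules, expr, design, "gstar"
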