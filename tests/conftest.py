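import numpy as np
import pytest

from metaharm.ontology import OntologyGraph, OntologyTerm


@pytest.fixture
def diamond_graph():
    """Small DAG: A -> {B, C}, B -> D  (edges child is_a parent)."""
    return OntologyGraph([
        OntologyTerm("T:A", "Alpha"),
        OntologyTerm("T:B", "Beta", parents={"T:A"}),
        OntologyTerm("T:C", "Gamma", parents={"T:A"}, synonyms={"ACE inhibitor"}),
        OntologyTerm("T:D", "Delta", parents={"T:B"}),
    ])


@pytest.fixture
def neoplasm_graph():
    return OntologyGraph([
        OntologyTerm("N:1", "Neoplasm"),
        OntologyTerm("N:2", "Primary Neoplasm", parents={"N:1"}),
        OntologyTerm("N:3", "Metastatic Neoplasm", parents={"N:1"}),
    ])


def random_dag(rng: np.random.Generator, max_nodes: int = 50) -> OntologyGraph:
    """Random rooted DAG: each non-root node gets 1-2 parents among earlier
    nodes, so acyclicity is structural."""
    n = int(rng.integers(2, max_nodes + 1))
    terms = [OntologyTerm("R:0", "node 0")]
    for i in range(1, n):
        k = 1 + int(rng.random() < 0.3 and i > 1)
        parents = {f"R:{int(p)}" for p in rng.choice(i, size=min(k, i), replace=False)}
        syn = {f"alias {i}"} if rng.random() < 0.3 else set()
        terms.append(OntologyTerm(f"R:{i}", f"node {i}", parents=parents, synonyms=syn))
    return OntologyGraph(terms)


def brute_relatives(graph: OntologyGraph, node: str, direction: str) -> set:
    """Independent recursive traversal oracle (no memoisation, no obsolete
    filtering shortcuts)."""
    def step(i):
        if direction == "descendants":
            return {t.id for t in graph.terms.values() if i in t.parents}
        return {p for p in graph.terms[i].parents if p in graph.terms}

    out = set()

    def rec(i):
        for j in step(i):
            if j not in out:
                out.add(j)
                rec(j)

    rec(node)
    return {i for i in out if not graph.terms[i].obsolete}
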