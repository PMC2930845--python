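import random

import pytest

from gofunc.ontology import AnnotationRecord, OntologyGraph


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    """A -> (B, C) -> D diamond plus an off-path sibling E of B/C."""
    return OntologyGraph(
        term_ids={"A", "B", "C", "D", "E"},
        is_a_parents={
            "B": {"A"},
            "C": {"A"},
            "E": {"A"},
            "D": {"B", "C"},
        },
        namespace={t: "molecular_function" for t in "ABCDE"},
    )


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """C is_a B is_a A."""
    return OntologyGraph(
        term_ids={"A", "B", "C"},
        is_a_parents={"B": {"A"}, "C": {"B"}},
        namespace={t: "molecular_function" for t in "ABC"},
    )


def random_dag(n_terms: int, rng: random.Random) -> OntologyGraph:
    """Random single-rooted DAG built independently of the package generator."""
    ids = [f"T{i}" for i in range(n_terms)]
    parents = {}
    for i in range(1, n_terms):
        k = rng.randint(1, min(2, i))
        parents[ids[i]] = set(rng.sample(ids[:i], k))
    return OntologyGraph(term_ids=set(ids), is_a_parents=parents)


def brute_force_descendants(graph: OntologyGraph, term: str) -> set:
    """Reachability by fixed-point iteration over direct children (oracle)."""
    child_of = {t: set() for t in graph.term_ids}
    for c, ps in graph.is_a_parents.items():
        for p in ps:
            child_of[p].add(c)
    reach = set(child_of[term])
    while True:
        new = set()
        for t in reach:
            new |= child_of[t]
        if new <= reach:
            return reach
        reach |= new


@pytest.fixture
def toy_annotations() -> list[AnnotationRecord]:
    return [
        AnnotationRecord("P1", "D", "IDA"),   # positive for B via descendant D
        AnnotationRecord("P2", "B", "IEA"),   # electronic: never a positive
        AnnotationRecord("P3", "A", "IDA"),   # ancestor-only: susceptible for B
        AnnotationRecord("P4", "C", "IDA"),   # sibling of B (also under A)
        AnnotationRecord("P5", "E", "TAS"),   # unrelated sibling branch
        AnnotationRecord("P6", "B", "IMP"),   # direct positive for B
    ]
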