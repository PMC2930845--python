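"""Gene Ontology input: OBO ontologies, GAF annotation files, DAG queries.

The ontology is restricted to ``is_a`` edges.  GO also defines ``part_of``
and other relationship types, but for the molecular-function aspect these
are negligible and are deliberately discarded at parse time.  Edges point
from the more specific child term to its more general parent(s); a term may
have several parents, so the structure is a DAG, not a tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet

from .errors import LookupError_, ParseError, ValidationError

#: The 12 evidence codes used by the GOA project.
EVIDENCE_CODES = frozenset(
    {"IDA", "IEP", "IGI", "IMP", "IPI", "RCA", "TAS", "IC", "IEA", "ISS", "NAS", "ND"}
)

#: Experimental / traceable codes accepted when building positive sets.
EXPERIMENTAL_CODES = frozenset({"IDA", "IEP", "IGI", "IMP", "IPI", "RCA", "TAS"})

#: Electronic or ambiguous codes, filtered out of positive sets.
NON_EXPERIMENTAL_CODES = frozenset({"IC", "IEA", "ISS", "NAS", "ND"})


@dataclass(frozen=True)
class AnnotationRecord:
    """One protein-to-term association with its evidence code."""

    protein_id: str
    term_id: str
    evidence_code: str

    def __post_init__(self) -> None:
        if self.evidence_code not in EVIDENCE_CODES:
            raise ValidationError(
                f"unknown evidence code {self.evidence_code!r} "
                f"(expected one of {sorted(EVIDENCE_CODES)})"
            )


@dataclass
class OntologyGraph:
    """An ``is_a`` DAG over GO terms, restricted to one ontology file.

    ``is_a_parents[t]`` is the set of direct parents of ``t``.  Transitive
    queries (:meth:`descendants`, :meth:`ancestors`) exclude the query term
    itself.  Construction validates acyclicity and referential closure.
    """

    term_ids: set[str]
    is_a_parents: dict[str, set[str]]
    namespace: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, parents in self.is_a_parents.items():
            if child not in self.term_ids:
                raise ValidationError(f"edge source {child!r} not a known term")
            missing = parents - self.term_ids
            if missing:
                raise ValidationError(
                    f"term {child!r} lists unknown parent(s) {sorted(missing)}"
                )
        g = self._digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(f"is_a cycle detected: {cycle}")

    def _digraph(self) -> nx.DiGraph:
        """child -> parent edge direction."""
        g = nx.DiGraph()
        g.add_nodes_from(self.term_ids)
        for child, parents in self.is_a_parents.items():
            g.add_edges_from((child, p) for p in parents)
        return g

    def _require(self, term: str) -> None:
        if term not in self.term_ids:
            raise LookupError_(f"unknown term {term!r}")

    def parents(self, term: str) -> set[str]:
        self._require(term)
        return set(self.is_a_parents.get(term, set()))

    def children(self, term: str) -> set[str]:
        self._require(term)
        return {c for c, ps in self.is_a_parents.items() if term in ps}

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward via is_a, excluding ``term``."""
        self._require(term)
        out: set[str] = set()
        stack = list(self.is_a_parents.get(term, set()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.is_a_parents.get(t, set()))
        return out

    def descendants(self, term: str) -> set[str]:
        """All terms reachable downward via is_a, excluding ``term``."""
        self._require(term)
        child_map: dict[str, set[str]] = {}
        for c, ps in self.is_a_parents.items():
            for p in ps:
                child_map.setdefault(p, set()).add(c)
        out: set[str] = set()
        stack = list(child_map.get(term, set()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(child_map.get(t, set()))
        return out

    def siblings(self, term: str) -> set[str]:
        """Terms (other than ``term``) sharing at least one is_a parent."""
        self._require(term)
        sibs: set[str] = set()
        for parent in self.is_a_parents.get(term, set()):
            sibs |= self.children(parent)
        sibs.discard(term)
        return sibs

    def terms_in_namespace(self, aspect: str) -> set[str]:
        return {t for t in self.term_ids if self.namespace.get(t) == aspect}


def parse_obo(path: str | Path | io.TextIOBase) -> OntologyGraph:
    """Read an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Obsolete terms are dropped; only ``is_a`` edges are retained
    (``relationship:`` lines such as part_of are ignored).  A cycle in the
    is_a closure raises :class:`ValidationError`.
    """
    try:
        multigraph = obonet.read_obo(path, ignore_obsolete=True)
    except ValidationError:
        raise
    except Exception as exc:  # malformed stanza, bad tag line, ...
        raise ParseError(f"could not parse OBO file {path!r}: {exc}") from exc

    term_ids = set(multigraph.nodes)
    parents: dict[str, set[str]] = {}
    for child, parent, key in multigraph.edges(keys=True):
        if key != "is_a":
            continue
        if parent not in term_ids:
            # is_a reference to a term with no stanza (or an obsolete one)
            continue
        parents.setdefault(child, set()).add(parent)
    namespace = {
        t: data["namespace"]
        for t, data in multigraph.nodes(data=True)
        if "namespace" in data
    }
    return OntologyGraph(term_ids=term_ids, is_a_parents=parents, namespace=namespace)


def parse_gaf(path: str | Path | io.TextIOBase) -> list[AnnotationRecord]:
    """Read a GAF 2.x file, or the simplified 3-column fixture dialect.

    GAF columns used: 2 (DB object id), 4 (qualifier), 5 (GO id),
    7 (evidence code).  NOT-qualified associations are dropped entirely:
    they are neither positive nor negative evidence here.  The fixture
    dialect is plain ``protein_id<TAB>term_id<TAB>evidence_code``.
    """
    if isinstance(path, (str, Path)):
        handle: io.TextIOBase = open(path)  # noqa: SIM115 - closed below
        close = True
    else:
        handle, close = path, False
    records: list[AnnotationRecord] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) == 3:
                protein, term, code = cols
                qualifier = ""
            elif len(cols) >= 15:  # GAF 2.x has 17 columns; tolerate 15+
                protein, qualifier, term, code = cols[1], cols[3], cols[4], cols[6]
            else:
                raise ParseError(
                    f"line {lineno}: expected 3 or >=15 tab-separated columns, "
                    f"got {len(cols)}"
                )
            if "NOT" in qualifier.split("|"):
                continue
            try:
                records.append(AnnotationRecord(protein, term, code))
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
    finally:
        if close:
            handle.close()
    return records


def write_gaf(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    """Serialize records in the 3-column fixture dialect (lossless)."""
    with open(path, "w") as fh:
        fh.write("!gaf fixture dialect: protein_id\tterm_id\tevidence_code\n")
        for r in records:
            fh.write(f"{r.protein_id}\t{r.term_id}\t{r.evidence_code}\n")
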