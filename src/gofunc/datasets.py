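"""Per-term positive / negative training sets from GO annotations.

For each target term a one-vs-rest training set is built:

* **positives** — proteins annotated to the target term or any is_a
  descendant, with an experimental / traceable evidence code
  (IDA, IEP, IGI, IMP, IPI, RCA, TAS).  Electronic or ambiguous codes
  (IC, IEA, ISS, NAS, ND) never contribute a positive.
* **negatives** — up to ``per_term_cap`` proteins sampled from each
  non-target term, subject to two eligibility conditions:

  1. the protein has no annotation to the target or any descendant;
  2. if it is annotated to an ancestor of the target, it must also be
     annotated to a sibling of the target.

  Proteins failing only condition 2 are "susceptible" — possibly
  under-annotated positives — and are excluded from both sets.

Sampling is reproducible: each source term draws from its own
deterministic substream derived from ``(seed, term_id)``, so adding or
removing one term never perturbs another term's sample.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field

from .errors import GofuncError, LookupError_
from .ontology import (
    EXPERIMENTAL_CODES,
    AnnotationRecord,
    OntologyGraph,
)

#: Broad, uninformative terms dropped from the trainable-term list.  The
#: config may extend this; "binding" is the canonical example of a term too
#: broad to be worth a classifier.
DEFAULT_BLACKLIST_NAMES = frozenset({"binding", "molecular_function"})


@dataclass
class TermDataset:
    """Positive / negative protein-id sets for one GO term."""

    term_id: str
    positives: set[str]
    negatives: set[str]
    excluded_susceptible: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise GofuncError(
                f"{self.term_id}: positives and negatives overlap: "
                f"{sorted(self.positives & self.negatives)[:5]}"
            )
        overlap = self.excluded_susceptible & (self.positives | self.negatives)
        if overlap:
            raise GofuncError(
                f"{self.term_id}: susceptible proteins leaked into training sets: "
                f"{sorted(overlap)[:5]}"
            )


def _annotations_by_protein(
    annotations: list[AnnotationRecord],
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for rec in annotations:
        out.setdefault(rec.protein_id, set()).add(rec.term_id)
    return out


def _term_scope(graph: OntologyGraph, term: str) -> set[str]:
    """The target term together with its is_a descendants."""
    return {term} | graph.descendants(term)


def annotated_proteins(
    term: str,
    annotations: list[AnnotationRecord],
    graph: OntologyGraph,
    accepted_evidence: frozenset[str] = EXPERIMENTAL_CODES,
) -> set[str]:
    """Distinct proteins associated with ``term`` (direct or via descendants)
    after evidence filtering."""
    scope = _term_scope(graph, term)
    return {
        r.protein_id
        for r in annotations
        if r.term_id in scope and r.evidence_code in accepted_evidence
    }


def filter_terms(
    annotations: list[AnnotationRecord],
    graph: OntologyGraph,
    min_products: int = 100,
    blacklist: frozenset[str] | set[str] = frozenset(),
    accepted_evidence: frozenset[str] = EXPERIMENTAL_CODES,
    aspect: str | None = "molecular_function",
) -> set[str]:
    """Terms with at least ``min_products`` associated gene products.

    A product counts if it has an accepted-evidence annotation to the term
    or one of its is_a descendants.  ``blacklist`` removes broad terms
    regardless of size.  ``aspect=None`` disables namespace filtering.
    """
    if min_products < 1:
        raise ValueError(f"min_products must be >= 1, got {min_products}")
    if not annotations:
        return set()
    candidates = graph.term_ids
    if aspect is not None and graph.namespace:
        candidates = {t for t in candidates if graph.namespace.get(t) == aspect}
    kept = set()
    for term in candidates:
        if term in blacklist:
            continue
        if len(annotated_proteins(term, annotations, graph, accepted_evidence)) >= min_products:
            kept.add(term)
    return kept


def build_positive_set(
    term: str,
    annotations: list[AnnotationRecord],
    graph: OntologyGraph,
    accepted_evidence: frozenset[str] = EXPERIMENTAL_CODES,
) -> set[str]:
    """Proteins annotated to ``term`` or an is_a descendant with accepted
    evidence."""
    if term not in graph.term_ids:
        raise LookupError_(f"unknown term {term!r}")
    return annotated_proteins(term, annotations, graph, accepted_evidence)


def _substream(seed: int, term_id: str) -> random.Random:
    """Deterministic per-term RNG independent of Python hash randomization."""
    digest = hashlib.blake2b(
        f"{seed}|{term_id}".encode(), digest_size=8
    ).digest()
    return random.Random(int.from_bytes(digest, "big"))


def build_negative_set(
    term: str,
    annotations: list[AnnotationRecord],
    graph: OntologyGraph,
    per_term_cap: int = 10,
    seed: int = 0,
    accepted_evidence: frozenset[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Sample negatives from every non-target term; flag susceptible proteins.

    Returns ``(negatives, excluded_susceptible)``.  ``accepted_evidence``
    is normally ``None``: the evidence filter applies to the positive side
    only, and negatives are drawn from annotated proteins regardless of
    code.  Pass a code set to filter the negative side as well.
    """
    if term not in graph.term_ids:
        raise LookupError_(f"unknown term {term!r}")
    if per_term_cap < 1:
        raise ValueError(f"per_term_cap must be >= 1, got {per_term_cap}")

    usable = (
        annotations
        if accepted_evidence is None
        else [r for r in annotations if r.evidence_code in accepted_evidence]
    )
    by_protein = _annotations_by_protein(usable)
    scope = _term_scope(graph, term)
    ancestors = graph.ancestors(term)
    siblings = graph.siblings(term)

    eligible: set[str] = set()
    susceptible: set[str] = set()
    for protein, terms in by_protein.items():
        if terms & scope:  # condition 1: prospective positive
            continue
        if terms & ancestors and not terms & siblings:  # condition 2
            susceptible.add(protein)
            continue
        eligible.add(protein)

    # Per source term, sample up to the cap from its eligible pool.
    negatives: set[str] = set()
    per_source: dict[str, list[str]] = {}
    for protein in eligible:
        for t in by_protein[protein]:
            if t != term:
                per_source.setdefault(t, []).append(protein)
    for source_term in sorted(per_source):
        pool = sorted(per_source[source_term])
        rng = _substream(seed, source_term)
        if len(pool) <= per_term_cap:
            chosen = pool
        else:
            chosen = rng.sample(pool, per_term_cap)
        negatives.update(chosen)
    return negatives, susceptible


def build_term_dataset(
    term: str,
    annotations: list[AnnotationRecord],
    graph: OntologyGraph,
    per_term_cap: int = 10,
    seed: int = 0,
    accepted_evidence: frozenset[str] = EXPERIMENTAL_CODES,
    apply_evidence_filter_to_negatives: bool = False,
) -> TermDataset:
    """Build the full one-vs-rest dataset for one term."""
    positives = build_positive_set(term, annotations, graph, accepted_evidence)
    negatives, susceptible = build_negative_set(
        term,
        annotations,
        graph,
        per_term_cap=per_term_cap,
        seed=seed,
        accepted_evidence=accepted_evidence if apply_evidence_filter_to_negatives else None,
    )
    # A protein can reach the eligible pool through a non-experimental record
    # while also being an experimental positive is impossible (condition 1
    # uses all records), but guard the invariant explicitly.
    negatives -= positives
    susceptible -= positives | negatives
    return TermDataset(
        term_id=term,
        positives=positives,
        negatives=negatives,
        excluded_susceptible=susceptible,
    )


def write_manifest(
    dataset: TermDataset,
    annotations: list[AnnotationRecord],
    path,
) -> None:
    """TSV manifest: protein_id, role (pos/neg/susceptible), source_term,
    evidence_codes."""
    by_protein: dict[str, list[AnnotationRecord]] = {}
    for r in annotations:
        by_protein.setdefault(r.protein_id, []).append(r)
    rows = []
    for role, ids in (
        ("pos", dataset.positives),
        ("neg", dataset.negatives),
        ("susceptible", dataset.excluded_susceptible),
    ):
        for pid in sorted(ids):
            recs = by_protein.get(pid, [])
            terms = ",".join(sorted({r.term_id for r in recs}))
            codes = ",".join(sorted({r.evidence_code for r in recs}))
            rows.append((pid, role, terms, codes))
    with open(path, "w") as fh:
        fh.write("protein_id\trole\tsource_term\tevidence_codes\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
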