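"""Self-contained synthetic worlds: toy GO DAGs, protein families, GAF records.

The generator emulates the raw ingredients of a GO-annotation corpus — an
is_a DAG, protein sequences, and annotation records with mixed evidence
codes — at desk scale, so every pipeline stage can be exercised without
downloads.  Three planted signal types line up one-to-one with the three
classifier families:

* **motif** — a short conserved subsequence inserted into a configured
  fraction (default 0.9) of the family, on a random background;
  invisible to global composition statistics, visible to subsequence
  profiles.
* **composition** — residues drawn from a biased distribution (default:
  Lys/Arg-enriched); invisible to motif detectors, visible to peptide
  statistics.
* **homology** — mutated copies of a common ancestor at a configured
  identity (default 0.6); the natural prey of alignment-based search.

Background residues are uniform over the 20 amino acids by default
(option: Dayhoff frequencies), which keeps composition signals
unambiguous.  Everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import GofuncError
from .ontology import EVIDENCE_CODES, AnnotationRecord, OntologyGraph
from .pepstats import AA20, DAYHOFF_REF

SIGNAL_KINDS = ("motif", "composition", "homology")

_DAYHOFF_P = np.array([DAYHOFF_REF[a] for a in AA20])
_DAYHOFF_P = _DAYHOFF_P / _DAYHOFF_P.sum()


@dataclass(frozen=True)
class SignalSpec:
    """Ground-truth signal planted into one term's family."""

    kind: str
    motif: str | None = None            # motif kind
    bias: dict[str, float] | None = None  # composition kind: residue -> multiplier
    identity: float = 0.6               # homology kind
    fraction: float = 0.9               # motif kind: fraction of carriers

    def __post_init__(self) -> None:
        if self.kind not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal kind {self.kind!r}")


@dataclass
class SyntheticWorld:
    """A complete fixture: ontology + sequences + annotations + ground truth."""

    ontology: OntologyGraph
    sequences: dict[str, str]
    annotations: list[AnnotationRecord]
    signal_registry: dict[str, SignalSpec] = field(default_factory=dict)

    def validate(self) -> None:
        for rec in self.annotations:
            if rec.protein_id not in self.sequences:
                raise GofuncError(f"annotated protein {rec.protein_id} has no sequence")
            if rec.term_id not in self.ontology.term_ids:
                raise GofuncError(f"annotation to unknown term {rec.term_id}")


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def generate_ontology(
    n_terms: int, max_parents: int = 2, seed: int = 0
) -> OntologyGraph:
    """Random single-rooted is_a DAG; acyclic by construction.

    Term i > 0 draws 1..max_parents parents among terms 0..i-1, so every
    edge points toward an earlier term and no cycle can form.
    """
    if n_terms < 3:
        raise ValueError(f"need at least 3 terms, got {n_terms}")
    rng = np.random.default_rng(seed)
    ids = [_term_id(i) for i in range(n_terms)]
    parents: dict[str, set[str]] = {}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        chosen = rng.choice(i, size=k, replace=False)
        parents[ids[i]] = {ids[int(j)] for j in chosen}
    namespace = {t: "molecular_function" for t in ids}
    return OntologyGraph(term_ids=set(ids), is_a_parents=parents, namespace=namespace)


def _random_sequence(rng: np.random.Generator, length: int,
                     p: np.ndarray | None = None) -> str:
    return "".join(rng.choice(list(AA20), size=length, p=p))


def _background_probs(background: str) -> np.ndarray | None:
    if background == "uniform":
        return None
    if background == "dayhoff":
        return _DAYHOFF_P
    raise ValueError(f"unknown background {background!r}")


def generate_term_family(
    term: str,
    n: int,
    signal: SignalSpec,
    length_range: tuple[int, int] = (80, 120),
    seed: int = 0,
    background: str = "uniform",
    id_prefix: str | None = None,
) -> tuple[dict[str, str], SignalSpec]:
    """Generate ``n`` member sequences of one functional family."""
    if n < 2:
        raise ValueError(f"family size must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    p = _background_probs(background)
    prefix = id_prefix or term.replace(":", "_")
    seqs: dict[str, str] = {}

    if signal.kind == "motif":
        motif = signal.motif or _random_sequence(rng, 6)
        if len(motif) > lo:
            raise ValueError("motif longer than the minimum sequence length")
        signal = SignalSpec(kind="motif", motif=motif, fraction=signal.fraction)
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            seq = _random_sequence(rng, length, p)
            if rng.random() < signal.fraction:
                pos = int(rng.integers(0, length - len(motif) + 1))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
            seqs[f"{prefix}_P{i:03d}"] = seq
    elif signal.kind == "composition":
        bias = signal.bias or {"K": 4.0, "R": 4.0}
        base = _DAYHOFF_P if background == "dayhoff" else np.full(20, 1 / 20)
        weights = np.array([base[i] * bias.get(a, 1.0) for i, a in enumerate(AA20)])
        weights = weights / weights.sum()
        signal = SignalSpec(kind="composition", bias=dict(bias))
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            seqs[f"{prefix}_P{i:03d}"] = _random_sequence(rng, length, weights)
    else:  # homology
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_sequence(rng, length, p)
        signal = SignalSpec(kind="homology", identity=signal.identity)
        for i in range(n):
            chars = list(ancestor)
            for j in range(length):
                if rng.random() > signal.identity:
                    chars[j] = AA20[int(rng.integers(0, 20))]
            seqs[f"{prefix}_P{i:03d}"] = "".join(chars)
    return seqs, signal


def generate_annotations(
    world: SyntheticWorld,
    members_by_term: Mapping[str, list[str]],
    evidence_mix: Mapping[str, float] | None = None,
    ancestor_only_fraction: float = 0.0,
    seed: int = 0,
) -> list[AnnotationRecord]:
    """Annotate each family member to its term with a sampled evidence code.

    With probability ``ancestor_only_fraction`` a member is annotated to a
    random proper ancestor of its term *instead* of the term — an
    under-annotated protein, which the dataset rules must treat as
    susceptible rather than negative.
    """
    mix = dict(evidence_mix or {"IDA": 1.0})
    bad = set(mix) - EVIDENCE_CODES
    if bad:
        raise ValueError(f"unknown evidence codes in mix: {sorted(bad)}")
    probs = np.array(list(mix.values()), dtype=float)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("evidence mix must be a probability distribution")
    codes = list(mix)
    rng = np.random.default_rng(seed)
    records: list[AnnotationRecord] = []
    for term, members in members_by_term.items():
        ancestors = sorted(world.ontology.ancestors(term))
        for pid in members:
            code = codes[int(rng.choice(len(codes), p=probs))]
            if ancestors and rng.random() < ancestor_only_fraction:
                target = ancestors[int(rng.integers(0, len(ancestors)))]
            else:
                target = term
            records.append(AnnotationRecord(pid, target, code))
    return records


def generate_world(
    n_terms: int = 12,
    signals: Mapping[str, SignalSpec] | None = None,
    n_signal_terms: int = 3,
    n_per_family: int = 40,
    length_range: tuple[int, int] = (80, 120),
    evidence_mix: Mapping[str, float] | None = None,
    ancestor_only_fraction: float = 0.0,
    background: str = "uniform",
    seed: int = 0,
) -> SyntheticWorld:
    """A complete world: DAG + families on leaf terms + annotations.

    If ``signals`` is not given, ``n_signal_terms`` leaf terms receive
    motif / composition / homology signals in rotation.  Every signal
    term gets a family of ``n_per_family`` members; remaining leaf terms
    each get a small background family (uniform sequences) to populate
    the negative pool.
    """
    rng = np.random.default_rng(seed)
    needed = n_signal_terms if signals is None else len(signals)
    for _attempt in range(100):  # redraw until the DAG has enough leaves
        graph = generate_ontology(n_terms, max_parents=2,
                                  seed=int(rng.integers(2**31)))
        children_count = {t: 0 for t in graph.term_ids}
        for ps in graph.is_a_parents.values():
            for p in ps:
                children_count[p] += 1
        leaves = sorted(t for t, c in children_count.items() if c == 0)
        if len(leaves) >= max(needed, 2):
            break
    if signals is None:
        if len(leaves) < n_signal_terms:
            raise GofuncError(
                f"DAG has only {len(leaves)} leaves for {n_signal_terms} signal terms"
            )
        signals = {
            leaves[i]: SignalSpec(kind=SIGNAL_KINDS[i % 3])
            for i in range(n_signal_terms)
        }
    unknown = set(signals) - graph.term_ids
    if unknown:
        raise GofuncError(f"signal terms not in ontology: {sorted(unknown)}")

    world = SyntheticWorld(ontology=graph, sequences={}, annotations=[])
    members_by_term: dict[str, list[str]] = {}
    for term in sorted(signals):
        fam_seed = int(rng.integers(2**31))
        seqs, realized = generate_term_family(
            term, n_per_family, signals[term], length_range, fam_seed, background
        )
        world.sequences.update(seqs)
        world.signal_registry[term] = realized
        members_by_term[term] = sorted(seqs)
    # background families on the remaining leaves feed the negative pool
    for term in leaves:
        if term in signals:
            continue
        fam_seed = int(rng.integers(2**31))
        seqs, _ = generate_term_family(
            term, max(n_per_family // 2, 5),
            SignalSpec(kind="motif", fraction=0.0),
            length_range, fam_seed, background,
        )
        world.sequences.update(seqs)
        members_by_term[term] = sorted(seqs)

    world.annotations = generate_annotations(
        world, members_by_term, evidence_mix, ancestor_only_fraction,
        seed=int(rng.integers(2**31)),
    )
    world.validate()
    return world


# --- writers: exercise the real parsers with generated fixtures -----------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(sequences):
            fh.write(f">{pid}\n")
            seq = sequences[pid]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: gofunc-synthetic\n")
        for term in sorted(graph.term_ids):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
            ns = graph.namespace.get(term)
            if ns:
                fh.write(f"namespace: {ns}\n")
            for parent in sorted(graph.is_a_parents.get(term, set())):
                fh.write(f"is_a: {parent}\n")
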