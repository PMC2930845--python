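"""Homology-based classifier: k-nearest neighbours under local alignment.

A query is scored against every training sequence with a Smith–Waterman
local alignment (BLOSUM62, gap open 11 / extend 1 — the protein defaults
of the standard local-alignment search tools), and the k highest-scoring
neighbours vote through their scores:

    S = (Sp - Sn) / (Sp + Sn)

where Sp (Sn) is the summed score of positive (negative) neighbours among
the top k.  S is +1 when all k nearest neighbours are positives, -1 when
all are negatives, and 0 when the query has no scoring neighbour at all
(maximum uncertainty, flagged ``no_homology``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ValidationError

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

# Karlin-Altschul gapped constants for BLOSUM62, open 11 / extend 1
_LAMBDA = 0.267
_K = 0.041


@dataclass(frozen=True)
class NeighborHit:
    """One training sequence scoring > 0 against the query."""

    train_protein_id: str
    score: float
    label: bool  # True = positive training example

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError(f"negative alignment score {self.score}")


@dataclass(frozen=True)
class KnnScore:
    """Eq.-style neighbour vote: value = (sp - sn)/(sp + sn) in [-1, 1]."""

    value: float
    sp: float
    sn: float
    k_used: int
    no_homology: bool = False


def validate_sequence(seq: str, what: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"empty {what}")
    bad = set(seq.upper()) - AA_ALPHABET
    if bad:
        raise ValidationError(f"{what} contains non-amino-acid characters {sorted(bad)}")
    return seq.upper()


def make_aligner(
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def raw_to_bits(raw: float) -> float:
    """Convert a raw local-alignment score to bit-score-like units."""
    return (_LAMBDA * raw - math.log(_K)) / math.log(2)


def compute_similarities(
    query: str,
    train: list[tuple[str, str, bool]],
    aligner: Align.PairwiseAligner | None = None,
    use_bits: bool = True,
) -> list[NeighborHit]:
    """Score ``query`` against every (id, sequence, label) training triple.

    Only training sequences with positive raw alignment score yield a hit.
    Hits are sorted by descending score, ties broken by protein id.
    """
    query = validate_sequence(query, "query")
    if aligner is None:
        aligner = make_aligner()
    hits: list[NeighborHit] = []
    for pid, seq, label in train:
        seq = validate_sequence(seq, f"training sequence {pid!r}")
        raw = aligner.score(query, seq)
        if raw <= 0:
            continue
        score = raw_to_bits(raw) if use_bits else raw
        hits.append(NeighborHit(pid, score, bool(label)))
    hits.sort(key=lambda h: (-h.score, h.train_protein_id))
    return hits


def knn_score(hits: list[NeighborHit], k: int = 5) -> KnnScore:
    """Score from the top-k hits; ties at the k-th rank are all included."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not hits:
        return KnnScore(value=0.0, sp=0.0, sn=0.0, k_used=0, no_homology=True)
    ordered = sorted(hits, key=lambda h: (-h.score, h.train_protein_id))
    if len(ordered) > k:
        cutoff = ordered[k - 1].score
        top = [h for h in ordered if h.score >= cutoff]
    else:
        top = ordered
    sp = sum(h.score for h in top if h.label)
    sn = sum(h.score for h in top if not h.label)
    total = sp + sn
    value = (sp - sn) / total if total > 0 else 0.0
    return KnnScore(value=value, sp=sp, sn=sn, k_used=len(top))


class KnnMethod:
    """Trainable-method facade used by the cross-validation harness.

    "Training" just stores the labelled sequences; all work happens at
    decision time.
    """

    name = "knn"

    def __init__(self, k: int = 5, use_bits: bool = True,
                 matrix: str = "BLOSUM62", gap_open: float = 11.0,
                 gap_extend: float = 1.0):
        self.k = k
        self.use_bits = use_bits
        self._aligner_params = (matrix, gap_open, gap_extend)
        self._train: list[tuple[str, str, bool]] | None = None

    def fit(self, ids: list[str], sequences: list[str], labels) -> "KnnMethod":
        labels = np.asarray(labels, dtype=bool)
        self._train = [
            (pid, validate_sequence(seq), bool(lab))
            for pid, seq, lab in zip(ids, sequences, labels)
        ]
        return self

    def decision_values(self, sequences: list[str]) -> np.ndarray:
        if self._train is None:
            raise RuntimeError("fit() must be called before decision_values()")
        aligner = make_aligner(*self._aligner_params)
        out = np.empty(len(sequences))
        for i, seq in enumerate(sequences):
            hits = compute_similarities(seq, self._train, aligner, self.use_bits)
            out[i] = knn_score(hits, self.k).value
        return out
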