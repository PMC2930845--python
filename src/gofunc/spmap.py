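"""Subsequence-profile feature space (SPMap-style) + margin classifier.

The subsequence-based classifier detects conserved short regions (motifs)
shared by a functional family:

1. every length-``l`` window is extracted from the positive training
   sequences;
2. windows are clustered greedily: a window joins the first cluster whose
   *representative* (founding window) it matches with an ungapped BLOSUM62
   score >= ``threshold``, else it founds a new cluster;
3. each cluster is summarised by a probabilistic profile (an l x 20
   position-specific probability matrix with pseudocounts);
4. a sequence maps to a d-dimensional vector (d = number of clusters):
   dimension j is the best window probability of the sequence under
   profile j, so a sequence containing a motif similar to cluster j gets
   a high j-th coordinate.

The vectors are then fed to an SVM.  Per-window probability is the
geometric mean of per-position probabilities, ``exp(mean log p)``, which
keeps every feature in (0, 1] and comparable across window lengths; the
raw product is available via ``normalize="product"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .margin import MarginClassifier

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
# X (unknown residue) is mapped to index 20; profiles give it the row mean.
_X_INDEX = 20

_BLOSUM = substitution_matrices.load("BLOSUM62")
# 21 x 21 integer matrix over AA_ORDER + X for fast ungapped scoring
_SCORE = np.zeros((21, 21))
for _i, _a in enumerate(AA_ORDER + "X"):
    for _j, _b in enumerate(AA_ORDER + "X"):
        _SCORE[_i, _j] = _BLOSUM[_a][_b]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX.get(c, _X_INDEX) for c in seq], dtype=np.int64)
    except TypeError:  # pragma: no cover
        raise ValidationError(f"cannot encode sequence {seq!r}")


@dataclass
class SubsequenceCluster:
    """A group of similar fixed-length subsequences and its profile."""

    representative: str
    members: list[str]
    profile: np.ndarray | None = None  # (l, 20), rows sum to 1

    @property
    def length(self) -> int:
        return len(self.representative)


@dataclass
class ProfileMap:
    """Ordered clusters; the number of clusters is the feature dimension."""

    clusters: list[SubsequenceCluster]
    subsequence_length: int

    @property
    def dimension(self) -> int:
        return len(self.clusters)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "gofunc-profile-map",
            "version": 1,
            "subsequence_length": self.subsequence_length,
            "alphabet": AA_ORDER,
            "clusters": [
                {
                    "representative": c.representative,
                    "members": c.members,
                    "profile": None if c.profile is None else c.profile.tolist(),
                }
                for c in self.clusters
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileMap":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "gofunc-profile-map":
            raise ValidationError(f"{path}: not a profile-map file")
        clusters = [
            SubsequenceCluster(
                representative=c["representative"],
                members=list(c["members"]),
                profile=None if c["profile"] is None else np.array(c["profile"]),
            )
            for c in payload["clusters"]
        ]
        return cls(clusters=clusters, subsequence_length=payload["subsequence_length"])


def extract_subsequences(sequences: list[str], l: int = 5) -> list[str]:
    """All contiguous length-``l`` windows, in input order."""
    if l < 2:
        raise ValueError(f"subsequence length must be >= 2, got {l}")
    out: list[str] = []
    for seq in sequences:
        seq = seq.upper()
        out.extend(seq[i : i + l] for i in range(len(seq) - l + 1))
    return out


def ungapped_score(a: str, b: str) -> float:
    """Positionwise BLOSUM62 score of two equal-length subsequences."""
    if len(a) != len(b):
        raise ValidationError("subsequences differ in length")
    return float(_SCORE[_encode(a), _encode(b)].sum())


def cluster_subsequences(
    subseqs: list[str],
    threshold: float = 8.0,
    canonicalize: bool = True,
) -> list[SubsequenceCluster]:
    """Greedy single-pass clustering against cluster representatives.

    Deterministic given input order; ``canonicalize`` sorts the input
    first so the result does not depend on sequence order upstream.
    """
    if not subseqs:
        return []
    lengths = {len(s) for s in subseqs}
    if len(lengths) != 1:
        raise ValidationError(f"mixed subsequence lengths {sorted(lengths)}")
    items = sorted(subseqs) if canonicalize else list(subseqs)
    clusters: list[SubsequenceCluster] = []
    reps: list[np.ndarray] = []  # encoded representatives
    rep_matrix = None  # (n_clusters, l) refreshed lazily
    for sub in items:
        enc = _encode(sub)
        if reps:
            if rep_matrix is None or rep_matrix.shape[0] != len(reps):
                rep_matrix = np.stack(reps)
            scores = _SCORE[rep_matrix, enc[None, :]].sum(axis=1)
            hit = np.nonzero(scores >= threshold)[0]
            if hit.size:
                clusters[hit[0]].members.append(sub)
                continue
        clusters.append(SubsequenceCluster(representative=sub, members=[sub]))
        reps.append(enc)
        rep_matrix = None
    return clusters


def build_profiles(
    clusters: list[SubsequenceCluster],
    pseudocount: float = 1.0,
) -> ProfileMap:
    """Position-specific probability profiles with additive pseudocounts.

    profile[i][a] = (count(a at i) + pc) / (n_members + 20 * pc).
    Positions holding an X are spread uniformly over the 20 residues.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    if not clusters:
        raise ValidationError("no clusters to profile")
    l = clusters[0].length
    for c in clusters:
        if not c.members:
            raise ValidationError("empty cluster")
        if c.length != l:
            raise ValidationError("clusters have mixed subsequence lengths")
    for c in clusters:
        counts = np.zeros((l, 20))
        for m in c.members:
            enc = _encode(m)
            for i, idx in enumerate(enc):
                if idx == _X_INDEX:
                    counts[i] += 1.0 / 20.0
                else:
                    counts[i, idx] += 1.0
        c.profile = (counts + pseudocount) / (len(c.members) + 20 * pseudocount)
    return ProfileMap(clusters=clusters, subsequence_length=l)


def map_sequence(
    seq: str,
    pm: ProfileMap,
    normalize: str = "geometric",
) -> np.ndarray:
    """Fixed-dimensional feature vector: best window probability per profile.

    ``normalize="geometric"`` returns exp(mean log p) per window (default);
    ``"product"`` returns the raw per-window probability product.
    """
    seq = seq.upper()
    l = pm.subsequence_length
    if len(seq) < l:
        raise ValidationError(
            f"sequence length {len(seq)} shorter than subsequence length {l}"
        )
    if normalize not in ("geometric", "product"):
        raise ValueError(f"unknown normalization {normalize!r}")
    enc = _encode(seq)
    n_win = len(seq) - l + 1
    windows = np.stack([enc[i : i + l] for i in range(n_win)])  # (w, l)
    # (d, l, 21): append an X column holding the profile row mean (1/20)
    profs = np.stack([c.profile for c in pm.clusters])
    profs = np.concatenate([profs, profs.mean(axis=2, keepdims=True)], axis=2)
    logp = np.log(profs)  # strictly positive thanks to pseudocounts
    # gather: win_log[w, d] = sum_i logp[d, i, windows[w, i]]
    lp_t = logp.transpose(1, 2, 0)  # (l, 21, d)
    per_pos = lp_t[np.arange(l)[None, :], windows]  # (w, l, d)
    win_log = per_pos.sum(axis=1)  # (w, d)
    best = win_log.max(axis=0)  # (d,)
    if normalize == "geometric":
        return np.exp(best / l)
    return np.exp(best)


def map_sequences(sequences: list[str], pm: ProfileMap,
                  normalize: str = "geometric") -> np.ndarray:
    return np.stack([map_sequence(s, pm, normalize) for s in sequences])


def build_feature_space(
    positive_sequences: list[str],
    l: int = 5,
    threshold: float = 8.0,
    pseudocount: float = 1.0,
) -> ProfileMap:
    """Full feature-space construction from the positive training data."""
    subs = extract_subsequences(positive_sequences, l)
    if not subs:
        raise ValidationError("no subsequences extractable from positives")
    clusters = cluster_subsequences(subs, threshold)
    return build_profiles(clusters, pseudocount)


class SpmapMethod:
    """Trainable-method facade: feature space from positives + RBF SVM."""

    name = "spmap"

    def __init__(self, l: int = 5, threshold: float = 8.0,
                 pseudocount: float = 1.0, normalize: str = "geometric",
                 random_state: int = 0):
        self.l = l
        self.threshold = threshold
        self.pseudocount = pseudocount
        self.normalize = normalize
        self.random_state = random_state
        self.profile_map: ProfileMap | None = None
        self._clf: MarginClassifier | None = None

    def fit(self, ids, sequences, labels) -> "SpmapMethod":
        labels = np.asarray(labels, dtype=bool)
        positives = [s for s, lab in zip(sequences, labels) if lab]
        self.profile_map = build_feature_space(
            positives, self.l, self.threshold, self.pseudocount
        )
        X = map_sequences(list(sequences), self.profile_map, self.normalize)
        self._clf = MarginClassifier(random_state=self.random_state).fit(X, labels)
        return self

    def decision_values(self, sequences) -> np.ndarray:
        if self._clf is None or self.profile_map is None:
            raise RuntimeError("fit() must be called before decision_values()")
        X = map_sequences(list(sequences), self.profile_map, self.normalize)
        return self._clf.decision_values(X)
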