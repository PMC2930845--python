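"""Peptide-statistics classifier: 37 physicochemical features + SVM.

Per sequence, the classical protein statistics report is condensed to a
37-dimensional vector: molecular weight, residue count, average residue
weight, isoelectric point, net charge at pH 7, the two A280 extinction
coefficients, the improbability of expression in inclusion bodies
(Wilkinson–Harrison solubility model), 20 Dayhoff statistics (residue
frequency relative to the Dayhoff 1978 reference composition), and nine
residue-category percentages.

Constant tables follow the EMBOSS dialect: average residue masses, the
EMBOSS pK set for the isoelectric point, Gill–von Hippel extinction
coefficients (Trp 5500, Tyr 1490, cystine 125; free cysteines count 0),
and the EMBOSS residue-category table.  Feature vectors are scaled by the
min/max ranges of the *positive* training data — applied identically to
training and test vectors — so the scale is anchored to the class being
recognised rather than to the much larger negative pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError, ValidationError
from .margin import MarginClassifier

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Average (isotopically averaged) residue masses, daltons
RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155, "F": 147.1766,
    "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741, "L": 113.1594,
    "M": 131.1926, "N": 114.1038, "P": 97.1167, "Q": 128.1307, "R": 156.1875,
    "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.01524
MEAN_RESIDUE_MASS = sum(RESIDUE_MASS.values()) / 20.0  # used for X

# EMBOSS pK set for the charge / isoelectric-point model
PK = {
    "Nterm": 8.6, "Cterm": 3.6,
    "D": 3.9, "E": 4.1, "H": 6.5, "C": 8.5, "Y": 10.1, "K": 10.8, "R": 12.5,
}
_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")

# Gill & von Hippel molar extinction at 280 nm
EXT_TRP, EXT_TYR, EXT_CYSTINE = 5500.0, 1490.0, 125.0

# Dayhoff (1978) reference composition, percent
DAYHOFF_REF = {
    "A": 8.6, "C": 2.9, "D": 5.5, "E": 6.0, "F": 3.6, "G": 8.4, "H": 2.0,
    "I": 4.5, "K": 6.6, "L": 7.4, "M": 1.7, "N": 4.3, "P": 5.2, "Q": 3.9,
    "R": 4.9, "S": 7.0, "T": 6.1, "V": 6.6, "W": 1.3, "Y": 3.4,
}

# EMBOSS residue-category table (restricted to the 20 standard residues)
CATEGORIES = {
    "tiny": set("ACGST"),
    "small": set("ACDGNPSTV"),
    "aliphatic": set("ILV"),
    "aromatic": set("FHWY"),
    "nonpolar": set("ACFGILMPVWY"),
    "polar": set("DEHKNQRST"),
    "charged": set("DEHKR"),
    "basic": set("HKR"),
    "acidic": set("DE"),
}

#: Fixed column order of the 37-feature vector.
FEATURE_NAMES = (
    ["molecular_weight", "n_residues", "avg_residue_weight", "isoelectric_point",
     "charge", "molar_ext_coeff_a280", "ext_coeff_1mgml_a280",
     "inclusion_body_improbability"]
    + [f"dayhoff_{a}" for a in AA20]
    + ["pct_tiny", "pct_small", "pct_aliphatic", "pct_aromatic",
       "pct_nonpolar", "pct_polar", "pct_charged", "pct_basic", "pct_acidic"]
)
N_FEATURES = len(FEATURE_NAMES)  # 37


def net_charge(counts: dict[str, int], n_term: bool, c_term: bool, ph: float) -> float:
    """Henderson–Hasselbalch net charge at a given pH."""
    pos = 0.0
    if n_term:
        pos += 1.0 / (1.0 + 10 ** (ph - PK["Nterm"]))
    for a in _BASIC:
        pos += counts.get(a, 0) / (1.0 + 10 ** (ph - PK[a]))
    neg = 0.0
    if c_term:
        neg += 1.0 / (1.0 + 10 ** (PK["Cterm"] - ph))
    for a in _ACIDIC:
        neg += counts.get(a, 0) / (1.0 + 10 ** (PK[a] - ph))
    return pos - neg


def isoelectric_point(counts: dict[str, int], tol: float = 1e-4) -> float:
    """Bisection on the monotone-decreasing charge-vs-pH curve."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(counts, True, True, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _wilkinson_harrison(counts: dict[str, int], n: int) -> float:
    """Improbability of expression in inclusion bodies (solubility model).

    CV = 15.43 * f(N,G,P,S) - 29.56 * |f_charge - 0.03|, discriminant
    CV - 1.71; probability = 0.4934 + 0.276|disc| - 0.0392 disc^2; a
    negative discriminant predicts soluble expression with that
    probability, a positive one insoluble (so improbability = 1 - p).
    """
    turn = sum(counts.get(a, 0) for a in "NGPS") / n
    charge = (counts.get("R", 0) + counts.get("K", 0)
              - counts.get("D", 0) - counts.get("E", 0)) / n
    cv = 15.43 * turn - 29.56 * abs(charge - 0.03)
    disc = cv - 1.71
    p = 0.4934 + 0.276 * abs(disc) - 0.0392 * disc ** 2
    p = min(max(p, 0.0), 1.0)
    return p if disc < 0 else 1.0 - p


@dataclass(frozen=True)
class PeptideFeatures:
    """The 37 statistics, exposed both by name and as a vector."""

    values: tuple

    def __post_init__(self) -> None:
        if len(self.values) != N_FEATURES:
            raise ValidationError(
                f"expected {N_FEATURES} features, got {len(self.values)}"
            )

    def __getitem__(self, name: str) -> float:
        return self.values[FEATURE_NAMES.index(name)]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def compute_features(seq: str) -> PeptideFeatures:
    """All 37 statistics for one sequence.

    X residues contribute the mean residue mass to the molecular weight
    but are excluded from every composition denominator.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - set(AA20) - {"X"}
    if bad:
        raise ValidationError(f"non-amino-acid characters {sorted(bad)}")
    counts = {a: seq.count(a) for a in AA20}
    n_x = seq.count("X")
    n = sum(counts.values())
    if n == 0:
        raise ValidationError("sequence contains no standard residues")

    mw = sum(counts[a] * RESIDUE_MASS[a] for a in AA20) + n_x * MEAN_RESIDUE_MASS + WATER_MASS
    n_total = n + n_x
    avg_w = (mw - WATER_MASS) / n_total
    pi = isoelectric_point(counts)
    charge = net_charge(counts, True, True, ph=7.0)
    molar_ext = (counts["W"] * EXT_TRP + counts["Y"] * EXT_TYR
                 + (counts["C"] // 2) * EXT_CYSTINE)
    ext_1mg = molar_ext / mw
    improb = _wilkinson_harrison(counts, n)
    dayhoff = [100.0 * (counts[a] / n) / DAYHOFF_REF[a] for a in AA20]
    pcts = [
        100.0 * sum(counts[a] for a in CATEGORIES[cat]) / n
        for cat in ("tiny", "small", "aliphatic", "aromatic",
                    "nonpolar", "polar", "charged", "basic", "acidic")
    ]
    values = tuple(
        [mw, float(n_total), avg_w, pi, charge, float(molar_ext), ext_1mg, improb]
        + dayhoff + pcts
    )
    return PeptideFeatures(values=values)


def feature_matrix(sequences: list[str]) -> np.ndarray:
    return np.stack([compute_features(s).as_array() for s in sequences])


@dataclass
class FeatureScaler:
    """Min/max ranges learned from positive training vectors only."""

    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, vectors) -> np.ndarray:
        X = np.atleast_2d(np.asarray(vectors, dtype=float))
        span = self.maxs - self.mins
        out = np.empty_like(X)
        const = span == 0
        out[:, const] = 0.5
        out[:, ~const] = (X[:, ~const] - self.mins[~const]) / span[~const]
        return out


def fit_scaler(positive_vectors) -> FeatureScaler:
    X = np.asarray(positive_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise FitError("need at least 2 positive vectors to fit ranges")
    return FeatureScaler(mins=X.min(axis=0), maxs=X.max(axis=0))


def apply_scaler(scaler: FeatureScaler, vector) -> np.ndarray:
    return scaler.transform(vector)


class PepstatsMethod:
    """Trainable-method facade: 37 features, positive-range scaling, SVM."""

    name = "pepstats"

    def __init__(self, random_state: int = 0):
        self.random_state = random_state
        self.scaler: FeatureScaler | None = None
        self._clf: MarginClassifier | None = None

    def fit(self, ids, sequences, labels) -> "PepstatsMethod":
        labels = np.asarray(labels, dtype=bool)
        X = feature_matrix(list(sequences))
        self.scaler = fit_scaler(X[labels])
        self._clf = MarginClassifier(random_state=self.random_state).fit(
            self.scaler.transform(X), labels
        )
        return self

    def decision_values(self, sequences) -> np.ndarray:
        if self._clf is None or self.scaler is None:
            raise RuntimeError("fit() must be called before decision_values()")
        X = self.scaler.transform(feature_matrix(list(sequences)))
        return self._clf.decision_values(X)
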