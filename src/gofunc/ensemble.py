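"""Combination of the three calibrated classifiers for one GO term.

Four combiners:

* **vote** — majority of the three post-relaxation labels; the output
  values are ignored and no tie is possible with three voters.
* **mean** — arithmetic mean of the three calibrated probabilities;
  positive iff the mean exceeds 0.5 (strictly).
* **weighted mean** — probabilities weighted by each method's
  discriminative power on the helper set: w_i = ROC_i^e / sum_j ROC_j^e,
  with a large exponent (default e = 10) so the better method dominates.
* **addition** — raw outputs are summed on their native scales and the
  summed score is calibrated against a helper set of summed scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    CalibratedPrediction,
    HelperSet,
    combine_confidences,
    confidence_negative,
    confidence_positive,
)

METHOD_IDS = ("knn", "spmap", "pepstats")


@dataclass(frozen=True)
class EnsembleWeights:
    """Per-method weights, summing to 1."""

    w: dict[str, float]

    def __post_init__(self) -> None:
        if abs(sum(self.w.values()) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(self.w.values())}")

    def as_tuple(self, order=METHOD_IDS) -> tuple[float, ...]:
        return tuple(self.w[m] for m in order)


def vote(labels) -> bool:
    """Majority vote over exactly three labels."""
    labels = list(labels)
    if len(labels) != 3:
        raise ValueError(f"expected exactly 3 labels, got {len(labels)}")
    return sum(bool(b) for b in labels) >= 2


def mean_combine(ps, sample_id: str = "", threshold: float = 0.5) -> CalibratedPrediction:
    ps = [float(p) for p in ps]
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ValueError(f"probabilities must lie in [0, 1], got {ps}")
    p = float(np.mean(ps))
    return CalibratedPrediction(
        sample_id=sample_id, raw=p, cp=float("nan"), cn=float("nan"),
        p=p, label=p > threshold,
    )


def weights_from_roc(rocs: dict[str, float], exponent: float = 10.0) -> EnsembleWeights:
    """w_i proportional to ROC_i^e; all-zero ROC scores fall back to uniform."""
    if exponent <= 0:
        raise ValueError(f"exponent must be > 0, got {exponent}")
    if any(r < 0 or r > 1 for r in rocs.values()):
        raise ValueError(f"ROC scores must lie in [0, 1], got {rocs}")
    powered = {m: r ** exponent for m, r in rocs.items()}
    total = sum(powered.values())
    if total == 0:
        return EnsembleWeights(w={m: 1.0 / len(rocs) for m in rocs})
    return EnsembleWeights(w={m: v / total for m, v in powered.items()})


def weighted_mean_combine(
    ps: dict[str, float],
    weights: EnsembleWeights,
    sample_id: str = "",
    threshold: float = 0.5,
) -> CalibratedPrediction:
    if set(ps) != set(weights.w):
        raise ValueError("probability and weight method ids differ")
    if any(not 0.0 <= p <= 1.0 for p in ps.values()):
        raise ValueError(f"probabilities must lie in [0, 1], got {ps}")
    p = float(sum(weights.w[m] * ps[m] for m in ps))
    return CalibratedPrediction(
        sample_id=sample_id, raw=p, cp=float("nan"), cn=float("nan"),
        p=p, label=p > threshold,
    )


def addition_combine(
    raws,
    helper: HelperSet,
    sample_id: str = "",
    threshold: float = 0.5,
) -> CalibratedPrediction:
    """Sum the raw outputs, then calibrate the sum against summed-score
    helper distributions."""
    s = float(np.sum([float(r) for r in raws]))
    cp = confidence_positive(s, helper)
    cn = confidence_negative(s, helper)
    p = combine_confidences(cp, cn)
    return CalibratedPrediction(
        sample_id=sample_id, raw=s, cp=cp, cn=cn, p=p, label=p > threshold,
    )
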