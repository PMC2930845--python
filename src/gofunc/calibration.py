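"""Threshold relaxation: empirical-CDF calibration of raw classifier output.

A margin classifier trained on a one-vs-rest split is biased toward the
(much larger) negative class, so its natural threshold 0 gives poor
sensitivity.  Instead of moving the threshold directly, each raw output x
is converted to a probability using a labelled *helper set*:

* Cp(x) — fraction of positive helper samples whose raw output is
  strictly below x;
* Cn(x) — fraction of negative helper samples whose raw output is
  strictly above x;
* P(x)  = Cp / (Cp + Cn), with P = 0.5 when both confidences vanish.

P rises toward 1 as x overtakes the positive helper distribution or
escapes above the negative one, which implicitly relaxes the decision
threshold in favour of the minority class.  In evaluation the helper set
is the test fold minus the one held-out sample (leave-one-out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError


@dataclass
class HelperSet:
    """Raw outputs of labelled helper samples, split by class."""

    positive_outputs: list[float]
    negative_outputs: list[float]


@dataclass(frozen=True)
class CalibratedPrediction:
    """A raw output with its confidences and calibrated probability."""

    sample_id: str
    raw: float
    cp: float
    cn: float
    p: float
    label: bool  # True = predicted positive


def confidence_positive(x: float, helper: HelperSet) -> float:
    """Fraction of positive helper outputs strictly below x (ties count 0)."""
    pos = helper.positive_outputs
    if not pos:
        raise CalibrationError("empty positive helper set")
    return sum(1 for s in pos if s < x) / len(pos)


def confidence_negative(x: float, helper: HelperSet) -> float:
    """Fraction of negative helper outputs strictly above x (mirror count)."""
    neg = helper.negative_outputs
    if not neg:
        raise CalibrationError("empty negative helper set")
    return sum(1 for s in neg if s > x) / len(neg)


def combine_confidences(cp: float, cn: float) -> float:
    """P = Cp / (Cp + Cn); the doubly-degenerate case is maximal uncertainty."""
    if not (0.0 <= cp <= 1.0 and 0.0 <= cn <= 1.0):
        raise ValueError(f"confidences must lie in [0, 1], got cp={cp}, cn={cn}")
    total = cp + cn
    return cp / total if total > 0 else 0.5


def calibrate(
    x: float,
    helper: HelperSet,
    sample_id: str = "",
    threshold: float = 0.5,
) -> CalibratedPrediction:
    cp = confidence_positive(x, helper)
    cn = confidence_negative(x, helper)
    p = combine_confidences(cp, cn)
    return CalibratedPrediction(
        sample_id=sample_id, raw=x, cp=cp, cn=cn, p=p, label=p > threshold
    )


def calibrate_loo(
    outputs: list[tuple[str, float, bool]],
    threshold: float = 0.5,
) -> list[CalibratedPrediction]:
    """Leave-one-out calibration over (sample_id, raw, truth) triples.

    Each sample is calibrated against a helper set of all *other* samples,
    so its own output never informs its probability.
    """
    truths = [t for _, _, t in outputs]
    if sum(truths) < 2 or len(truths) - sum(truths) < 2:
        raise CalibrationError(
            "need at least 2 samples of each class for leave-one-out calibration"
        )
    preds: list[CalibratedPrediction] = []
    for i, (sid, raw, _truth) in enumerate(outputs):
        helper = HelperSet(
            positive_outputs=[r for j, (_, r, t) in enumerate(outputs) if t and j != i],
            negative_outputs=[r for j, (_, r, t) in enumerate(outputs) if not t and j != i],
        )
        preds.append(calibrate(raw, helper, sample_id=sid, threshold=threshold))
    return preds


def natural_threshold_labels(raws: list[float], threshold: float = 0.0) -> np.ndarray:
    """Labels at the classifier's natural threshold (no relaxation)."""
    return np.asarray(raws) > threshold
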