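"""Ordinal response classes and LDA segmentation of the PC space.

Survival relative to control is binned treatment-specifically into three
ordinal classes — highly responsive (survival <= 30%), low responsive
(30-80%] and resistant (> 80%) — and classes left with a single member are
pooled with a neighbour so linear discriminant analysis (LDA) has at least
two members per class.  The LDA model (class means, pooled ridge-regularized
within-class covariance, uniform priors) carves the retained PC space into
convex response regions; classifying a placed point reads off its region.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np


class ClassificationError(ValueError):
    pass


class ResponseClass(IntEnum):
    """Ordinal responsiveness; lower value = more responsive."""

    HIGH = 0
    LOW = 1
    RESISTANT = 2


#: Survival-fraction bin edges: <=0.30 HIGH, (0.30, 0.80] LOW, >0.80 RESISTANT.
DEFAULT_THRESHOLDS: tuple[float, float] = (0.30, 0.80)


def assign_response_class(
    survival: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> ResponseClass:
    """Bin a survival fraction into its ordinal response class.

    Boundaries are upper-inclusive: exactly 30% survival is still HIGH,
    exactly 80% still LOW.
    """
    t_high, t_resistant = thresholds
    if not 0 < t_high < t_resistant < 1:
        raise ValueError("thresholds must satisfy 0 < t_high < t_resistant < 1")
    if survival < 0:
        raise ClassificationError(f"negative survival fraction: {survival}")
    if survival <= t_high:
        return ResponseClass.HIGH
    if survival <= t_resistant:
        return ResponseClass.LOW
    return ResponseClass.RESISTANT


def pool_singleton_classes(labels: Sequence[int]) -> list[int]:
    """Merge classes with a single member into a neighbouring class.

    A singleton merges into the adjacent occupied class toward lower
    responsiveness (HIGH into LOW, LOW into RESISTANT); a singleton in the
    least-responsive occupied class merges upward instead.  Repeats until no
    singleton remains or only one class is left.  Works on any ordinal integer
    labels (response or synergy classes).
    """
    labels = list(int(l) for l in labels)
    if len(labels) < 2:
        raise ClassificationError("need at least 2 labelled lines")
    if all(c == 1 for c in Counter(labels).values()):
        raise ClassificationError(
            "every class is a singleton; use coarser response bins"
        )
    while True:
        counts = Counter(labels)
        present = sorted(counts)
        if len(present) == 1:
            break
        singletons = [c for c in present if counts[c] == 1]
        if not singletons:
            break
        c = singletons[0]  # most responsive singleton first
        below = [d for d in present if d > c]
        above = [d for d in present if d < c]
        target = min(below) if below else max(above)
        labels = [target if l == c else l for l in labels]
    return labels


@dataclass
class ClassRegionModel:
    """Linear discriminant segmentation of the k-dim PC space.

    Equal-covariance Gaussian classes: discriminant score
    ``mu_c' S^-1 x - mu_c' S^-1 mu_c / 2 + log prior_c`` with S the pooled
    within-class covariance plus a ridge term.  Ties break toward the less
    responsive (higher ordinal) class, the conservative choice for a
    treatment decision.
    """

    classes: np.ndarray  # sorted ordinal labels
    means: np.ndarray  # n_classes x k
    covariance: np.ndarray  # pooled, ridge-regularized, k x k
    priors: np.ndarray

    def discriminant_scores(self, coord: np.ndarray) -> np.ndarray:
        coord = np.asarray(coord, dtype=float)
        if coord.shape[-1] != self.means.shape[1]:
            raise ClassificationError(
                f"coordinate dimension {coord.shape[-1]} != model k "
                f"{self.means.shape[1]}"
            )
        inv_mu = np.linalg.solve(self.covariance, self.means.T)  # k x C
        lin = coord @ inv_mu
        const = -0.5 * np.einsum("ck,kc->c", self.means, inv_mu) + np.log(self.priors)
        return lin + const


def fit_class_regions(
    coords: np.ndarray,
    labels: Sequence[int],
    ridge: float | None = None,
    priors: str = "uniform",
) -> ClassRegionModel:
    """Fit the LDA segmentation on training coordinates.

    ``ridge`` defaults to 1e-6 * trace(pooled covariance)/k, enough to keep
    small-sample fits (11 lines in 4 dimensions) numerically stable without
    visibly moving the hyperplanes.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray([int(l) for l in labels])
    if coords.ndim != 2 or len(coords) != len(labels):
        raise ClassificationError("coords must be (n, k) matching labels")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ClassificationError("need at least 2 classes to fit regions")
    counts = np.array([(labels == c).sum() for c in classes])
    if (counts < 2).any():
        bad = classes[counts < 2][0]
        raise ClassificationError(
            f"class {bad} has fewer than 2 members; pool singletons first"
        )

    n, k = coords.shape
    means = np.vstack([coords[labels == c].mean(axis=0) for c in classes])
    pooled = np.zeros((k, k))
    for c, mu in zip(classes, means):
        d = coords[labels == c] - mu
        pooled += d.T @ d
    pooled /= n - len(classes)

    lam = ridge if ridge is not None else 1e-6 * np.trace(pooled) / k
    cov = pooled + lam * np.eye(k)
    # reject degenerate fits (all points identical -> zero covariance)
    if np.trace(pooled) <= 0 or np.linalg.matrix_rank(cov) < k:
        raise ClassificationError(
            "singular within-class covariance; increase ridge or check inputs"
        )

    if priors == "uniform":
        pr = np.full(len(classes), 1.0 / len(classes))
    elif priors == "empirical":
        pr = counts / n
    else:
        raise ValueError(f"unknown priors mode {priors!r}")
    return ClassRegionModel(classes=classes, means=means, covariance=cov, priors=pr)


def classify(model: ClassRegionModel, coord: np.ndarray) -> int:
    """Ordinal class of a placed point: maximal discriminant score.

    Equal scores resolve to the less responsive class.
    """
    scores = model.discriminant_scores(np.asarray(coord, dtype=float))
    best = scores.max()
    tied = model.classes[scores >= best - 0.0]
    return int(tied.max())


def resubstitution_accuracy(
    model: ClassRegionModel, coords: np.ndarray, labels: Sequence[int]
) -> float:
    """Fraction of training points classified into their own class."""
    labels = [int(l) for l in labels]
    pred = [classify(model, c) for c in np.asarray(coords, dtype=float)]
    return float(np.mean([p == l for p, l in zip(pred, labels)]))
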