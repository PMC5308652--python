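"""Webb fractional-product combination index and synergy-class prediction.

Under Bliss/Webb independence, two non-interacting drugs leave a fraction
``s_a * s_b`` of cells alive.  The combination index (CI) is the observed
combination survival divided by that expectation: CI < 1 means the
combination kills more than independence predicts (synergy), CI of 1
additivity, CI > 1 antagonism.  CI values are binned into ordinal synergy
classes, which run through exactly the same PC-space/LDA/LOOCV machinery as
the survival-based response classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import pandas as pd

from .functional_groups import FGMatrix
from .io_model import ResponseTable, ValidationError
from .loocv_prediction import LoocvResult, loocv_predict


class SynergyClass(IntEnum):
    """Ordinal synergy; lower value = more synergistic (lower CI)."""

    SYNERGY_HIGH = 0
    SYNERGY_MODERATE = 1
    NON_SYNERGISTIC = 2


#: Default CI bin edges for synthetic work: CI <= 0.5 strongly synergistic,
#: (0.5, 0.9] moderately synergistic, > 0.9 non-synergistic.
DEFAULT_CI_BINS: tuple[float, float] = (0.5, 0.9)


def webb_ci(s_a: float, s_b: float, s_ab: float, clip: bool = True) -> float:
    """Combination index: observed over expected (fractional-product) survival.

    Monotherapy survivals of zero leave the expectation at zero and the CI
    undefined — a monotherapy that already kills everything cannot be
    improved upon multiplicatively.  ``clip`` truncates survivals above 1
    (assay noise above the untreated control) before the computation.
    """
    if s_a < 0 or s_b < 0 or s_ab < 0:
        raise ValidationError("survival fractions must be nonnegative")
    if clip:
        warn = max(s_a, s_b, s_ab) > 1.0
        s_a, s_b, s_ab = min(s_a, 1.0), min(s_b, 1.0), min(s_ab, 1.0)
        if warn:
            warnings.warn(
                "survival above control clipped to 1.0 for CI computation",
                stacklevel=2,
            )
    if s_a == 0 or s_b == 0:
        raise ValidationError(
            "CI undefined: a monotherapy survival is zero (already fully effective)"
        )
    return s_ab / (s_a * s_b)


def assign_synergy_class(
    ci: float, bins: tuple[float, float] = DEFAULT_CI_BINS
) -> SynergyClass:
    """Bin a CI value into its ordinal synergy class (upper-edge inclusive)."""
    lo, hi = bins
    if not 0 < lo < hi:
        raise ValueError("bins must be strictly increasing positive edges")
    if ci <= 0:
        raise ValidationError(f"CI must be positive, got {ci}")
    if ci <= lo:
        return SynergyClass.SYNERGY_HIGH
    if ci <= hi:
        return SynergyClass.SYNERGY_MODERATE
    return SynergyClass.NON_SYNERGISTIC


@dataclass
class CombinationIndex:
    cell_line: str
    s_tmz: float
    s_trail: float
    s_combo: float
    ci: float
    synergy_class: SynergyClass


def combination_index_table(
    responses: ResponseTable,
    bins: tuple[float, float] = DEFAULT_CI_BINS,
    arms: tuple[str, str, str] = ("TMZ", "TRAIL", "TMZ+TRAIL"),
) -> pd.DataFrame:
    """Per-line CI and synergy class from mono- and combination-arm survival."""
    a, b, ab = arms
    s_a, s_b, s_ab = responses.arm(a), responses.arm(b), responses.arm(ab)
    rows = []
    for line in s_ab.index:
        ci = webb_ci(float(s_a[line]), float(s_b[line]), float(s_ab[line]))
        # zero observed combination survival: CI = 0, maximal synergy
        cls = (
            SynergyClass.SYNERGY_HIGH if ci == 0 else assign_synergy_class(ci, bins)
        )
        rows.append(
            {
                "cell_line": line,
                f"survival_{a}": float(s_a[line]),
                f"survival_{b}": float(s_b[line]),
                "survival_combo": float(s_ab[line]),
                "ci": ci,
                "synergy_class": int(cls),
            }
        )
    return pd.DataFrame(rows)


def synergy_loocv(
    fg: FGMatrix,
    synergy_labels: Sequence[int],
    fixed_k: int | None = None,
    ridge: float | None = None,
    priors: str = "uniform",
) -> LoocvResult:
    """Leave-one-out synergy-class prediction; mechanics as for response classes."""
    return loocv_predict(
        fg, synergy_labels, fixed_k=fixed_k, ridge=ridge, priors=priors
    )
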