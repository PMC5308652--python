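"""In-silico BH3-mimetic sensitization prediction.

ABT-737 neutralizes Bcl-2 and Bcl-xL (but not Mcl-1).  Its effect is modeled
by setting the target protein amounts to zero, recomputing the functional
groups, and reprojecting the perturbed line into the PC space and LDA
segmentation fitted on unperturbed data — exactly as a held-out test point.
A line is predicted SENSITIZED when its post-depletion position falls in a
strictly more responsive LDA region.

Because projection is linear in the z-scored FG values, a perturbation that
changes a single FG moves the point along that FG's loading row; the
explicit "movement vector" formulation (minus the standardized FG change
times the loading row) is algebraically identical to direct reprojection and
is exposed both as an API and as the module's central consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .functional_groups import FGDefinition, compute_fg_row
from .io_model import canonical_protein
from .pc_space import PCModel, project
from .response_classification import ClassRegionModel, classify

#: Proteins neutralized by ABT-737.
ABT737_TARGETS: tuple[str, ...] = ("Bcl-2", "Bcl-xL")


def deplete_targets(
    protein_values: pd.Series,
    targets: Sequence[str] = ABT737_TARGETS,
    fraction: float = 1.0,
) -> pd.Series:
    """Return the per-protein row with the targets depleted.

    ``fraction`` scales the depletion (1.0 = set to zero, the default
    total-neutralization model); other proteins are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("depletion fraction must be in [0, 1]")
    targets = [canonical_protein(t) for t in targets]
    missing = [t for t in targets if t not in protein_values.index]
    if missing:
        raise KeyError(f"target protein not in panel row: {missing[0]!r}")
    row = protein_values.copy()
    row[targets] = row[targets] * (1.0 - fraction)
    return row


def reposition(
    model: PCModel,
    original_fg_row: pd.Series,
    perturbed_fg_row: pd.Series,
) -> tuple[np.ndarray, np.ndarray]:
    """(displacement, new coordinates) of a perturbed line.

    Both rows project through the model's frozen standardization; nothing is
    refit.
    """
    old = project(model, original_fg_row)
    new = project(model, perturbed_fg_row)
    return new - old, new


def movement_vector(model: PCModel, fg_name: str, delta_z: float) -> np.ndarray:
    """Displacement for reducing one FG by ``delta_z`` standardized units.

    The vector is minus ``delta_z`` times the FG's loading row over the
    retained PCs: lines carrying more of the depleted proteins (larger
    standardized change) move further.
    """
    if fg_name not in model.loadings.index:
        raise KeyError(f"unknown FG {fg_name!r}")
    if delta_z < 0:
        raise ValueError("delta_z must be nonnegative")
    row = model.loadings.loc[fg_name].to_numpy()[: model.k]
    return -delta_z * row


@dataclass
class SensitizationPrediction:
    cell_line: str
    arm: str
    pre_class: int
    post_class: int
    displacement: np.ndarray
    pre_coord: np.ndarray
    post_coord: np.ndarray
    mahalanobis_improvement: float

    @property
    def verdict(self) -> str:
        return "SENSITIZED" if self.post_class < self.pre_class else "NOT_SENSITIZED"


def predict_sensitization(
    pc_model: PCModel,
    region_model: ClassRegionModel,
    cell_line: str,
    protein_values: pd.Series,
    targets: Sequence[str] = ABT737_TARGETS,
    arm: str = "TRAIL",
    definitions: Sequence[FGDefinition] | None = None,
    fraction: float = 1.0,
) -> SensitizationPrediction:
    """Predict whether depleting ``targets`` sensitizes one line to ``arm``.

    ``protein_values`` is the line's aggregated per-protein row.  Both models
    must have been fitted on unperturbed data for the same treatment arm.
    Alongside the class verdict, the reduction in Mahalanobis distance to the
    most responsive class mean is reported as a continuous readout for
    borderline repositionings.
    """
    fg_pre = compute_fg_row(protein_values, definitions)
    fg_post = compute_fg_row(
        deplete_targets(protein_values, targets, fraction), definitions
    )
    displacement, post_coord = reposition(pc_model, fg_pre, fg_post)
    pre_coord = post_coord - displacement
    pre_class = classify(region_model, pre_coord)
    post_class = classify(region_model, post_coord)

    best_mean = region_model.means[int(np.argmin(region_model.classes))]
    cov_inv = np.linalg.inv(region_model.covariance)

    def _maha(x: np.ndarray) -> float:
        d = x - best_mean
        return float(np.sqrt(d @ cov_inv @ d))

    return SensitizationPrediction(
        cell_line=cell_line,
        arm=arm,
        pre_class=pre_class,
        post_class=post_class,
        displacement=displacement,
        pre_coord=pre_coord,
        post_coord=post_coord,
        mahalanobis_improvement=_maha(pre_coord) - _maha(post_coord),
    )


def sensitization_table(
    predictions: Sequence[SensitizationPrediction],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_line": p.cell_line,
                "arm": p.arm,
                "pre_class": p.pre_class,
                "post_class": p.post_class,
                "verdict": p.verdict,
                "displacement_norm": float(np.linalg.norm(p.displacement)),
                "mahalanobis_improvement": p.mahalanobis_improvement,
            }
            for p in predictions
        ]
    )
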