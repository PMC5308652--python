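"""Leave-one-out prediction of per-line responsiveness, and the treatment
recommendation built on paired TMZ/TRAIL predictions.

Each fold drops one cell line, refits standardization, PCA and the LDA
segmentation on the remaining lines only (no leakage: nothing about the
held-out line touches the fold's models), projects the held-out line's FG
values through the fold's frozen model, and reads off the response region it
lands in.  A prediction is correct when the placed line sits in its own
response region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .functional_groups import FGMatrix
from .pc_space import fit_pc_model, project, project_matrix
from .response_classification import (
    ClassificationError,
    classify,
    fit_class_regions,
    pool_singleton_classes,
)


@dataclass
class FoldRecord:
    cell_line: str
    observed: int
    observed_pooled: int | None
    predicted: int | None
    k: int | None
    correct: bool
    degenerate: bool = False


@dataclass
class LoocvResult:
    records: list[FoldRecord]
    skip_degenerate: bool = False

    @property
    def accuracy(self) -> float:
        recs = self.records
        if self.skip_degenerate:
            recs = [r for r in recs if not r.degenerate]
        if not recs:
            return float("nan")
        return float(np.mean([r.correct for r in recs]))

    @property
    def n_correct(self) -> int:
        return sum(r.correct for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_line": r.cell_line,
                    "observed": r.observed,
                    "observed_pooled": r.observed_pooled,
                    "predicted": r.predicted,
                    "k": r.k,
                    "correct": r.correct,
                    "degenerate": r.degenerate,
                }
                for r in self.records
            ]
        )

    def to_frame_dict(self) -> dict:
        return {"accuracy": self.accuracy, "folds": self.to_frame()}


def loocv_predict(
    fg: FGMatrix,
    labels: Sequence[int],
    fixed_k: int | None = None,
    ridge: float | None = None,
    priors: str = "uniform",
    skip_degenerate: bool = False,
) -> LoocvResult:
    """Leave-one-out prediction over all cell lines.

    ``labels`` are ordinal class labels aligned with ``fg.cell_lines``
    (response classes from survival bins, or synergy classes from CI bins).
    ``fixed_k`` pins the retained PC dimension in every fold; by default the
    Kaiser rule is re-applied per fold.  Folds whose training labels collapse
    to a single class after pooling are marked degenerate and count as
    incorrect unless ``skip_degenerate``.
    """
    lines = fg.cell_lines
    labels = [int(l) for l in labels]
    if len(labels) != len(lines):
        raise ValueError("labels must align with fg.cell_lines")
    if len(lines) < 4:
        raise ValueError("leave-one-out needs at least 4 cell lines")

    records: list[FoldRecord] = []
    for i, line in enumerate(lines):
        train_fg = fg.drop(line)
        train_labels = labels[:i] + labels[i + 1 :]
        observed = labels[i]
        try:
            pooled = pool_singleton_classes(train_labels)
            label_map = {o: p for o, p in zip(train_labels, pooled)}
            if len(set(pooled)) < 2:
                raise ClassificationError("fold collapsed to one class")
            pc = fit_pc_model(train_fg, n_components=fixed_k)
            coords = project_matrix(pc, train_fg).to_numpy()
            lda = fit_class_regions(coords, pooled, ridge=ridge, priors=priors)
            test_coord = project(pc, fg.row(line))
            predicted = classify(lda, test_coord)
        except ClassificationError:
            records.append(
                FoldRecord(line, observed, None, None, None, False, degenerate=True)
            )
            continue
        # the held-out line's own class may have been pooled away in training;
        # compare against its pooled image (nearest pooled class if unseen)
        if observed in label_map:
            observed_pooled = label_map[observed]
        else:
            observed_pooled = min(
                set(pooled), key=lambda c: (abs(c - observed), c)
            )
        records.append(
            FoldRecord(
                line,
                observed,
                observed_pooled,
                predicted,
                pc.k,
                predicted == observed_pooled,
            )
        )
    return LoocvResult(records, skip_degenerate=skip_degenerate)


@dataclass
class Recommendation:
    cell_line: str
    pred_tmz: int | None
    pred_trail: int | None
    recommended: str  # "TMZ" | "TRAIL" | "either" | "unavailable"


def recommend_treatment(
    cell_line: str, pred_tmz: int | None, pred_trail: int | None
) -> Recommendation:
    """Recommend the arm with the more responsive predicted class.

    Equal predicted classes yield "either"; a missing prediction makes the
    recommendation unavailable.
    """
    if pred_tmz is None or pred_trail is None:
        return Recommendation(cell_line, pred_tmz, pred_trail, "unavailable")
    if pred_tmz < pred_trail:
        rec = "TMZ"
    elif pred_trail < pred_tmz:
        rec = "TRAIL"
    else:
        rec = "either"
    return Recommendation(cell_line, pred_tmz, pred_trail, rec)


def evaluate_recommendations(
    recommendations: Sequence[Recommendation],
    survival_tmz: pd.Series,
    survival_trail: pd.Series,
    similar_tol: float = 0.10,
) -> pd.DataFrame:
    """Score recommendations against observed survival in both arms.

    A recommendation fails only when it names the arm whose observed survival
    is higher (less cell death) than the alternative by more than
    ``similar_tol``; arms within ``similar_tol`` of each other make any
    recommendation acceptable, as does "either".
    """
    rows = []
    for rec in recommendations:
        s_tmz = float(survival_tmz[rec.cell_line])
        s_trail = float(survival_trail[rec.cell_line])
        similar = abs(s_tmz - s_trail) <= similar_tol
        if rec.recommended == "unavailable":
            correct = False
        elif similar:
            correct = True
        elif rec.recommended == "either":
            # arms clearly differ but no arm was singled out: a miss
            correct = False
        else:
            chosen = s_tmz if rec.recommended == "TMZ" else s_trail
            other = s_trail if rec.recommended == "TMZ" else s_tmz
            correct = chosen <= other
        rows.append(
            {
                "cell_line": rec.cell_line,
                "recommended": rec.recommended,
                "survival_tmz": s_tmz,
                "survival_trail": s_trail,
                "correct": bool(correct),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["accuracy"] = float(df["correct"].mean()) if len(df) else float("nan")
    df.attrs["similar_tol"] = similar_tol
    return df
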