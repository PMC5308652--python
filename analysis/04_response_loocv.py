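#!/usr/bin/env python
"""Classify TMZ and TRAIL responsiveness, run leave-one-out cross-validation
per arm, and evaluate per-line treatment recommendations."""

from pathlib import Path

import apoptopredict as ap
from apoptopredict.functional_groups import FGMatrix

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fg = FGMatrix.from_csv(RESULTS / "fg_matrix.csv")
    responses = ap.read_viability(RESULTS / "viability.csv", percent=False)

    preds = {}
    for arm in ("TMZ", "TRAIL"):
        survival = responses.arm(arm).reindex(fg.cell_lines)
        labels = ap.pool_singleton_classes(
            [int(ap.assign_response_class(s)) for s in survival]
        )
        res = ap.loocv_predict(fg, labels)
        res.to_frame().to_csv(RESULTS / f"loocv_{arm.lower()}.csv", index=False)
        preds[arm] = {r.cell_line: r.predicted for r in res.records}
        print(f"{arm}: LOOCV accuracy = {res.accuracy:.3f}")

    recs = [
        ap.recommend_treatment(l, preds["TMZ"][l], preds["TRAIL"][l])
        for l in fg.cell_lines
    ]
    table = ap.evaluate_recommendations(
        recs,
        responses.arm("TMZ").reindex(fg.cell_lines),
        responses.arm("TRAIL").reindex(fg.cell_lines),
    )
    table.to_csv(RESULTS / "recommendations.csv", index=False)
    print(f"recommendation accuracy = {table.attrs['accuracy']:.3f}")


if __name__ == "__main__":
    main()
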