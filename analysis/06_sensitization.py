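#!/usr/bin/env python
"""Predict which lines an in-silico Bcl-2/Bcl-xL depletion (the ABT-737
mechanism) moves into a more TRAIL-responsive class region."""

from pathlib import Path

import apoptopredict as ap
from apoptopredict.functional_groups import FGMatrix
from apoptopredict.io_model import aggregate_replicates
from apoptopredict.pc_space import PCModel, project_matrix
from apoptopredict.sensitization import sensitization_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panel = ap.read_protein_panel(RESULTS / "panel.csv")
    fg = FGMatrix.from_csv(RESULTS / "fg_matrix.csv")
    pc = PCModel.load(RESULTS / "pc_model.json")
    responses = ap.read_viability(RESULTS / "viability.csv", percent=False)

    survival = responses.arm("TRAIL").reindex(fg.cell_lines)
    labels = ap.pool_singleton_classes(
        [int(ap.assign_response_class(s)) for s in survival]
    )
    lda = ap.fit_class_regions(project_matrix(pc, fg).to_numpy(), labels)

    wide = aggregate_replicates(panel).data.pivot(
        index="cell_line", columns="protein", values="value"
    )
    preds = [
        ap.predict_sensitization(pc, lda, line, wide.loc[line])
        for line in fg.cell_lines
    ]
    table = sensitization_table(preds)
    table.to_csv(RESULTS / "sensitization.csv", index=False)
    print(table.round(3).to_string(index=False))
    n = int((table["verdict"] == "SENSITIZED").sum())
    print(f"{n}/{len(table)} lines predicted sensitized by Bcl-2/Bcl-xL depletion")


if __name__ == "__main__":
    main()
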