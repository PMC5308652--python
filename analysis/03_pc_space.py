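#!/usr/bin/env python
"""Fit the correlation-scale PC space on the FG matrix, report the scree and
Kaiser retention, and persist the frozen model and line coordinates."""

from pathlib import Path

import pandas as pd

import apoptopredict as ap
from apoptopredict.functional_groups import FGMatrix
from apoptopredict.pc_space import project_matrix

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fg = FGMatrix.from_csv(RESULTS / "fg_matrix.csv")
    model = ap.fit_pc_model(fg)
    model.save(RESULTS / "pc_model.json")

    scree = pd.DataFrame(
        {
            "pc": [f"PC{i + 1}" for i in range(len(model.eigenvalues))],
            "eigenvalue": model.eigenvalues,
            "cumulative_explained": model.eigenvalues.cumsum()
            / model.eigenvalues.sum(),
        }
    )
    scree.to_csv(RESULTS / "scree.csv", index=False)

    coords = project_matrix(model, fg)
    coords.to_csv(RESULTS / "pc_coordinates.csv")

    print(f"retained k = {model.k} (Kaiser)")
    print(f"explained fraction = {model.explained_fraction:.3f}")
    print(scree.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
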