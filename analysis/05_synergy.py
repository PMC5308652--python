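#!/usr/bin/env python
"""Score TMZ+TRAIL synergy per line with the Webb fractional-product
combination index and cross-validate synergy-class prediction."""

import warnings
from pathlib import Path

import numpy as np

import apoptopredict as ap
from apoptopredict.functional_groups import FGMatrix
from apoptopredict.synergy import combination_index_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fg = FGMatrix.from_csv(RESULTS / "fg_matrix.csv")
    responses = ap.read_viability(RESULTS / "viability.csv", percent=False)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        table = combination_index_table(responses)
    table.to_csv(RESULTS / "combination_index.csv", index=False)
    print(f"median CI = {np.median(table['ci']):.3f} (CI < 1 = synergy)")
    print(table.round(3).to_string(index=False))

    labels = ap.pool_singleton_classes(
        [int(c) for c in table.set_index("cell_line")["synergy_class"]
         .reindex(fg.cell_lines)]
    )
    res = ap.synergy_loocv(fg, labels)
    res.to_frame().to_csv(RESULTS / "loocv_synergy.csv", index=False)
    print(f"synergy LOOCV accuracy = {res.accuracy:.3f}")


if __name__ == "__main__":
    main()
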