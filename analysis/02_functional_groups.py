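#!/usr/bin/env python
"""Collapse the 19-protein panel into the 11 pathway-informed functional
groups and persist the FG matrix and definitions."""

from pathlib import Path

import apoptopredict as ap
from apoptopredict.functional_groups import definitions_to_yaml

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panel = ap.read_protein_panel(RESULTS / "panel.csv")
    fg = ap.compute_fg_matrix(panel)
    fg.to_csv(RESULTS / "fg_matrix.csv")
    definitions_to_yaml(ap.default_fg_definitions(), RESULTS / "fg_definitions.yaml")
    print(fg.values.round(3).to_string())


if __name__ == "__main__":
    main()
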