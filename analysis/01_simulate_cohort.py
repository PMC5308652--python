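#!/usr/bin/env python
"""Simulate the study cohort: an 11-line protein panel with TMZ, TRAIL and
combination viability, written under results/ for the downstream steps."""

from pathlib import Path

import numpy as np

import apoptopredict as ap

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = ap.SimulationConfig(n_lines=11, seed=SEED)
    panel = ap.generate_panel(cfg)
    responses, class_truth = ap.generate_responses(panel, cfg)
    responses, true_ci, synergy_truth = ap.generate_combination(
        panel, cfg, responses
    )

    ap.write_protein_panel(panel, RESULTS / "panel.csv")
    ap.write_viability(responses, RESULTS / "viability.csv")
    np.savetxt(RESULTS / "true_ci.csv", true_ci, header="true_ci", comments="")

    print(f"cell lines: {len(true_ci)}")
    print(f"measurements: {panel.n_measurements}")
    print(f"true response classes (TMZ): {class_truth['TMZ']}")
    print(f"true synergy classes: {synergy_truth}")


if __name__ == "__main__":
    main()
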