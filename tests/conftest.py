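import numpy as np
import pandas as pd
import pytest

import apoptopredict as ap


@pytest.fixture(scope="session")
def cohort():
    """Default 11-line synthetic cohort: panel, full response table, truth."""
    cfg = ap.SimulationConfig(n_lines=11, seed=7)
    panel = ap.generate_panel(cfg)
    responses, truth = ap.generate_responses(panel, cfg)
    responses, true_ci, synergy_truth = ap.generate_combination(
        panel, cfg, responses
    )
    return {
        "cfg": cfg,
        "panel": panel,
        "responses": responses,
        "truth": truth,
        "true_ci": true_ci,
        "synergy_truth": synergy_truth,
    }


@pytest.fixture(scope="session")
def fg_matrix(cohort):
    return ap.compute_fg_matrix(cohort["panel"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_fg_matrix(rng, n_lines=8, n_fgs=11):
    """Positive FG-like matrix with independent log-normal columns."""
    names = [f"fg{i}" for i in range(n_fgs)]
    values = pd.DataFrame(
        np.exp(rng.normal(size=(n_lines, n_fgs))),
        index=[f"L{i}" for i in range(n_lines)],
        columns=names,
    )
    values.index.name = "cell_line"
    return ap.FGMatrix(values)
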