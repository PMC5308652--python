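"""Synthetic protein panels and viability tables with known ground truth.

The generator emulates the statistical structure of the real inputs: protein
abundances are log-normal at plausible nM scales (receptors in relative
units), replicate measurements scatter with a configurable CV, and per-arm
responsiveness is a latent linear function of the standardized functional
groups pushed through a logistic link onto the survival scale.  Combination
viability follows the fractional-product expectation scaled by a controllable
true combination index.  Everything is deterministic under the seed, so every
pipeline stage can be tested against known truth without any measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .functional_groups import FGMatrix, compute_fg_matrix, default_fg_definitions
from .io_model import CANONICAL_PROTEINS, ProteinPanel, ResponseTable, default_units
from .response_classification import DEFAULT_THRESHOLDS, assign_response_class
from .synergy import DEFAULT_CI_BINS, assign_synergy_class

#: Median abundance per protein (nM for immunoblot proteins, relative units
#: for DR4/DR5), spanning roughly 0.1-500 nM as in quantitative apoptosis
#: proteomics panels.
DEFAULT_PROTEIN_MEDIANS: dict[str, float] = {
    "Apaf-1": 50.0,
    "Bak": 80.0,
    "Bax": 120.0,
    "Bcl-2": 20.0,
    "Bcl-xL": 60.0,
    "Bid": 30.0,
    "Bim": 5.0,
    "caspase-3": 150.0,
    "caspase-8": 30.0,
    "caspase-9": 20.0,
    "cFLIP": 4.0,
    "FADD": 12.0,
    "Mcl-1": 10.0,
    "Noxa": 1.0,
    "Puma": 2.0,
    "SMAC": 200.0,
    "XIAP": 40.0,
    "DR4": 30.0,
    "DR5": 60.0,
}

#: Latent-survival coefficients over FGs (positive = pro-survival) per arm.
#: TMZ engages the intrinsic pathway (apoptosome, BH3-only, MOMP pore);
#: TRAIL the extrinsic one (DISC, caspase-8/cFLIP, Bid); the anti-apoptotic
#: Bcl-2 pool protects against both.
DEFAULT_ARM_COEFFICIENTS: dict[str, dict[str, float]] = {
    "TMZ": {
        "anti_apoptotic_bcl2": 1.0,
        "momp_pore": -0.8,
        "apoptosome": -0.8,
        "puma": -0.5,
        "noxa": -0.3,
        "bim": -0.3,
        "executioner_ratio": -0.5,
        "smac": -0.3,
    },
    "TRAIL": {
        "anti_apoptotic_bcl2": 0.8,
        "disc": -1.0,
        "initiator_ratio": -0.8,
        "bid": -0.5,
        "executioner_ratio": -0.5,
        "momp_pore": -0.3,
    },
}

#: Coefficients generating the latent synergy score (positive = higher CI,
#: i.e. less synergy).
DEFAULT_CI_COEFFICIENTS: dict[str, float] = {
    "anti_apoptotic_bcl2": 0.7,
    "apoptosome": -0.7,
    "disc": -0.5,
    "smac": -0.5,
}


@dataclass
class SimulationConfig:
    """Everything the generator needs; the seed fully determines the output."""

    n_lines: int = 11
    seed: int = 0
    protein_medians: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROTEIN_MEDIANS)
    )
    protein_log_sigma: float = 0.8  # between-line spread on the log scale
    n_replicates: int = 3
    replicate_cv: float = 0.15
    bcl2_bclxl_correlation: float = 0.0  # optional co-regulation block
    arm_coefficients: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ARM_COEFFICIENTS.items()}
    )
    arm_intercepts: Mapping[str, float] = field(
        default_factory=lambda: {"TMZ": 0.3, "TRAIL": 0.3}
    )
    class_separation: float = 3.0  # SD of the latent survival score
    viability_noise_sd: float = 0.05
    min_survival: float = 0.01  # assay detection floor (fraction of control)
    true_ci: float | Sequence[float] | None = None  # None -> FG-driven
    ci_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CI_COEFFICIENTS)
    )
    ci_separation: float = 2.0
    ci_intercept: float = 0.0
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    ci_bins: tuple[float, float] = DEFAULT_CI_BINS

    def __post_init__(self) -> None:
        if self.n_lines < 2 or self.n_replicates < 1:
            raise ValueError("need n_lines >= 2 and n_replicates >= 1")
        if self.class_separation < 0 or self.viability_noise_sd < 0:
            raise ValueError("separation and noise SD must be nonnegative")
        if not -1.0 < self.bcl2_bclxl_correlation < 1.0:
            raise ValueError("correlation must be in (-1, 1)")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_panel(cfg: SimulationConfig) -> ProteinPanel:
    """Log-normal protein panel, replicate-resolved, deterministic per seed."""
    rng = cfg.rng(1)
    lines = [f"SL{i + 1:02d}" for i in range(cfg.n_lines)]
    log_true = pd.DataFrame(
        rng.normal(size=(cfg.n_lines, len(CANONICAL_PROTEINS))),
        index=lines,
        columns=list(CANONICAL_PROTEINS),
    )
    rho = cfg.bcl2_bclxl_correlation
    if rho:
        a, b = log_true["Bcl-2"].to_numpy(), log_true["Bcl-xL"].to_numpy()
        log_true["Bcl-xL"] = rho * a + np.sqrt(1 - rho**2) * b
    true = pd.DataFrame(
        {
            p: cfg.protein_medians[p]
            * np.exp(cfg.protein_log_sigma * log_true[p].to_numpy())
            for p in CANONICAL_PROTEINS
        },
        index=lines,
    )

    # multiplicative replicate scatter at the configured CV
    sigma_rep = np.sqrt(np.log1p(cfg.replicate_cv**2))
    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        noise = (
            np.exp(rng.normal(0.0, sigma_rep, size=true.shape) - sigma_rep**2 / 2)
            if sigma_rep > 0
            else np.ones(true.shape)
        )
        rep_vals = true.to_numpy() * noise
        for i, line in enumerate(lines):
            for j, prot in enumerate(CANONICAL_PROTEINS):
                rows.append((line, prot, rep, rep_vals[i, j]))
    data = pd.DataFrame(rows, columns=["cell_line", "protein", "replicate", "value"])
    return ProteinPanel(data, default_units())


def _latent(
    fg: FGMatrix, coefficients: Mapping[str, float], separation: float, intercept: float
) -> np.ndarray:
    """Standardize FGs, combine, rescale to exactly `separation` sample SD."""
    values = fg.values
    sd = values.std(axis=0, ddof=1).replace(0.0, 1.0)
    z = (values - values.mean(axis=0)) / sd
    w = pd.Series(0.0, index=values.columns)
    for name, coef in coefficients.items():
        if name not in w.index:
            raise KeyError(f"coefficient names unknown FG {name!r}")
        w[name] = coef
    u = z.to_numpy() @ w.to_numpy()
    spread = u.std(ddof=1)
    if spread > 0:
        u = u / spread * separation
    else:
        u = np.zeros_like(u)
    return u + intercept


def generate_responses(
    panel: ProteinPanel, cfg: SimulationConfig
) -> tuple[ResponseTable, dict[str, list[int]]]:
    """Mono-arm survival (TMZ, TRAIL) plus noiseless ground-truth classes.

    Latent pro-survival score = linear combination of standardized FG values,
    scaled to ``class_separation`` SD; survival = logistic(latent) + Gaussian
    noise, clipped to [0, 1.1].  Ground truth comes from the noiseless
    survival via the response thresholds.
    """
    fg = compute_fg_matrix(panel, default_fg_definitions())
    rng = cfg.rng(2)
    rows = []
    truth: dict[str, list[int]] = {}
    for arm in ("TMZ", "TRAIL"):
        latent = _latent(
            fg,
            cfg.arm_coefficients[arm],
            cfg.class_separation,
            cfg.arm_intercepts.get(arm, 0.0),
        )
        clean = _sigmoid(latent)
        noisy = np.clip(
            clean + rng.normal(0.0, cfg.viability_noise_sd, size=len(clean)),
            cfg.min_survival,
            1.1,
        )
        truth[arm] = [
            int(assign_response_class(s, cfg.thresholds)) for s in clean
        ]
        rows += [
            {"cell_line": line, "treatment": arm, "survival": float(s)}
            for line, s in zip(fg.cell_lines, noisy)
        ]
    return ResponseTable(pd.DataFrame(rows)), truth


def generate_gaussian_fg_cohort(
    n_lines: int,
    separation: float,
    n_classes: int = 3,
    seed: int = 0,
    baseline: float = 50.0,
) -> tuple[FGMatrix, list[int]]:
    """FG matrix with class-conditional Gaussian structure and known labels.

    Classes sit at means spaced ``separation`` within-class SDs apart along a
    random direction in the 11-dim FG space (unit within-class SD); values are
    shifted by ``baseline`` to stay positive.  This is the controlled geometry
    for testing whether the PCA/LDA machinery recovers a known separable class
    structure, complementing the heavier-tailed protein-level generator.
    """
    if n_classes < 2 or separation < 0:
        raise ValueError("need n_classes >= 2 and separation >= 0")
    rng = np.random.default_rng([int(seed), 4])
    fg_names = [d.name for d in default_fg_definitions()]
    p = len(fg_names)
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    labels = [i % n_classes for i in range(n_lines)]
    rng.shuffle(labels)
    offsets = (np.asarray(labels) - (n_classes - 1) / 2) * separation
    values = (
        baseline
        + offsets[:, None] * direction[None, :]
        + rng.normal(size=(n_lines, p))
    )
    values = np.clip(values, 0.0, None)
    frame = pd.DataFrame(
        values,
        index=[f"SL{i + 1:02d}" for i in range(n_lines)],
        columns=fg_names,
    )
    frame.index.name = "cell_line"
    return FGMatrix(frame), [int(l) for l in labels]


def true_combination_index(panel: ProteinPanel, cfg: SimulationConfig) -> np.ndarray:
    """Per-line true CI: configured directly, or an FG-driven latent mapped
    into (0.15, 1.2) so synergy classes are a deterministic function of the
    protein profile."""
    n = len(pd.unique(panel.data["cell_line"]))
    if cfg.true_ci is not None:
        ci = np.broadcast_to(np.asarray(cfg.true_ci, dtype=float), (n,)).copy()
        if (ci <= 0).any():
            raise ValueError("true CI values must be positive")
        return ci
    fg = compute_fg_matrix(panel, default_fg_definitions())
    latent = _latent(fg, cfg.ci_coefficients, cfg.ci_separation, cfg.ci_intercept)
    return 0.15 + 1.05 * _sigmoid(latent)


def generate_combination(
    panel: ProteinPanel, cfg: SimulationConfig, responses: ResponseTable
) -> tuple[ResponseTable, np.ndarray, list[int]]:
    """Combination-arm survival with known true CI.

    ``s_combo = true_CI * s_TMZ * s_TRAIL + noise`` (clipped to [0, 1.1]);
    returns the extended response table, the true CI vector, and the
    ground-truth synergy classes from the noiseless CI.
    """
    lines = list(pd.unique(panel.data["cell_line"]))
    ci = true_combination_index(panel, cfg)
    s_tmz = responses.arm("TMZ").reindex(lines).to_numpy()
    s_trail = responses.arm("TRAIL").reindex(lines).to_numpy()
    rng = cfg.rng(3)
    # the combination survival quantizes the requested CI to the float grid;
    # store the realized noiseless CI (within 1 ulp of the request) as ground
    # truth so the Webb estimator recovers it exactly when noise is zero
    expected = s_tmz * s_trail
    s_ab = ci * expected
    ci = s_ab / expected
    combo = np.clip(
        s_ab + rng.normal(0.0, cfg.viability_noise_sd, size=len(ci)),
        0.0,
        1.1,
    )
    rows = responses.data.to_dict(orient="records") + [
        {"cell_line": line, "treatment": "TMZ+TRAIL", "survival": float(s)}
        for line, s in zip(lines, combo)
    ]
    truth = [int(assign_synergy_class(c, cfg.ci_bins)) for c in ci]
    return ResponseTable(pd.DataFrame(rows)), ci, truth
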