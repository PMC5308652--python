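"""End-to-end orchestration: encode -> PCA -> classify -> LOOCV -> recommend
-> synergy -> sensitize, from one configuration, with persisted artifacts."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .functional_groups import (
    compute_fg_matrix,
    default_fg_definitions,
    definitions_to_yaml,
)
from .io_model import (
    ProteinPanel,
    ResponseTable,
    aggregate_replicates,
    read_protein_panel,
    read_viability,
    write_report,
)
from .loocv_prediction import (
    evaluate_recommendations,
    loocv_predict,
    recommend_treatment,
)
from .pc_space import explained_variance, fit_pc_model, project_matrix
from .response_classification import (
    DEFAULT_THRESHOLDS,
    assign_response_class,
    fit_class_regions,
    pool_singleton_classes,
    resubstitution_accuracy,
)
from .sensitization import ABT737_TARGETS, predict_sensitization, sensitization_table
from .synergy import DEFAULT_CI_BINS, combination_index_table, synergy_loocv


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    panel_path: str | None = None
    viability_path: str | None = None
    viability_percent: bool = True
    disc_variant: str = "receptor_sum"
    ratio_policy: str = "strict"
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    fixed_k: int | None = None  # None -> per-fold Kaiser
    ridge: float | None = None
    priors: str = "uniform"
    similar_tol: float = 0.10
    ci_bins: tuple[float, float] = DEFAULT_CI_BINS
    sensitization_targets: tuple[str, ...] = ABT737_TARGETS
    sensitization_lines: Sequence[str] | None = None  # None -> LOW/RESISTANT lines
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("thresholds", "ci_bins", "sensitization_targets"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def run_full_analysis(
    cfg: RunConfig,
    panel: ProteinPanel | None = None,
    responses: ResponseTable | None = None,
) -> dict:
    """Run the whole pipeline; returns the summary dict and persists artifacts.

    ``panel``/``responses`` may be passed in memory (e.g. from the synthetic
    generator); otherwise they are read from the configured paths.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if panel is None:
        if cfg.panel_path is None:
            raise PipelineError("input", "no panel provided (path or in-memory)")
        panel = read_protein_panel(cfg.panel_path)
    if responses is None:
        if cfg.viability_path is None:
            raise PipelineError(
                "classification", "no viability table provided (path or in-memory)"
            )
        responses = read_viability(cfg.viability_path, percent=cfg.viability_percent)

    # --- functional groups -------------------------------------------------
    defs = default_fg_definitions(cfg.disc_variant)
    fg = compute_fg_matrix(panel, defs, ratio_policy=cfg.ratio_policy)
    fg.to_csv(out / "fg_matrix.csv")
    definitions_to_yaml(defs, out / "fg_definitions.yaml")

    # --- PC space -----------------------------------------------------------
    pc = fit_pc_model(fg, n_components=cfg.fixed_k)
    pc.save(out / "pc_model.json")
    scree = pd.DataFrame(
        {
            "PC": [f"PC{i + 1}" for i in range(len(pc.eigenvalues))],
            "eigenvalue": pc.eigenvalues,
            "cumulative_variance": [
                explained_variance(pc, m) for m in range(1, len(pc.eigenvalues) + 1)
            ],
        }
    )
    scree.to_csv(out / "scree.csv", index=False)
    coords_all = project_matrix(pc, fg)
    coords_all.to_csv(out / "pc_coordinates.csv")

    summary: dict = {
        "k_retained": pc.k,
        "explained_fraction": pc.explained_fraction,
        "n_lines": len(fg.cell_lines),
    }

    # --- per-arm classes, resubstitution, LOOCV -----------------------------
    loocv_results = {}
    predictions = {}
    for arm in ("TMZ", "TRAIL", "TMZ+TRAIL"):
        try:
            survival = responses.arm(arm).reindex(fg.cell_lines)
        except KeyError:
            continue
        if survival.isna().any():
            raise PipelineError("classification", f"missing survival for arm {arm}")
        labels = [
            int(assign_response_class(s, cfg.thresholds)) for s in survival
        ]
        pooled = pool_singleton_classes(labels)
        lda = fit_class_regions(
            coords_all.to_numpy(), pooled, ridge=cfg.ridge, priors=cfg.priors
        )
        resub = resubstitution_accuracy(lda, coords_all.to_numpy(), pooled)
        res = loocv_predict(
            fg,
            labels,
            fixed_k=cfg.fixed_k,
            ridge=cfg.ridge,
            priors=cfg.priors,
        )
        res.to_frame().to_csv(out / f"loocv_{arm.replace('+', '_')}.csv", index=False)
        loocv_results[arm] = res
        predictions[arm] = {r.cell_line: r.predicted for r in res.records}
        summary[f"resubstitution_accuracy_{arm}"] = resub
        summary[f"loocv_accuracy_{arm}"] = res.accuracy

    # --- treatment recommendation -------------------------------------------
    if {"TMZ", "TRAIL"} <= set(loocv_results):
        recs = [
            recommend_treatment(
                line, predictions["TMZ"].get(line), predictions["TRAIL"].get(line)
            )
            for line in fg.cell_lines
        ]
        rec_table = evaluate_recommendations(
            recs,
            responses.arm("TMZ"),
            responses.arm("TRAIL"),
            similar_tol=cfg.similar_tol,
        )
        rec_table.to_csv(out / "recommendations.csv", index=False)
        summary["recommendation_accuracy"] = rec_table.attrs["accuracy"]

    # --- synergy -------------------------------------------------------------
    arms_present = set(responses.data["treatment"])
    if {"TMZ", "TRAIL", "TMZ+TRAIL"} <= arms_present:
        ci_table = combination_index_table(responses, bins=cfg.ci_bins)
        ci_table.to_csv(out / "combination_index.csv", index=False)
        ci_labels = ci_table.set_index("cell_line")["synergy_class"].reindex(
            fg.cell_lines
        )
        syn = synergy_loocv(
            fg,
            list(ci_labels),
            fixed_k=cfg.fixed_k,
            ridge=cfg.ridge,
            priors=cfg.priors,
        )
        syn.to_frame().to_csv(out / "loocv_synergy.csv", index=False)
        summary["synergy_loocv_accuracy"] = syn.accuracy
        summary["median_ci"] = float(ci_table["ci"].median())

    # --- ABT-737 sensitization -----------------------------------------------
    wide = aggregate_replicates(panel).data.pivot(
        index="cell_line", columns="protein", values="value"
    )
    sens_rows = []
    for arm in ("TMZ", "TRAIL"):
        if arm not in loocv_results:
            continue
        survival = responses.arm(arm).reindex(fg.cell_lines)
        labels = [int(assign_response_class(s, cfg.thresholds)) for s in survival]
        pooled = pool_singleton_classes(labels)
        lda = fit_class_regions(
            coords_all.to_numpy(), pooled, ridge=cfg.ridge, priors=cfg.priors
        )
        if cfg.sensitization_lines is None:
            # poorly responsive lines are the sensitization candidates
            candidates = [
                line for line, lab in zip(fg.cell_lines, labels) if lab >= 1
            ]
        else:
            candidates = list(cfg.sensitization_lines)
        for line in candidates:
            sens_rows.append(
                predict_sensitization(
                    pc,
                    lda,
                    line,
                    wide.loc[line],
                    targets=cfg.sensitization_targets,
                    arm=arm,
                    definitions=defs,
                )
            )
    if sens_rows:
        sens = sensitization_table(sens_rows)
        sens.to_csv(out / "sensitization.csv", index=False)
        for arm in ("TMZ", "TRAIL"):
            sub = sens[sens["arm"] == arm]
            if len(sub):
                summary[f"n_sensitized_{arm}"] = int(
                    (sub["verdict"] == "SENSITIZED").sum()
                )
                summary[f"n_sensitization_candidates_{arm}"] = int(len(sub))

    write_report(summary, out / "summary.json", config=asdict(cfg), seed=cfg.seed)
    return summary
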