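"""Correlation-scale principal-component space over functional-group values.

FG units are heterogeneous (nM sums, nM^2-scale products, dimensionless
ratios), so each FG is z-scored over the training cell lines before the
eigendecomposition — i.e. PCA of the correlation matrix, the scale on which
the Kaiser eigenvalue-greater-than-one retention rule is defined.  The fitted
model freezes the standardization so held-out or perturbed lines project into
the same space without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .functional_groups import FGMatrix


class PCFitError(ValueError):
    pass


@dataclass
class StandardizationParams:
    """Per-FG mean and SD (ddof=1) frozen at fit time."""

    mean: pd.Series
    sd: pd.Series

    def transform(self, values: pd.DataFrame | pd.Series):
        if isinstance(values, pd.Series):
            values = values.reindex(self.mean.index)
        else:
            values = values.reindex(columns=self.mean.index)
        if values.isna().any(axis=None):
            raise PCFitError("missing FG value(s) at projection time")
        return (values - self.mean) / self.sd


@dataclass
class PCModel:
    """Loadings, eigenvalues and retained dimension of the PC space.

    ``loadings`` is FG x PC with orthonormal columns; eigenvalues are on the
    correlation scale (they sum to the FG count) in descending order; ``k``
    is the retained dimension (Kaiser: eigenvalues above 1, floor 1).
    """

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    k: int
    standardization: StandardizationParams
    training_lines: list[str]

    @property
    def explained_fraction(self) -> float:
        return explained_variance(self, self.k)

    def save(self, path: str | Path) -> None:
        payload = {
            "loadings": self.loadings.to_dict(orient="split"),
            "eigenvalues": self.eigenvalues.tolist(),
            "k": self.k,
            "mean": self.standardization.mean.to_dict(),
            "sd": self.standardization.sd.to_dict(),
            "training_lines": self.training_lines,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "PCModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        ld = payload["loadings"]
        loadings = pd.DataFrame(ld["data"], index=ld["index"], columns=ld["columns"])
        fg_order = list(loadings.index)
        return cls(
            loadings=loadings,
            eigenvalues=np.asarray(payload["eigenvalues"], dtype=float),
            k=int(payload["k"]),
            standardization=StandardizationParams(
                mean=pd.Series(payload["mean"]).reindex(fg_order),
                sd=pd.Series(payload["sd"]).reindex(fg_order),
            ),
            training_lines=list(payload["training_lines"]),
        )


def fit_pc_model(fg: FGMatrix, n_components: int | None = None) -> PCModel:
    """Fit standardization + correlation PCA on the training cell lines.

    ``n_components`` overrides the Kaiser retention count when given.
    Constant FGs (SD below 1e-12 of the mean magnitude) are a fit error.
    """
    values = fg.values
    n, p = values.shape
    if n < 3:
        raise PCFitError(f"need at least 3 cell lines, got {n}")

    # canonical C-contiguous layout: identical inputs then give bit-identical
    # reductions and BLAS results regardless of the frame's block structure
    arr = np.ascontiguousarray(values.to_numpy(dtype=float))
    mean = pd.Series(arr.mean(axis=0), index=values.columns)
    sd = pd.Series(arr.std(axis=0, ddof=1), index=values.columns)
    tiny = 1e-12 * np.maximum(mean.abs(), 1.0)
    constant = sd[(sd <= 0) | (sd < tiny)]
    if not constant.empty:
        raise PCFitError(f"constant FG column: {constant.index[0]!r}")

    z = (arr - mean.to_numpy()) / sd.to_numpy()
    corr = z.T @ z / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]

    # deterministic sign: largest-|coefficient| entry of each PC positive
    for j in range(p):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]

    if n_components is None:
        k = max(1, int(np.sum(evals > 1.0)))
    else:
        if not 1 <= n_components <= p:
            raise PCFitError(f"n_components must be in [1, {p}]")
        k = int(n_components)

    loadings = pd.DataFrame(
        evecs, index=values.columns, columns=[f"PC{j + 1}" for j in range(p)]
    )
    return PCModel(
        loadings=loadings,
        eigenvalues=evals,
        k=k,
        standardization=StandardizationParams(mean=mean, sd=sd),
        training_lines=list(values.index),
    )


def project(model: PCModel, fg_row: pd.Series) -> np.ndarray:
    """Coordinates of one line in the retained k-dim PC space.

    Uses the model's frozen standardization; never refits.
    """
    z = model.standardization.transform(fg_row).to_numpy(dtype=float)
    return z @ model.loadings.to_numpy()[:, : model.k]


def project_matrix(model: PCModel, fg: FGMatrix) -> pd.DataFrame:
    z = np.ascontiguousarray(
        model.standardization.transform(fg.values).to_numpy(dtype=float)
    )
    coords = z @ model.loadings.to_numpy()[:, : model.k]
    return pd.DataFrame(
        coords, index=fg.values.index, columns=list(model.loadings.columns[: model.k])
    )


def explained_variance(model: PCModel, m: int) -> float:
    """Cumulative variance share of the first m PCs."""
    p = len(model.eigenvalues)
    if not 1 <= m <= p:
        raise ValueError(f"m must be in [1, {p}], got {m}")
    return float(model.eigenvalues[:m].sum() / model.eigenvalues.sum())
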