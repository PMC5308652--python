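"""Tabular I/O for protein panels and viability tables.

All downstream stages operate on two containers: a :class:`ProteinPanel`
(replicate-resolved protein quantifications per cell line, nM for immunoblot
proteins and relative surface-expression units for the death receptors) and a
:class:`ResponseTable` (survival fractions relative to untreated control, per
cell line and treatment arm).  This module owns the canonical protein
vocabulary, alias normalization, validation, and round-trip-safe readers and
writers for both.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """Input violates the expected table schema (unknown names, bad headers)."""


class ValidationError(ValueError):
    """Input parses but carries invalid values (negative amounts, etc.)."""


#: The 19 proteins of the apoptosis panel.  DR4/DR5 are measured as relative
#: cell-surface expression; the remaining 17 as nM concentrations calibrated
#: against a reference standard.
CANONICAL_PROTEINS: tuple[str, ...] = (
    "Apaf-1",
    "Bak",
    "Bax",
    "Bcl-2",
    "Bcl-xL",
    "Bid",
    "Bim",
    "caspase-3",
    "caspase-8",
    "caspase-9",
    "cFLIP",
    "FADD",
    "Mcl-1",
    "Noxa",
    "Puma",
    "SMAC",
    "XIAP",
    "DR4",
    "DR5",
)

#: Proteins quantified in relative (non-nM) units.
RELATIVE_UNIT_PROTEINS: frozenset[str] = frozenset({"DR4", "DR5"})

#: Recognized treatment arms.
TREATMENTS: tuple[str, ...] = (
    "TMZ",
    "TRAIL",
    "TMZ+TRAIL",
    "TMZ+ABT737",
    "TRAIL+ABT737",
    "ABT737",
)

# Extra spellings seen in the wild, beyond plain case/punctuation variants.
_EXTRA_ALIASES: dict[str, str] = {
    "bcl2l1": "Bcl-xL",
    "bclx": "Bcl-xL",
    "bclxl": "Bcl-xL",
    "mcl1l": "Mcl-1",
    "casp3": "caspase-3",
    "casp8": "caspase-8",
    "casp9": "caspase-9",
    "flip": "cFLIP",
    "trailr1": "DR4",
    "trailr2": "DR5",
    "tnfrsf10a": "DR4",
    "tnfrsf10b": "DR5",
    "smacdiablo": "SMAC",
    "diablo": "SMAC",
    "bbc3": "Puma",
    "pmaip1": "Noxa",
}

_TREATMENT_ALIASES: dict[str, str] = {
    "tmz": "TMZ",
    "trail": "TRAIL",
    "tmztrail": "TMZ+TRAIL",
    "trailtmz": "TMZ+TRAIL",
    "combo": "TMZ+TRAIL",
    "combination": "TMZ+TRAIL",
    "tmzabt737": "TMZ+ABT737",
    "abt737tmz": "TMZ+ABT737",
    "trailabt737": "TRAIL+ABT737",
    "abt737trail": "TRAIL+ABT737",
    "abt737": "ABT737",
    "abt": "ABT737",
}


def _norm_key(name: str) -> str:
    return "".join(ch for ch in name.casefold() if ch.isalnum())


_ALIAS_TABLE: dict[str, str] = {_norm_key(p): p for p in CANONICAL_PROTEINS}
_ALIAS_TABLE.update(_EXTRA_ALIASES)


def canonical_protein(name: str) -> str:
    """Map a protein name or alias onto the canonical vocabulary.

    Raises :class:`SchemaError` for names outside the panel.
    """
    key = _norm_key(str(name))
    try:
        return _ALIAS_TABLE[key]
    except KeyError:
        raise SchemaError(f"unknown protein name: {name!r}") from None


def canonical_treatment(label: str) -> str:
    key = _norm_key(str(label))
    try:
        return _TREATMENT_ALIASES[key]
    except KeyError:
        raise SchemaError(f"unknown treatment label: {label!r}") from None


def default_units() -> dict[str, str]:
    return {
        p: ("relative" if p in RELATIVE_UNIT_PROTEINS else "nM")
        for p in CANONICAL_PROTEINS
    }


@dataclass
class ProteinPanel:
    """Replicate-resolved cell line x protein quantification matrix.

    ``data`` is long-format with columns ``cell_line, protein, replicate,
    value``; ``units`` maps each protein to ``"nM"`` or ``"relative"``.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=default_units)

    def __post_init__(self) -> None:
        required = {"cell_line", "protein", "replicate", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"panel table missing columns: {sorted(missing)}")
        bad = [p for p in self.data["protein"].unique() if p not in CANONICAL_PROTEINS]
        if bad:
            raise SchemaError(f"unknown protein name: {bad[0]!r}")
        neg = self.data[self.data["value"] < 0]
        if not neg.empty:
            row = neg.iloc[0]
            raise ValidationError(
                f"negative value {row['value']} for "
                f"({row['cell_line']}, {row['protein']}, rep {row['replicate']})"
            )

    @property
    def cell_lines(self) -> list[str]:
        return list(pd.unique(self.data["cell_line"]))

    @property
    def proteins(self) -> list[str]:
        return list(pd.unique(self.data["protein"]))

    @property
    def n_measurements(self) -> int:
        return len(self.data)

    def to_wide(self) -> pd.DataFrame:
        """Aggregated lines x proteins matrix (replicate means)."""
        agg = aggregate_replicates(self)
        wide = agg.data.pivot(index="cell_line", columns="protein", values="value")
        return wide.reindex(index=self.cell_lines, columns=self.proteins)

    @classmethod
    def from_wide(
        cls,
        wide: pd.DataFrame,
        units: Mapping[str, str] | None = None,
    ) -> "ProteinPanel":
        """Build a single-replicate panel from a lines x proteins frame."""
        wide = wide.rename(columns=canonical_protein)
        long = wide.reset_index(names="cell_line").melt(
            id_vars="cell_line", var_name="protein", value_name="value"
        )
        long["replicate"] = 1
        long = long[["cell_line", "protein", "replicate", "value"]]
        return cls(long, dict(units) if units is not None else default_units())


def aggregate_replicates(panel: ProteinPanel) -> ProteinPanel:
    """Average replicates to one value per (line, protein); units unchanged.

    Idempotent: a single-replicate panel is returned unchanged in value.
    """
    grouped = (
        panel.data.groupby(["cell_line", "protein"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    grouped["replicate"] = 1
    grouped = grouped[["cell_line", "protein", "replicate", "value"]]
    return ProteinPanel(grouped, dict(panel.units))


@dataclass
class ResponseTable:
    """Per (cell line, treatment) survival fraction relative to control.

    Values slightly above 1 are tolerated (assay noise around the untreated
    control); negatives are rejected.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cell_line", "treatment", "survival"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"viability table missing columns: {sorted(missing)}")
        bad = [t for t in self.data["treatment"].unique() if t not in TREATMENTS]
        if bad:
            raise SchemaError(f"unknown treatment label: {bad[0]!r}")
        neg = self.data[self.data["survival"] < 0]
        if not neg.empty:
            row = neg.iloc[0]
            raise ValidationError(
                f"negative survival {row['survival']} for "
                f"({row['cell_line']}, {row['treatment']})"
            )
        dup = self.data.duplicated(subset=["cell_line", "treatment"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise ValidationError(
                f"duplicate (cell_line, treatment) pair: "
                f"({row['cell_line']}, {row['treatment']})"
            )

    def survival(self, cell_line: str, treatment: str) -> float:
        sel = self.data[
            (self.data["cell_line"] == cell_line)
            & (self.data["treatment"] == treatment)
        ]
        if sel.empty:
            raise KeyError(f"no survival recorded for ({cell_line}, {treatment})")
        return float(sel["survival"].iloc[0])

    def arm(self, treatment: str) -> pd.Series:
        """Survival fractions for one treatment arm, indexed by cell line."""
        sel = self.data[self.data["treatment"] == treatment]
        return sel.set_index("cell_line")["survival"]


def read_protein_panel(
    path: str | Path,
    sep: str = ",",
    units: Mapping[str, str] | None = None,
) -> ProteinPanel:
    """Read a delimited panel table.

    Layout: header row names proteins, first column names cell lines; an
    optional ``replicate`` column (any position) carries the replicate index.
    Without one, repeated cell-line rows are numbered as successive replicates.
    """
    raw = pd.read_csv(path, sep=sep)
    first = raw.columns[0]
    rep_col = next((c for c in raw.columns if _norm_key(c) == "replicate"), None)
    protein_cols = [c for c in raw.columns if c not in (first, rep_col)]
    rename = {c: canonical_protein(c) for c in protein_cols}
    raw = raw.rename(columns=rename)

    long = raw.melt(
        id_vars=[c for c in (first, rep_col) if c is not None],
        var_name="protein",
        value_name="value",
    )
    long = long.rename(columns={first: "cell_line"})
    if rep_col is not None:
        long = long.rename(columns={rep_col: "replicate"})
    else:
        long["replicate"] = long.groupby(["cell_line", "protein"]).cumcount() + 1
    long = long[["cell_line", "protein", "replicate", "value"]]
    long["value"] = pd.to_numeric(long["value"])
    return ProteinPanel(long, dict(units) if units is not None else default_units())


def write_protein_panel(panel: ProteinPanel, path: str | Path, sep: str = ",") -> None:
    """Write a panel in the wide dialect :func:`read_protein_panel` accepts."""
    wide = panel.data.pivot_table(
        index=["cell_line", "replicate"],
        columns="protein",
        values="value",
        sort=False,
    ).reset_index()
    cols = ["cell_line", "replicate"] + [
        p for p in panel.proteins if p in wide.columns
    ]
    wide[cols].to_csv(path, sep=sep, index=False)


def read_viability(
    path: str | Path,
    sep: str = ",",
    percent: bool = True,
) -> ResponseTable:
    """Read a viability table with columns cell_line, treatment, survival.

    ``percent=True`` (the assay's 100%-of-control convention) divides survival
    by 100; ``percent=False`` reads fractions as-is.
    """
    raw = pd.read_csv(path, sep=sep)
    cols = {_norm_key(c): c for c in raw.columns}
    try:
        df = pd.DataFrame(
            {
                "cell_line": raw[cols["cellline"]],
                "treatment": raw[cols["treatment"]].map(canonical_treatment),
                "survival": pd.to_numeric(raw[cols["survival"]]),
            }
        )
    except KeyError as exc:
        raise SchemaError(f"viability table missing column: {exc}") from None
    if percent:
        df["survival"] = df["survival"] / 100.0
    return ResponseTable(df)


def write_viability(
    table: ResponseTable, path: str | Path, sep: str = ",", percent: bool = False
) -> None:
    df = table.data.copy()
    if percent:
        df["survival"] = df["survival"] * 100.0
    df.to_csv(path, sep=sep, index=False)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "to_frame_dict"):
        return _jsonable(obj.to_frame_dict())
    return obj


def write_report(
    results,
    path: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> None:
    """Serialize a pipeline output with run metadata.

    DataFrames are additionally written as a CSV sibling of ``path``; the JSON
    report always carries config hash, seed and library versions so every
    number is traceable to a run.
    """
    path = Path(path)
    cfg_json = json.dumps(_jsonable(config or {}), sort_keys=True)
    meta = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    payload = {"metadata": meta, "results": _jsonable(results)}
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
    if isinstance(results, pd.DataFrame):
        results.to_csv(path.with_suffix(".csv"), index=False)
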