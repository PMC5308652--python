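"""Pathway-informed functional-group (FG) encoding of the protein panel.

Each FG condenses a small set of mechanistically related apoptosis proteins
into one feature via simple arithmetic: functionally redundant proteins are
summed (the anti-apoptotic Bcl-2/Bcl-xL/Mcl-1 pool, the Bax/Bak MOMP pore),
obligate complexes are multiplied so the feature vanishes when any component
is absent (the Apaf-1 x caspase-9 apoptosome, the death-inducing signaling
complex), effector/inhibitor pairs become ratios (caspase-8/cFLIP,
caspase-3/XIAP), and proteins with individually debated roles stay single
(the BH3-only proteins Bid, Bim, Puma, Noxa; SMAC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .io_model import CANONICAL_PROTEINS, ProteinPanel, aggregate_replicates

COMBINATORS = ("SUM", "PRODUCT", "RATIO", "SINGLE")


class FGError(ValueError):
    pass


@dataclass(frozen=True)
class FGDefinition:
    """One functional group.

    ``members`` holds protein lists by combinator:

    - SUM / SINGLE: one list, values added (SINGLE must have exactly one).
    - PRODUCT: a list of factors, each factor a protein list whose values are
      summed before the factors are multiplied.  A plain product uses
      single-protein factors; ``[["DR4","DR5"],["FADD"]]`` encodes
      (DR4+DR5) x FADD, which vanishes only when an obligatory component does.
    - RATIO: ``[numerator list, denominator list]``, each summed.
    """

    name: str
    combinator: str
    members: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.combinator not in COMBINATORS:
            raise FGError(f"unknown combinator {self.combinator!r}")
        object.__setattr__(self, "members", _freeze(self.members))
        flat = self.protein_members()
        unknown = [p for p in flat if p not in CANONICAL_PROTEINS]
        if unknown:
            raise FGError(f"{self.name}: unknown protein {unknown[0]!r}")
        if self.combinator == "SINGLE" and len(flat) != 1:
            raise FGError(f"{self.name}: SINGLE needs exactly one member")
        if self.combinator == "RATIO":
            if len(self.members) != 2 or not self.members[0] or not self.members[1]:
                raise FGError(
                    f"{self.name}: RATIO needs nonempty numerator and denominator"
                )
        if self.combinator == "PRODUCT" and any(
            not factor for factor in self.members
        ):
            raise FGError(f"{self.name}: PRODUCT factors must be nonempty")

    def protein_members(self) -> list[str]:
        if self.combinator in ("SUM", "SINGLE"):
            return list(self.members)
        return [p for group in self.members for p in group]

    def evaluate(
        self, row: pd.Series, ratio_policy: str = "strict", eps: float = 0.0
    ) -> float:
        """Compute the FG value from one line's protein amounts."""
        if self.combinator in ("SUM", "SINGLE"):
            return float(sum(row[p] for p in self.members))
        if self.combinator == "PRODUCT":
            val = 1.0
            for factor in self.members:
                val *= sum(row[p] for p in factor)
            return float(val)
        num = float(sum(row[p] for p in self.members[0]))
        den = float(sum(row[p] for p in self.members[1]))
        if den == 0.0:
            if ratio_policy == "strict":
                raise FGError(
                    f"zero denominator in ratio FG {self.name!r} "
                    f"for line {row.name!r} (policy=strict)"
                )
            den = eps
            if den == 0.0:
                raise FGError(
                    f"zero denominator in ratio FG {self.name!r} and zero floor"
                )
        return num / den


def _freeze(members) -> tuple:
    if all(isinstance(m, str) for m in members):
        return tuple(members)
    return tuple(tuple(group) for group in members)


def default_fg_definitions(disc: str = "receptor_sum") -> list[FGDefinition]:
    """The default 11-group encoding of the 19-protein panel.

    ``disc`` selects the DISC arithmetic: ``"receptor_sum"`` computes
    (DR4 + DR5) x FADD — the receptors are redundant seeds of the complex
    while FADD is obligatory — and ``"triple_product"`` the strict
    DR4 x DR5 x FADD.
    """
    if disc == "receptor_sum":
        disc_members = (("DR4", "DR5"), ("FADD",))
    elif disc == "triple_product":
        disc_members = (("DR4",), ("DR5",), ("FADD",))
    else:
        raise FGError(f"unknown DISC variant {disc!r}")
    return [
        FGDefinition("anti_apoptotic_bcl2", "SUM", ("Bcl-2", "Bcl-xL", "Mcl-1")),
        FGDefinition("momp_pore", "SUM", ("Bax", "Bak")),
        FGDefinition("bid", "SINGLE", ("Bid",)),
        FGDefinition("bim", "SINGLE", ("Bim",)),
        FGDefinition("puma", "SINGLE", ("Puma",)),
        FGDefinition("noxa", "SINGLE", ("Noxa",)),
        FGDefinition("apoptosome", "PRODUCT", (("Apaf-1",), ("caspase-9",))),
        FGDefinition("disc", "PRODUCT", disc_members),
        FGDefinition("initiator_ratio", "RATIO", (("caspase-8",), ("cFLIP",))),
        FGDefinition("executioner_ratio", "RATIO", (("caspase-3",), ("XIAP",))),
        FGDefinition("smac", "SINGLE", ("SMAC",)),
    ]


def merged_bh3_fg_definitions(disc: str = "receptor_sum") -> list[FGDefinition]:
    """Variant pooling the four BH3-only proteins into one summed group.

    Kept available but non-default: the separate-variable encoding performed
    at least as well, and keeping Bid/Bim/Puma/Noxa apart preserves their
    individually distinct pathway roles.
    """
    defs = [d for d in default_fg_definitions(disc) if d.name not in
            ("bid", "bim", "puma", "noxa")]
    defs.insert(2, FGDefinition("bh3_only", "SUM", ("Bid", "Bim", "Puma", "Noxa")))
    return defs


@dataclass
class FGMatrix:
    """Cell line x functional group value matrix."""

    values: pd.DataFrame  # index: cell lines; columns: FG names

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.index)

    @property
    def fg_names(self) -> list[str]:
        return list(self.values.columns)

    def row(self, cell_line: str) -> pd.Series:
        return self.values.loc[cell_line]

    def drop(self, cell_line: str) -> "FGMatrix":
        return FGMatrix(self.values.drop(index=cell_line))

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.values.to_csv(path, sep=sep, index_label="cell_line")

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "FGMatrix":
        return cls(pd.read_csv(path, sep=sep, index_col="cell_line"))


def compute_fg_matrix(
    panel: ProteinPanel,
    definitions: Sequence[FGDefinition] | None = None,
    ratio_policy: str = "strict",
    ratio_floor_scale: float = 1e-6,
) -> FGMatrix:
    """Encode an (aggregated) panel into the FG matrix.

    Replicates are averaged first if present.  ``ratio_policy="strict"``
    raises on a zero ratio denominator; ``"floor"`` substitutes
    ``ratio_floor_scale`` times the denominator's panel median.
    """
    if definitions is None:
        definitions = default_fg_definitions()
    wide = aggregate_replicates(panel).data.pivot(
        index="cell_line", columns="protein", values="value"
    )
    wide = wide.reindex(index=pd.unique(panel.data["cell_line"]))
    missing = set(
        p for d in definitions for p in d.protein_members()
    ) - set(wide.columns)
    if missing:
        raise FGError(f"panel missing proteins required by FGs: {sorted(missing)}")

    eps_by_fg: dict[str, float] = {}
    if ratio_policy == "floor":
        for d in definitions:
            if d.combinator == "RATIO":
                dens = wide[list(d.members[1])].sum(axis=1)
                eps_by_fg[d.name] = ratio_floor_scale * float(dens.median())

    out = pd.DataFrame(index=wide.index, dtype=float)
    for d in definitions:
        out[d.name] = [
            d.evaluate(wide.loc[line], ratio_policy, eps_by_fg.get(d.name, 0.0))
            for line in wide.index
        ]
    out.columns.name = None
    out.index.name = "cell_line"
    return FGMatrix(out)


def compute_fg_row(
    protein_values: pd.Series,
    definitions: Sequence[FGDefinition] | None = None,
    ratio_policy: str = "strict",
) -> pd.Series:
    """FG values for a single line given its per-protein amounts."""
    if definitions is None:
        definitions = default_fg_definitions()
    return pd.Series(
        {d.name: d.evaluate(protein_values, ratio_policy) for d in definitions}
    )


def definitions_to_yaml(definitions: Sequence[FGDefinition], path: str | Path) -> None:
    payload = [
        {
            "name": d.name,
            "combinator": d.combinator,
            "members": [list(m) if not isinstance(m, str) else m for m in d.members],
        }
        for d in definitions
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def definitions_from_yaml(path: str | Path) -> list[FGDefinition]:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return [
        FGDefinition(d["name"], d["combinator"], _freeze(d["members"]))
        for d in payload
    ]
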