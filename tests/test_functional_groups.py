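import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import apoptopredict as ap
from apoptopredict.functional_groups import (
    FGError,
    compute_fg_row,
    default_fg_definitions,
    definitions_from_yaml,
    definitions_to_yaml,
    merged_bh3_fg_definitions,
)
from apoptopredict.io_model import CANONICAL_PROTEINS, ProteinPanel


def panel_from_values(values: dict[str, list[float]]) -> ProteinPanel:
    n = len(next(iter(values.values())))
    wide = pd.DataFrame(values, index=[f"L{i}" for i in range(n)])
    return ProteinPanel.from_wide(wide)


def uniform_panel(value: float = 10.0, n: int = 3, **overrides) -> ProteinPanel:
    values = {p: [value] * n for p in CANONICAL_PROTEINS}
    for prot, vals in overrides.items():
        values[prot] = vals
    return panel_from_values(values)


class TestDefaultDefinitions:
    def test_exactly_eleven_groups(self):
        assert len(default_fg_definitions()) == 11

    def test_every_protein_used_exactly_once(self):
        used = [
            p for d in default_fg_definitions() for p in d.protein_members()
        ]
        assert sorted(used) == sorted(CANONICAL_PROTEINS)

    def test_apoptosome_is_product_of_apaf1_and_caspase9(self):
        defs = {d.name: d for d in default_fg_definitions()}
        apo = defs["apoptosome"]
        assert apo.combinator == "PRODUCT"
        assert sorted(apo.protein_members()) == ["Apaf-1", "caspase-9"]

    def test_disc_variants(self):
        rec = {d.name: d for d in default_fg_definitions("receptor_sum")}["disc"]
        trip = {d.name: d for d in default_fg_definitions("triple_product")}["disc"]
        assert rec.members == (("DR4", "DR5"), ("FADD",))
        assert trip.members == (("DR4",), ("DR5",), ("FADD",))

    def test_merged_bh3_variant_has_eight_groups(self):
        defs = merged_bh3_fg_definitions()
        assert len(defs) == 8
        names = {d.name for d in defs}
        assert "bh3_only" in names and "bid" not in names

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "defs.yaml"
        definitions_to_yaml(default_fg_definitions(), path)
        back = definitions_from_yaml(path)
        assert back == default_fg_definitions()


class TestComputeFGMatrix:
    def test_anti_apoptotic_sum(self):
        panel = uniform_panel(
            **{"Bcl-2": [10.0], "Bcl-xL": [20.0], "Mcl-1": [5.0]},
            **{p: [1.0] for p in CANONICAL_PROTEINS if p not in
               ("Bcl-2", "Bcl-xL", "Mcl-1")},
        )
        fg = ap.compute_fg_matrix(panel)
        assert fg.values.loc["L0", "anti_apoptotic_bcl2"] == pytest.approx(35.0)

    def test_apoptosome_zero_propagation(self):
        panel = uniform_panel(10.0, n=1, **{"Apaf-1": [0.0], "caspase-9": [50.0]})
        fg = ap.compute_fg_matrix(panel)
        assert fg.values.loc["L0", "apoptosome"] == 0.0

    def test_ratio_value_and_strict_zero_denominator(self):
        panel = uniform_panel(10.0, n=1, **{"caspase-8": [10.0], "cFLIP": [2.0]})
        fg = ap.compute_fg_matrix(panel)
        assert fg.values.loc["L0", "initiator_ratio"] == pytest.approx(5.0)

        bad = uniform_panel(10.0, n=1, **{"cFLIP": [0.0]})
        with pytest.raises(FGError, match="initiator_ratio"):
            ap.compute_fg_matrix(bad, ratio_policy="strict")

    def test_floor_policy_substitutes_epsilon(self):
        panel = uniform_panel(10.0, n=3, **{"cFLIP": [0.0, 4.0, 4.0]})
        fg = ap.compute_fg_matrix(panel, ratio_policy="floor", ratio_floor_scale=1e-6)
        # denominator median is 4.0 -> floor 4e-6
        assert fg.values.loc["L0", "initiator_ratio"] == pytest.approx(10.0 / 4e-6)

    def test_disc_receptor_sum_vs_triple_product(self):
        panel = uniform_panel(
            10.0, n=1, **{"DR4": [0.0], "DR5": [5.0], "FADD": [2.0]}
        )
        rec = ap.compute_fg_matrix(panel, default_fg_definitions("receptor_sum"))
        trip = ap.compute_fg_matrix(panel, default_fg_definitions("triple_product"))
        # one absent receptor is tolerated by the redundant-receptor form only
        assert rec.values.loc["L0", "disc"] == pytest.approx(10.0)
        assert trip.values.loc["L0", "disc"] == 0.0

    def test_hand_arithmetic_oracle_random_panels(self, rng):
        """FG arithmetic agrees exactly with direct per-line hand computation."""
        for _ in range(100):
            wide = pd.DataFrame(
                rng.lognormal(mean=2.0, sigma=1.0, size=(5, 19)),
                index=[f"L{i}" for i in range(5)],
                columns=list(CANONICAL_PROTEINS),
            )
            fg = ap.compute_fg_matrix(ProteinPanel.from_wide(wide))
            for line in wide.index:
                r = wide.loc[line]
                expected = {
                    "anti_apoptotic_bcl2": r["Bcl-2"] + r["Bcl-xL"] + r["Mcl-1"],
                    "momp_pore": r["Bax"] + r["Bak"],
                    "bid": r["Bid"],
                    "bim": r["Bim"],
                    "puma": r["Puma"],
                    "noxa": r["Noxa"],
                    "apoptosome": r["Apaf-1"] * r["caspase-9"],
                    "disc": (r["DR4"] + r["DR5"]) * r["FADD"],
                    "initiator_ratio": r["caspase-8"] / r["cFLIP"],
                    "executioner_ratio": r["caspase-3"] / r["XIAP"],
                    "smac": r["SMAC"],
                }
                for name, val in expected.items():
                    assert fg.values.loc[line, name] == val  # exact


class TestFGProperties:
    @given(
        vals=st.lists(
            st.floats(min_value=0.0, max_value=1e4, allow_nan=False),
            min_size=3,
            max_size=3,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_sum_permutation_invariance(self, vals):
        row = pd.Series(
            dict(zip(("Bcl-2", "Bcl-xL", "Mcl-1"), vals)), name="L0"
        )
        d = ap.FGDefinition("s", "SUM", ("Bcl-2", "Bcl-xL", "Mcl-1"))
        d_perm = ap.FGDefinition("s", "SUM", ("Mcl-1", "Bcl-2", "Bcl-xL"))
        assert d.evaluate(row) == pytest.approx(d_perm.evaluate(row), rel=1e-12)

    @given(c=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_scaling_laws(self, c):
        base = pd.Series({p: 3.0 for p in CANONICAL_PROTEINS}, name="L0")
        scaled = base * c
        defs = {d.name: d for d in default_fg_definitions()}
        # SUM scales by c; 2-factor PRODUCT by c^2; RATIO invariant
        assert defs["momp_pore"].evaluate(scaled) == pytest.approx(
            c * defs["momp_pore"].evaluate(base)
        )
        assert defs["apoptosome"].evaluate(scaled) == pytest.approx(
            c**2 * defs["apoptosome"].evaluate(base), rel=1e-12
        )
        assert defs["initiator_ratio"].evaluate(scaled) == pytest.approx(
            defs["initiator_ratio"].evaluate(base), rel=1e-12
        )

    def test_product_zero_iff_member_zero(self, rng):
        defs = {d.name: d for d in default_fg_definitions()}
        for _ in range(20):
            row = pd.Series(
                rng.lognormal(size=len(CANONICAL_PROTEINS)),
                index=list(CANONICAL_PROTEINS),
                name="L0",
            )
            assert defs["apoptosome"].evaluate(row) > 0
            row["caspase-9"] = 0.0
            assert defs["apoptosome"].evaluate(row) == 0.0

    def test_single_needs_one_member(self):
        with pytest.raises(FGError):
            ap.FGDefinition("bad", "SINGLE", ("Bid", "Bim"))

    def test_unknown_protein_rejected(self):
        with pytest.raises(FGError, match="unknown protein"):
            ap.FGDefinition("bad", "SUM", ("Bcl-2", "NotAProtein"))


def test_compute_fg_row_matches_matrix(cohort, fg_matrix):
    from apoptopredict.io_model import aggregate_replicates

    wide = aggregate_replicates(cohort["panel"]).data.pivot(
        index="cell_line", columns="protein", values="value"
    )
    line = fg_matrix.cell_lines[0]
    row = compute_fg_row(wide.loc[line])
    pd.testing.assert_series_equal(
        row, fg_matrix.row(line), check_names=False
    )
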