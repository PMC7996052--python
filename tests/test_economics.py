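import numpy as np
import pytest

from oryzaroot.economics import (DEFAULT_VARIANTS, LEDGER_ROWS, benefit_cost,
                                 build_ledger, cost_from_weight,
                                 hypothetical_scan, recovery_case1,
                                 recovery_case2, recovery_case3,
                                 single_class_histogram)
from oryzaroot.growth import GrowthCurve


@pytest.fixture(scope="module")
def ledger(system31, uptake31):
    return build_ledger(system31, uptake31, 31)


class TestLedger:
    def test_totals_are_column_sums(self, ledger):
        for col in ("uptake_ug", "length_m", "surface_cm2", "weight_mg",
                    "cost_ug"):
            assert ledger.loc["total", col] == pytest.approx(
                ledger.drop("total")[col].sum(), rel=1e-12)

    def test_derived_columns_recompute_exactly(self, ledger):
        """The ledger is arithmetically closed: every derived column is the
        exact quotient/product of its own row's base columns."""
        for r in LEDGER_ROWS:
            row = ledger.loc[r]
            assert row["cost_ug"] == pytest.approx(0.8 * row["weight_mg"],
                                                   rel=1e-12)
            assert row["benefit_cost"] == pytest.approx(
                row["uptake_ug"] / row["cost_ug"], rel=1e-12)
            assert row["eff_length"] == pytest.approx(
                row["uptake_ug"] / row["length_m"], rel=1e-12)
            assert row["eff_surface"] == pytest.approx(
                row["uptake_ug"] / row["surface_cm2"], rel=1e-12)

    def test_cost_scales_linearly_with_tissue_p(self, ledger):
        assert cost_from_weight(50.5) == pytest.approx(40.4)
        assert cost_from_weight(50.5, 1.6) == pytest.approx(80.8)

    def test_benefit_cost_ordering_hairs_s_l_nodal(self, ledger):
        bc = ledger["benefit_cost"]
        assert bc["hairs"] > bc["stype"] > bc["ltype"] > bc["nodal"]

    def test_zero_cost_is_signalled(self):
        with pytest.raises(ValueError):
            benefit_cost(10.0, 0.0)


class TestRecovery:
    def test_case1_zero_cost_is_free(self):
        assert recovery_case1(0.0, 1.0) == 0.0

    def test_case1_zero_income_is_never(self):
        assert recovery_case1(5.0, 0.0) == float("inf")

    def test_case1_ordering_stype_ltype_nodal(self, ledger, uptake31):
        daily = uptake31.daily_uptake_ug(31)
        nodal_daily = sum(daily[c] for c in ("primary", "nodal_branched",
                                             "nodal_fast", "nodal_tiller"))
        days = {
            "stype": recovery_case1(ledger.loc["stype", "cost_ug"],
                                    daily["stype"]),
            "ltype": recovery_case1(ledger.loc["ltype", "cost_ug"],
                                    daily["ltype"]),
            "nodal": recovery_case1(ledger.loc["nodal", "cost_ug"],
                                    nodal_daily),
        }
        assert days["stype"] < days["ltype"] < days["nodal"]
        assert days["stype"] < 1.5

    def test_no_income_never_breaks_even(self, params):
        import dataclasses as dc
        p = params.copy()
        p.soil = dc.replace(p.soil, imax=0.0)
        assert recovery_case2("stype", p, horizon=20, n_nodes=16) == float("inf")

    def test_stype_breaks_even_within_two_days(self, params):
        assert recovery_case2("stype", params, horizon=20, n_nodes=24) <= 2.0
        assert recovery_case3("stype", params, horizon=20, n_nodes=24) <= 2.0

    @pytest.mark.parametrize("cls", ["stype", "ltype", "nodal_branched"])
    def test_case3_never_earlier_than_case2(self, params, cls):
        c2 = recovery_case2(cls, params, horizon=40, n_nodes=16)
        c3 = recovery_case3(cls, params, horizon=40, n_nodes=16)
        assert c3 >= c2

    def test_nodal_breaks_even_later_than_ltype(self, params):
        n = recovery_case2("nodal_branched", params, horizon=40, n_nodes=16)
        l = recovery_case2("ltype", params, horizon=40, n_nodes=16)
        assert n > l


class TestSingleClassSystem:
    def test_growth_is_continuous_past_one_lifetime(self, params):
        curve = GrowthCurve.for_class(params.classes["stype"])
        edges, hist = single_class_histogram("stype", params, 30.0)
        total = hist["stype"].sum()
        assert total > 2.5 * curve.max_length  # several re-initiations
        assert np.all(hist["stype"] >= 0.0)

    def test_matches_growth_curve_within_first_lifetime(self, params):
        curve = GrowthCurve.for_class(params.classes["ltype"])
        edges, hist = single_class_histogram("ltype", params, 10.0)
        grown = hist["ltype"].cumsum()
        k = int(8.0 / 0.2) - 1
        assert grown[k] == pytest.approx(curve.cumulative(edges[k + 1]),
                                         rel=1e-9)


@pytest.fixture(scope="module")
def scan(params):
    return hypothetical_scan(params, seed=5, at=21, n_nodes=16)


class TestHypotheticalScan:
    def test_identity_variant_changes_nothing(self, params):
        table = hypothetical_scan(params, variants={"same": []}, seed=5,
                                  at=15, n_nodes=16)
        assert table.loc["same", "d_uptake_pct"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc["same", "d_cost_pct"] == pytest.approx(0.0, abs=1e-9)

    def test_nodal_thinning_saves_cost_overproportionally(self, scan):
        row = scan.loc["nodal_thin"]
        assert row["d_cost_pct"] < 0.0
        assert row["d_uptake_pct"] < 0.0
        assert abs(row["d_cost_pct"]) > abs(row["d_uptake_pct"])

    def test_hairs_and_stype_keep_top_benefit_cost(self, scan):
        for variant in scan.index:
            ratios = {r: scan.loc[variant, f"bc_{r}"]
                      for r in ("hairs", "stype", "ltype", "nodal")}
            top2 = sorted(ratios, key=ratios.get, reverse=True)[:2]
            assert set(top2) == {"hairs", "stype"}

    def test_longer_ltype_raises_uptake(self, scan):
        assert scan.loc["ltype_double", "d_uptake_pct"] > 0.0
        assert scan.loc["ltype_half", "d_uptake_pct"] < 0.0

    def test_default_variant_set_matches_study_design(self):
        assert set(DEFAULT_VARIANTS) == {"stype_half", "stype_double",
                                         "ltype_half", "ltype_double",
                                         "nodal_thin"}
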