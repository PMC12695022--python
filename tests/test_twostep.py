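"""Two-step model algebra, inversion, ledger and error propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from docklock.thermo import ThermoRecord
from docklock.twostep import (
    build_energy_ledger,
    check_kon_inequality,
    dissect_pair,
    dock_state_population,
    effective_from_dock_lock,
    infer_lock_constant,
    lock_exchange_lower_bound,
    propagate_errors,
)


class TestEffectiveConstants:
    def test_no_lock_limit(self):
        assert effective_from_dock_lock(41.5, 1900.0, math.inf) == (41.5, 1900.0)
        kd, koff = effective_from_dock_lock(41.5, 1900.0, 1e9)
        assert kd == pytest.approx(41.5, rel=1e-8)

    def test_equal_partition(self):
        assert effective_from_dock_lock(10.0, 100.0, 1.0) == pytest.approx((5.0, 50.0))

    def test_wt_off_rate_self_consistency(self):
        # invert the rate relation on the same construct pair, then forward again
        kl = 130.2 / (1900.0 - 130.2)
        _, koff_eff = effective_from_dock_lock(41.5, 1900.0, kl)
        assert koff_eff == pytest.approx(130.2, abs=0.05)

    @settings(max_examples=60, derandomize=True)
    @given(kl=st.floats(1e-4, 1e3), kd=st.floats(1e-3, 1e4), koff=st.floats(1e-2, 1e4))
    def test_round_trip_and_ratio_identity(self, kl, kd, koff):
        kd_eff, koff_eff = effective_from_dock_lock(kd, koff, kl)
        assert infer_lock_constant(kd_eff, kd, "exact") == pytest.approx(kl, rel=1e-10)
        # Eqs. for K'_D and k'_off share the same scale factor exactly
        assert koff_eff / kd_eff == pytest.approx(koff / kd, rel=1e-12)


class TestLockConstantInversion:
    def test_vll_pair_small_kl(self):
        assert infer_lock_constant(0.081, 18.7, "small_kl_limit") == pytest.approx(
            0.0043, abs=5e-5
        )

    def test_wt_pair_small_kl(self):
        assert round(infer_lock_constant(3.5, 41.5, "small_kl_limit"), 2) == 0.08

    def test_exact_midpoint(self):
        assert infer_lock_constant(5.0, 10.0, "exact") == pytest.approx(1.0)

    def test_modes_agree_for_small_kl(self):
        for kl in (1e-3, 0.01, 0.049):
            kd_eff, _ = effective_from_dock_lock(10.0, 1.0, kl)
            exact = infer_lock_constant(kd_eff, 10.0, "exact")
            small = infer_lock_constant(kd_eff, 10.0, "small_kl_limit")
            assert small == pytest.approx(exact, rel=0.05)

    def test_inconsistent_pair_rejected(self):
        with pytest.raises(ValueError):
            infer_lock_constant(50.0, 41.5)
        with pytest.raises(ValueError):
            infer_lock_constant(10.0, 10.0, "exact")


class TestDockPopulationAndExchangeBound:
    def test_wt_dock_population_is_about_8_percent(self):
        assert dock_state_population(3.5, 41.5) == pytest.approx(0.084, abs=0.001)

    def test_vll_dock_population(self):
        assert dock_state_population(0.081, 18.7) == pytest.approx(0.0043, abs=5e-5)

    def test_no_lock_gives_unity(self):
        assert dock_state_population(7.0, 7.0) == 1.0

    @pytest.mark.parametrize("hz", [2000.0, 0.0, 500.0])
    def test_lock_exchange_threshold_identity(self, hz):
        assert lock_exchange_lower_bound(hz) == hz


class TestKonInequality:
    def test_wt_pair_consistent(self):
        assert (
            check_kon_inequality(
                kon_eff=37.0, kon_eff_err=11.0, kon_dock=45.8, kon_dock_err=9.8
            )
            == "consistent"
        )

    def test_vll_pair_violated(self):
        assert (
            check_kon_inequality(
                kon_eff=192.0, kon_eff_err=21.0, kon_dock=82.0, kon_dock_err=14.0
            )
            == "violated"
        )

    def test_equal_rates_are_consistent(self):
        assert (
            check_kon_inequality(
                kon_eff=50.0, kon_eff_err=5.0, kon_dock=50.0, kon_dock_err=5.0
            )
            == "consistent"
        )

    def test_missing_uncertainty_refused(self):
        with pytest.raises(ValueError):
            check_kon_inequality(kon_eff=37.0, kon_dock=45.8)
        # explicit override allowed
        assert (
            check_kon_inequality(kon_eff=37.0, kon_dock=45.8, allow_zero_uncertainty=True)
            == "consistent"
        )


class TestEnergyLedger:
    @pytest.fixture()
    def records(self):
        return [
            ThermoRecord("EBH/4MACF", kd=10400, dg=-11.312, dg_err=0.066),
            ThermoRecord("EBH/11MACF", kd=3.5, dg=-31.20, dg_err=0.81),
            ThermoRecord("EBH-dC/11MACF", kd=41.5, dg=-24.62, dg_err=1.7),
            ThermoRecord("EBH/11MACF-VLL", kd=0.081, dg=-40.50, dg_err=0.25),
        ]

    def test_headline_contrasts(self, records):
        ledger = build_energy_ledger(
            records,
            [
                ("total", "EBH/11MACF", "EBH/4MACF"),
                ("folding", "EBH/11MACF", "EBH-dC/11MACF"),
                ("vll", "EBH/11MACF-VLL", "EBH/11MACF"),
            ],
        )
        d = ledger.as_dict()
        assert d["total"] == pytest.approx(-19.888, abs=1e-9)
        assert d["folding"] == pytest.approx(-6.58, abs=1e-9)
        assert d["vll"] == pytest.approx(-9.30, abs=1e-9)
        # every entry reproduces the difference of the records it cites
        by = {r.complex_label: r for r in records}
        for e in ledger.entries:
            assert e.ddg == pytest.approx(by[e.pair[0]].dg - by[e.pair[1]].dg, abs=1e-9)

    def test_missing_record_named(self, records):
        with pytest.raises(KeyError, match="nope"):
            build_energy_ledger(records, [("x", "nope", "EBH/11MACF")])


class TestErrorPropagation:
    def test_kon_example(self):
        from docklock.thermo import kon_from_kd_koff

        v, s = propagate_errors(
            kon_from_kd_koff, [(41.5, 8.8), (1900.0, 54.0)], seed=11
        )
        assert v == pytest.approx(45.8, rel=0.03)
        assert s == pytest.approx(9.8, rel=0.30)

    def test_zero_sigma_degenerates(self):
        v, s = propagate_errors(lambda a, b: a / b, [(10.0, 0.0), (2.0, 0.0)], seed=1)
        assert (v, s) == (5.0, 0.0)

    def test_linear_function_matches_closed_form(self):
        a, sigma = 3.0, 0.5
        v, s = propagate_errors(
            lambda x: a * x + 1.0, [(10.0, sigma)], n_draws=60000, seed=2
        )
        assert v == pytest.approx(31.0, abs=0.05)
        assert s == pytest.approx(a * sigma, rel=0.03)

    def test_deterministic_given_seed(self):
        f = lambda x, y: x * y
        r1 = propagate_errors(f, [(2.0, 0.3), (4.0, 0.2)], seed=9)
        r2 = propagate_errors(f, [(2.0, 0.3), (4.0, 0.2)], seed=9)
        assert r1 == r2

    def test_rejects_tiny_draw_counts(self):
        with pytest.raises(ValueError):
            propagate_errors(lambda x: x, [(1.0, 0.1)], n_draws=10)


class TestDissectPair:
    def test_wt_pair_dissection(self):
        full = ThermoRecord(
            "EBH/11MACF", kd=3.5, kd_err=1.0, dg=-31.20, koff=130.2, koff_err=2.1
        )
        trunc = ThermoRecord(
            "EBH-dC/11MACF", kd=41.5, kd_err=8.8, dg=-24.62, koff=1900.0, koff_err=54.0
        )
        d = dissect_pair(full, trunc, max_shift_difference_hz=2000.0, seed=5)
        assert d.kl_small_limit == pytest.approx(0.0843, abs=1e-3)
        assert d.kl_rate_route == pytest.approx(0.0685, abs=1e-3)
        assert d.dock_fraction == pytest.approx(0.084, abs=1e-3)
        assert d.kex_lock_lower_bound == 2000.0
        assert d.kon_dock == pytest.approx(45.8, rel=0.05)
        assert d.kon_eff == pytest.approx(37.2, rel=0.08)
        assert d.kon_verdict == "consistent"
        # the two K_L routes bracket the printed 0.08-0.07 tension
        assert d.kl_rate_route < d.kl_small_limit
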