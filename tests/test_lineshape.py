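"""Bloch-McConnell lineshape simulation: closed forms, oracles, fitting."""

import math

import numpy as np
import pytest
from scipy.integrate import simpson

from docklock.lineshape import (
    ExchangeNetwork,
    TitrationSeries,
    default_grid,
    dimer_network,
    fit_titration,
    nucleus_frequency,
    spectrum_1d,
    three_state_effective_check,
    three_state_network,
    titration_networks,
    two_state_network,
)
from docklock.thermo import bound_fraction_two_state
from docklock.synthetic import fixture_preset, generate


def measure_fwhm(grid, s):
    half = s.max() / 2
    above = grid[s >= half]
    return above.max() - above.min()


def fourier_oracle(network, dim, grid_hz, t_max=None, n_t=120001):
    """Independent route: matrix-exponential time propagation + numerical FT.

    s(t) = 1^T exp(Lt) p sampled densely, absorption = Re \\int s(t) e^{-iwt} dt
    by Simpson quadrature.
    """
    nu = network.frequencies_hz(dim)
    L = (
        np.diag(1j * 2 * math.pi * nu - network.r2(dim))
        + network.rate_matrix.astype(complex)
    )
    lam, V = np.linalg.eig(L)
    c = np.linalg.solve(V, network.populations.astype(complex))
    w = (V.sum(axis=0) * c)  # s(t) = sum_j w_j exp(lam_j t)
    if t_max is None:
        t_max = 40.0 / min(-lam.real.max(), network.r2(dim).min())
    t = np.linspace(0, t_max, n_t)
    s_t = (w[None, :] * np.exp(lam[None, :] * t[:, None])).sum(axis=1)
    out = np.empty(len(grid_hz))
    for i, f in enumerate(grid_hz):
        out[i] = simpson(np.real(s_t * np.exp(-1j * 2 * math.pi * f * t)), x=t)
    return out


class TestSpectrumClosedForms:
    def test_single_state_is_lorentzian(self):
        r2 = 20.0
        net = ExchangeNetwork(
            ["a"], [1.0], [8.0], [118.0], [r2], [r2], np.zeros((1, 1)), 800.0
        )
        grid = default_grid(net, "H", 4001)
        s = spectrum_1d(net, "H", grid)
        assert measure_fwhm(grid, s) == pytest.approx(r2 / math.pi, rel=0.02)
        # peak at the state shift
        assert grid[np.argmax(s)] == pytest.approx(8.0 * 800.0, abs=1.0)
        # closed-form Lorentzian amplitude: 1/R2 at resonance
        assert s.max() == pytest.approx(1.0 / r2, rel=1e-3)

    def test_fast_exchange_collapses_to_weighted_mean(self):
        p = np.array([0.3, 0.7])
        nu = np.array([118.0, 120.0])
        dw = (nu[1] - nu[0]) * nucleus_frequency(800.0, "N") * 2 * math.pi
        kex = 400 * dw
        K = np.array([[-p[1] * kex, p[0] * kex], [p[1] * kex, -p[0] * kex]])
        net = ExchangeNetwork(
            ["f", "b"], p, [8.0, 8.0], nu, [15.0, 15.0], [15.0, 15.0], K, 800.0
        )
        mean_nu = float(p @ nu) * nucleus_frequency(800.0, "N")
        grid = np.linspace(mean_nu - 300, mean_nu + 300, 6001)
        s = spectrum_1d(net, "N", grid)
        assert grid[np.argmax(s)] == pytest.approx(mean_nu, abs=1.0)

    def test_slow_exchange_adds_exit_rate_to_width(self):
        p = np.array([0.5, 0.5])
        nu = np.array([110.0, 126.0])
        dw = (nu[1] - nu[0]) * nucleus_frequency(800.0, "N") * 2 * math.pi
        kex = dw / 60  # well inside the slow regime
        r2 = 12.0
        K = np.array([[-p[1] * kex, p[0] * kex], [p[1] * kex, -p[0] * kex]])
        net = ExchangeNetwork(
            ["f", "b"], p, [8.0, 8.0], nu, [r2, r2], [r2, r2], K, 800.0
        )
        mhz = nucleus_frequency(800.0, "N")
        for state_nu in nu:
            c = state_nu * mhz
            grid = np.linspace(c - 40, c + 40, 8001)
            s = spectrum_1d(net, "N", grid)
            expected = (r2 + p[0] * kex) / math.pi  # exit rate = kex/2 here
            assert measure_fwhm(grid, s) == pytest.approx(expected, rel=0.01)

    def test_integrated_intensity_conserved_across_regimes(self):
        p = np.array([0.4, 0.6])
        nu = np.array([116.0, 120.0])
        mhz = nucleus_frequency(800.0, "N")
        ref = None
        for kex in (1.0, 100.0, 1e4, 1e6):
            K = np.array([[-p[1] * kex, p[0] * kex], [p[1] * kex, -p[0] * kex]])
            net = ExchangeNetwork(
                ["f", "b"], p, [8.0, 8.0], nu, [15.0, 15.0], [15.0, 15.0], K, 800.0
            )
            grid = np.linspace(nu.min() * mhz - 2500, nu.max() * mhz + 2500, 30001)
            area = np.trapezoid(spectrum_1d(net, "N", grid), grid)
            if ref is None:
                ref = area
            assert area == pytest.approx(ref, rel=0.01)

    def test_matches_time_domain_fourier_oracle(self):
        net = two_state_network(
            5.0, 130.0, 50.0, 60.0, (8.0, 118.0), (8.3, 120.0),
            spectrometer_h_freq=800.0,
        )
        grid = np.linspace(117.5, 120.5, 7) * nucleus_frequency(800.0, "N")
        direct = spectrum_1d(net, "N", grid)
        oracle = fourier_oracle(net, "N", grid)
        assert np.max(np.abs(direct - oracle)) / np.max(np.abs(direct)) < 1e-6


class TestTitrationNetworks:
    def test_free_point_is_single_state(self):
        net = two_state_network(5.0, 100.0, 50.0, 0.0, (8.0, 118.0), (8.3, 120.0))
        assert net.n_states == 1 and net.labels == ["free"]

    def test_populations_match_equilibrium_and_detailed_balance(self):
        kd, koff, p, l = 4.91, 130.2, 50.0, 80.0
        net = two_state_network(kd, koff, p, l, (8.0, 118.0), (8.3, 120.0))
        fb = bound_fraction_two_state(p, l, kd)
        assert net.populations[1] == pytest.approx(fb, abs=1e-12)
        net.check_detailed_balance()

    def test_saturating_ligand(self):
        net = two_state_network(0.001, 100.0, 10.0, 1e5, (8.0, 118.0), (8.3, 120.0))
        assert net.populations[-1] == pytest.approx(1.0, abs=1e-4)

    def test_dimer_network_detailed_balance_and_populations(self):
        net = dimer_network(
            2.0, 50.0, 1.7, 50.0, 40.0, [8, 8.1, 8.3, 8.4], [118, 118.5, 119.5, 120]
        )
        net.check_detailed_balance()
        assert net.populations.sum() == pytest.approx(1.0)
        assert np.max(np.abs(net.rate_matrix.sum(axis=0))) < 1e-9

    def test_three_state_network_stationary_distribution(self):
        net = three_state_network(
            41.5, 1900.0, 0.08, 1e5, 50.0, 100.0, [8, 8.3, 8.6], [118, 119.5, 121]
        )
        net.check_detailed_balance()
        w, v = np.linalg.eig(net.rate_matrix)
        p_stat = np.real(v[:, np.argmin(np.abs(w))])
        p_stat /= p_stat.sum()
        assert np.allclose(p_stat, net.populations, atol=1e-10)

    def test_cross_module_population_identity(self):
        series = TitrationSeries(
            p_total=[50.0] * 4, l_total=[0.0, 20.0, 60.0, 150.0], residues=["r"]
        )
        nets = titration_networks(
            4.91, 130.2, series, "two_state", {"r": (8.0, 118.0)}, {"r": (8.3, 120.0)}
        )
        for i in range(1, 4):
            fb = bound_fraction_two_state(50.0, series.l_total[i], 4.91)
            assert nets[("r", i)].populations[1] == pytest.approx(fb, abs=1e-12)


class TestThreeStateReduction:
    def test_fast_lock_matches_effective_two_state(self):
        dw_rad = 2 * math.pi * (121.0 - 118.0) * nucleus_frequency(800.0, "N")
        kex = 100.0 * max(dw_rad, 1900.0)
        dev = three_state_effective_check(
            41.5, 1900.0, 0.08, kex, [8.0, 8.3, 8.6], [118.0, 119.5, 121.0],
            [(50.0, l) for l in (0.0, 20.0, 50.0, 100.0, 250.0)],
        )
        assert dev < 0.02

    def test_pure_dock_limit(self):
        dev = three_state_effective_check(
            41.5, 1900.0, 1e8, 1e6, [8.0, 8.3, 8.6], [118.0, 119.5, 121.0],
            [(50.0, l) for l in (0.0, 50.0, 200.0)],
        )
        assert dev < 1e-5

    def test_slow_lock_deviates(self):
        # reported, not asserted small: intermediate-rate lock must distort
        dw_rad = 2 * math.pi * 3.0 * nucleus_frequency(800.0, "N")
        dev = three_state_effective_check(
            41.5, 1900.0, 0.3, dw_rad, [8.0, 8.3, 8.6], [118.0, 119.5, 121.0],
            [(50.0, 100.0)],
        )
        assert dev > 0.02


class TestFitTitration:
    def test_noise_free_recovery_is_essentially_exact(self):
        fix = fixture_preset("EBH_11MACF", seed=3, n_residues=3, noise_nmr=0.0)
        series = generate(fix, "titration_lineshapes")
        fit = fit_titration(series, seed=1)
        assert fit.kd == pytest.approx(4.91, rel=0.01)
        assert fit.koff == pytest.approx(130.2, rel=0.01)

    def test_dimer_with_unit_cooperativity_reduces_to_two_state(self):
        fix = fixture_preset(
            "EBH_11MACF", seed=8, n_residues=3, model="dimer", alpha=1.0, noise_nmr=0.0
        )
        series = generate(fix, "titration_lineshapes")
        fit = fit_titration(series, model="two_state", seed=1)
        assert fit.kd == pytest.approx(4.91, rel=0.02)

    def test_free_point_alone_is_unidentifiable(self):
        fix = fixture_preset("EBH_11MACF", seed=3, n_residues=2)
        series = generate(fix, "titration_lineshapes")
        short = TitrationSeries(
            p_total=series.p_total[:1], l_total=series.l_total[:1],
            residues=series.residues,
            cross_sections={k: v for k, v in series.cross_sections.items() if k[1] == 0},
        )
        with pytest.raises(ValueError):
            fit_titration(short)

    def test_network_invariant_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ExchangeNetwork(
                ["a", "b"], [0.6, 0.6], [8, 8.2], [118, 119], [15, 15], [15, 15],
                np.array([[-1.0, 1.0], [1.0, -1.0]]), 800.0,
            )
        with pytest.raises(ValueError, match="columns"):
            ExchangeNetwork(
                ["a", "b"], [0.5, 0.5], [8, 8.2], [118, 119], [15, 15], [15, 15],
                np.array([[-1.0, 1.0], [2.0, -1.0]]), 800.0,
            )
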