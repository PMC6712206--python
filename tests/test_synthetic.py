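"""Synthetic-data generators: kernels, clamp/LIF simulators, DUO traces,
diode array, population scenarios."""

import numpy as np
import pytest

from eidecomp import Condition, TimeBase
from eidecomp.errors import ParameterError
from eidecomp.synthetic_data import (DEFAULT_TIMEBASE, ConductanceKernel,
                                     MembraneModel, NoiseModel,
                                     default_kernels, hexagonal_layout,
                                     kernel_waveform, make_duo,
                                     population_scenario, saturating_scale,
                                     simulate_current_clamp, simulate_vsd,
                                     simulate_voltage_clamp)


class TestKernelWaveform:
    def test_zero_peak(self):
        k = ConductanceKernel(5.0, 0.0)
        assert np.all(kernel_waveform(k, DEFAULT_TIMEBASE) == 0)

    def test_grid_max_equals_peak(self):
        k = ConductanceKernel(5.95, 2.94)
        g = kernel_waveform(k, DEFAULT_TIMEBASE)
        assert g.max() == pytest.approx(2.94, abs=1e-9)

    def test_argmax_matches_closed_form(self):
        k = ConductanceKernel(5.0, 1.0, tau_rise_ms=1.0, tau_decay_ms=10.0)
        g = kernel_waveform(k, DEFAULT_TIMEBASE)
        t_peak = DEFAULT_TIMEBASE.times()[np.argmax(g)]
        expected = 5.0 + (1.0 * 10.0 / 9.0) * np.log(10.0)
        assert t_peak == pytest.approx(expected, abs=DEFAULT_TIMEBASE.dt_ms)
        assert k.time_to_peak_ms == pytest.approx(expected)

    def test_zero_before_latency(self):
        k = ConductanceKernel(5.0, 1.0)
        g = kernel_waveform(k, DEFAULT_TIMEBASE)
        assert np.all(g[DEFAULT_TIMEBASE.times() < 5.0] == 0)

    def test_invalid_kinetics(self):
        with pytest.raises(ParameterError):
            ConductanceKernel(5.0, 1.0, tau_rise_ms=10.0, tau_decay_ms=1.0)


class TestVoltageClamp:
    def test_leak_only_current(self, analysis_timebase):
        z = np.zeros(analysis_timebase.n_samples)
        ss = simulate_voltage_clamp(z, z, analysis_timebase,
                                    potentials_mV=(-70.0, -50.0),
                                    noise=NoiseModel(current_sd_pA=0.0))
        sweep = ss.at_potential(-70.0)[0]
        # G_m (V_h - E_rest) = 9.009 * (-7.2) with the 111 MOhm default
        expected = (1000.0 / 111.0) * (-70.0 - (-62.8))
        assert np.allclose(sweep.values, expected)
        assert expected == pytest.approx(-64.86, abs=0.01)

    def test_seed_determinism(self, aip_truth, analysis_timebase):
        gexc, ginh = aip_truth
        kw = dict(noise=NoiseModel(current_sd_pA=10.0, seed=123))
        ss1 = simulate_voltage_clamp(gexc, ginh, analysis_timebase, **kw)
        ss2 = simulate_voltage_clamp(gexc, ginh, analysis_timebase, **kw)
        for s1, s2 in zip(ss1.sweeps, ss2.sweeps):
            assert np.array_equal(s1.values, s2.values)

    def test_excitation_blocked_abolishes_conductances(self, aip_truth,
                                                       analysis_timebase):
        gexc, ginh = aip_truth
        ss = simulate_voltage_clamp(gexc, ginh, analysis_timebase,
                                    noise=NoiseModel(current_sd_pA=0.0),
                                    excitation_blocked=True)
        # leak only: every sweep constant in time
        for s in ss.sweeps:
            assert np.ptp(s.values) == 0.0

    def test_too_few_potentials(self, aip_truth, analysis_timebase):
        gexc, ginh = aip_truth
        with pytest.raises(ParameterError):
            simulate_voltage_clamp(gexc, ginh, analysis_timebase,
                                   potentials_mV=(-70.0,))


class TestCurrentClamp:
    TB = TimeBase(-5.0, 0.01, 4501)

    def test_rest_without_input(self):
        z = np.zeros(self.TB.n_samples)
        sweep, train = simulate_current_clamp(z, z, self.TB)
        assert train.count == 0
        assert np.allclose(sweep.values, -62.8)

    def test_sustained_drive_above_threshold_spikes(self):
        m = MembraneModel()
        # steady state V_inf = (G_m E_rest + g E_exc) / (G_m + g);
        # g = 20 nS drives V_inf to about -25 mV, above the -37.3 threshold
        g = np.full(self.TB.n_samples, 20.0)
        v_inf = (m.G_m_nS * m.E_rest_mV) / (m.G_m_nS + 20.0)
        assert v_inf > m.V_thresh_mV
        _, train = simulate_current_clamp(g, np.zeros_like(g), self.TB, m)
        assert train.count >= 1

    def test_subthreshold_drive_never_spikes(self):
        m = MembraneModel()
        g = np.full(self.TB.n_samples, 3.0)
        v_inf = (m.G_m_nS * m.E_rest_mV) / (m.G_m_nS + 3.0)
        assert v_inf < m.V_thresh_mV
        _, train = simulate_current_clamp(g, np.zeros_like(g), self.TB, m)
        assert train.count == 0

    def test_unstable_dt_rejected(self):
        tb = TimeBase(0.0, 1.0, 100)
        z = np.zeros(100)
        with pytest.raises(ParameterError):
            simulate_current_clamp(z, z, tb)

    def test_duo_latency_not_later_than_single(self):
        from eidecomp.detection import first_spike_latency
        from eidecomp.synthetic_data import PV_AIP_EXC, PV_LA_EXC
        m = MembraneModel.pv_interneuron()
        z = np.zeros(self.TB.n_samples)
        g_aip = kernel_waveform(
            ConductanceKernel(**PV_AIP_EXC), self.TB)
        g_la = kernel_waveform(
            ConductanceKernel(**PV_LA_EXC), self.TB)
        lat = {}
        for name, g in (("AIP", g_aip),
                        ("DUO", make_duo(g_aip, g_la, 1.0))):
            _, train = simulate_current_clamp(g, z, self.TB, m)
            lat[name] = first_spike_latency(train)
        assert lat["AIP"] is not None and lat["DUO"] is not None
        assert lat["DUO"] <= lat["AIP"]

    def test_scaling_up_never_delays_first_spike(self):
        m = MembraneModel.pv_interneuron()
        z = np.zeros(self.TB.n_samples)
        g = kernel_waveform(ConductanceKernel(7.1, 20.0), self.TB)
        lats = []
        for c in (1.0, 1.5, 2.0, 3.0):
            _, train = simulate_current_clamp(c * g, z, self.TB, m)
            assert train.count >= 1
            lats.append(train.spike_times_ms[0])
        assert all(b <= a + 1e-12 for a, b in zip(lats, lats[1:]))


class TestMakeDuo:
    def test_exact_sum(self):
        a, b = np.arange(10.0), np.ones(10)
        assert np.array_equal(make_duo(a, b, 1.0), a + b)

    def test_zero_alpha(self):
        a, b = np.arange(10.0), np.ones(10)
        assert np.all(make_duo(a, b, 0.0) == 0)

    def test_pair_form(self):
        pair_a = (np.arange(5.0), np.ones(5))
        pair_b = (np.ones(5), np.arange(5.0))
        duo = make_duo(pair_a, pair_b, 0.5)
        assert np.allclose(duo[0], 0.5 * (pair_a[0] + pair_b[0]))
        assert np.allclose(duo[1], 0.5 * (pair_a[1] + pair_b[1]))

    def test_saturation_bounds_output(self):
        a = np.full(10, 100.0)
        out = make_duo(a, a, 1.0, saturation=50.0)
        assert np.all(out <= 50.0)


class TestDiodeArray:
    def test_hexagonal_layout_unique_and_sized(self):
        coords = hexagonal_layout(464, 150.0)
        assert coords.shape == (464, 2)
        assert len(np.unique(coords.round(6), axis=0)) == 464
        # nearest-neighbour spacing equals the pitch
        d = np.sqrt(((coords[None] - coords[:, None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(150.0, rel=1e-6)

    def test_seed_determinism(self):
        r1 = simulate_vsd(n_diodes=61, seed=5)
        r2 = simulate_vsd(n_diodes=61, seed=5)
        assert np.array_equal(r1.frames, r2.frames)
        assert np.array_equal(r1.amax, r2.amax)

    def test_zero_amplitude_gives_zero_mean_noise(self):
        rec = simulate_vsd(n_diodes=61, amplitude_fraction=0.0, seed=3)
        frac = rec.frames / rec.amax[None, :, None]
        assert abs(frac.mean()) < 1e-3
        assert frac.std() == pytest.approx(0.002, rel=0.05)

    def test_repeat_structure(self):
        rec = simulate_vsd(n_diodes=61, n_repeats=4, seed=1)
        assert rec.frames.shape[0] == 4


class TestPopulationScenario:
    def test_determinism(self):
        _, a1 = population_scenario(n_cells=6, seed=42)
        _, a2 = population_scenario(n_cells=6, seed=42)
        assert np.array_equal(a1, a2)

    def test_zero_sd_means_identical_alphas(self):
        _, alphas = population_scenario(n_cells=8, alpha_mean=0.77,
                                        alpha_sd=0.0, seed=0)
        assert np.allclose(alphas, 0.77)

    def test_cells_have_all_conditions(self):
        cells, alphas = population_scenario(n_cells=3, seed=1)
        assert len(cells) == 3 and len(alphas) == 3
        for cell in cells:
            assert set(cell) == {"AIP", "LA", "DUO"}
            for pair in cell.values():
                assert len(pair) == 2


def test_saturating_scale_half_max_at_s50():
    assert saturating_scale(400.0, s50_uA=400.0) == pytest.approx(0.5)
    assert saturating_scale(1e6, s50_uA=400.0) == pytest.approx(1.0, abs=1e-5)
    assert saturating_scale(0.0) == 0.0


def test_default_kernels_match_measured_parameters():
    exc, inh = default_kernels(Condition.AIP)
    assert (exc.latency_ms, exc.peak_nS) == (5.95, 2.94)
    assert (inh.latency_ms, inh.peak_nS) == (7.67, 8.89)
    exc_la, inh_la = default_kernels(Condition.LA)
    assert (exc_la.latency_ms, exc_la.peak_nS) == (5.55, 0.75)
    assert (inh_la.latency_ms, inh_la.peak_nS) == (6.72, 3.22)
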