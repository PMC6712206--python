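"""Per-timepoint I/V regression and conductance reconstruction."""

import itertools

import numpy as np
import pytest

from eidecomp import (Condition, ReversalPotentials, Sweep, SweepSet,
                      TimeBase, decompose, excitability_ratio,
                      fit_iv_per_timepoint, measure_gm, qc_linearity)
from eidecomp.decomposition import IVFit
from eidecomp.errors import (DataError, InsufficientDataError, ParameterError)
from eidecomp.synthetic_data import (NoiseModel, kernel_waveform,
                                     simulate_voltage_clamp, default_kernels,
                                     DEFAULT_TIMEBASE)

from conftest import preprocess

TB2 = TimeBase(0.0, 0.1, 11)


def averaged_set(currents_by_v, tb=TB2):
    sweeps = [Sweep(tb, np.asarray(vals, float), v, Condition.AIP, 0)
              for v, vals in currents_by_v.items()]
    return SweepSet(sweeps, Condition.AIP)


class TestIVFit:
    def test_two_point_hand_algebra(self):
        # G_exc = 2 nS, G_inh = 8 nS, E_exc = 0, E_inh = -70:
        # I(V) = 2 V + 8 (V + 70); I(-90) = -340, I(-50) = +60
        ss = averaged_set({-90.0: np.full(11, -340.0),
                           -50.0: np.full(11, 60.0)})
        fit = fit_iv_per_timepoint(ss)
        assert np.allclose(fit.a_nS, 10.0)
        assert np.allclose(fit.b_pA, 560.0)
        assert fit.n_potentials == 2

    def test_zero_current_everywhere(self):
        ss = averaged_set({v: np.zeros(11) for v in (-90.0, -70.0, -50.0)})
        fit = fit_iv_per_timepoint(ss)
        assert np.allclose(fit.a_nS, 0.0)
        assert np.allclose(fit.b_pA, 0.0)
        assert np.allclose(fit.r2, 1.0)  # flat-line convention

    def test_five_potentials_match_two(self):
        def current(v):
            return np.full(11, 2.0 * v + 8.0 * (v + 70.0))
        full = fit_iv_per_timepoint(
            averaged_set({v: current(v)
                          for v in (-90.0, -80.0, -70.0, -60.0, -50.0)}))
        assert np.allclose(full.a_nS, 10.0)
        assert np.allclose(full.b_pA, 560.0)
        assert np.allclose(full.r2, 1.0)

    def test_single_potential_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_iv_per_timepoint(averaged_set({-70.0: np.zeros(11)}))

    def test_nonfinite_rejected(self):
        bad = np.zeros(11)
        bad[3] = np.nan
        with pytest.raises(DataError):
            fit_iv_per_timepoint(averaged_set({-90.0: bad,
                                               -50.0: np.zeros(11)}))


class TestDecompose:
    def test_hand_example(self):
        fit = IVFit(TB2, np.full(11, 10.0), np.full(11, 560.0),
                    np.ones(11), 2)
        ct = decompose(fit)
        assert np.allclose(ct.G_inh_nS, 8.0)   # 560 / 70
        assert np.allclose(ct.G_exc_nS, 2.0)

    def test_null_fit(self):
        fit = IVFit(TB2, np.zeros(11), np.zeros(11), np.ones(11), 2)
        ct = decompose(fit)
        assert np.allclose(ct.G_exc_nS, 0.0)
        assert np.allclose(ct.G_inh_nS, 0.0)

    def test_pure_excitation_has_zero_inhibition(self):
        # with E_exc = 0 the intercept vanishes for pure excitation
        a = np.linspace(0, 3, 11)
        fit = IVFit(TB2, a, np.zeros(11), np.ones(11), 2)
        ct = decompose(fit)
        assert np.allclose(ct.G_inh_nS, 0.0)
        assert np.allclose(ct.G_exc_nS, a)

    def test_equal_reversals_rejected(self):
        with pytest.raises(ParameterError):
            ReversalPotentials(-70.0, -70.0)

    def test_slope_is_total_conductance(self, noisefree_sweepset, reversals):
        fit = fit_iv_per_timepoint(preprocess(noisefree_sweepset))
        ct = decompose(fit, reversals)
        assert np.allclose(ct.G_exc_nS + ct.G_inh_nS, fit.a_nS, atol=1e-12)

    def test_clipping_flag(self):
        fit = IVFit(TB2, np.full(11, 1.0), np.full(11, -140.0), np.ones(11), 2)
        ct = decompose(fit, clip_negative=True)
        assert ct.clipped
        assert np.all(ct.G_inh_nS >= 0)


class TestOracleEquivalence:
    """Noise-free simulated sweep sets recover ground truth for every
    subset of >= 2 holding potentials (max error < 1e-9 nS)."""

    def test_all_subsets(self, aip_truth, analysis_timebase, reversals):
        gexc, ginh = aip_truth
        potentials = (-90.0, -80.0, -70.0, -60.0, -50.0)
        for k in (2, 3, 4, 5):
            for subset in itertools.combinations(potentials, k):
                ss = simulate_voltage_clamp(
                    gexc, ginh, analysis_timebase,
                    potentials_mV=subset,
                    noise=NoiseModel(current_sd_pA=0.0))
                ct = decompose(fit_iv_per_timepoint(preprocess(ss)),
                               reversals)
                assert np.max(np.abs(ct.G_exc_nS - gexc)) < 1e-9
                assert np.max(np.abs(ct.G_inh_nS - ginh)) < 1e-9

    def test_linearity_of_decomposition(self, analysis_timebase, reversals):
        aip_e, aip_i = (kernel_waveform(k, analysis_timebase)
                        for k in default_kernels(Condition.AIP))
        la_e, la_i = (kernel_waveform(k, analysis_timebase)
                      for k in default_kernels(Condition.LA))

        def decomp(ge, gi):
            ss = simulate_voltage_clamp(ge, gi, analysis_timebase,
                                        noise=NoiseModel(current_sd_pA=0.0))
            return decompose(fit_iv_per_timepoint(preprocess(ss)), reversals)

        single_a = decomp(aip_e, aip_i)
        single_b = decomp(la_e, la_i)
        summed = decomp(aip_e + la_e, aip_i + la_i)
        assert np.max(np.abs(summed.G_exc_nS
                             - (single_a.G_exc_nS + single_b.G_exc_nS))) < 1e-9
        assert np.max(np.abs(summed.G_inh_nS
                             - (single_a.G_inh_nS + single_b.G_inh_nS))) < 1e-9


class TestMeasureGm:
    @pytest.mark.parametrize("r_mohm, expected_ns", [(111.0, 1000 / 111.0),
                                                     (104.0, 1000 / 104.0)])
    def test_passive_cell(self, r_mohm, expected_ns):
        # -10 mV step from holding: steady-state current dI = dV / R
        tb = TimeBase(-100.0, 0.1, 2001)
        step = -10.0
        i = np.where(tb.times() >= 0, step / r_mohm * 1000.0, 0.0)
        gm = measure_gm(Sweep(tb, i, -70.0, Condition.STEP), step)
        assert gm == pytest.approx(expected_ns, rel=0.01)

    def test_zero_response(self):
        tb = TimeBase(-100.0, 0.1, 2001)
        sw = Sweep(tb, np.zeros(tb.n_samples), -70.0, Condition.STEP)
        assert measure_gm(sw, -10.0) == 0.0

    def test_zero_step_rejected(self):
        tb = TimeBase(-100.0, 0.1, 2001)
        sw = Sweep(tb, np.zeros(tb.n_samples), -70.0, Condition.STEP)
        with pytest.raises(ParameterError):
            measure_gm(sw, 0.0)


class TestExcitabilityRatio:
    def test_hand_value(self):
        fit = IVFit(TB2, np.full(11, 10.0), np.full(11, 560.0),
                    np.ones(11), 2)
        er = excitability_ratio(decompose(fit), G_m_nS=9.0)
        assert np.allclose(er.ratio, 11.0 / 17.0)  # (2+9)/(8+9)

    @pytest.mark.parametrize("g", [0.0, 3.5])
    def test_balanced_conductances_give_unity(self, g):
        from eidecomp.decomposition import ConductanceTrace
        ct = ConductanceTrace(TB2, np.full(11, g), np.full(11, g))
        assert np.allclose(excitability_ratio(ct, 9.0).ratio, 1.0)

    def test_ratio_above_one_iff_more_excitation(self, noisefree_sweepset,
                                                 reversals):
        ct = decompose(fit_iv_per_timepoint(preprocess(noisefree_sweepset)),
                       reversals)
        er = excitability_ratio(ct, G_m_nS=9.0)
        np.testing.assert_array_equal(er.ratio > 1,
                                      ct.G_exc_nS > ct.G_inh_nS)

    def test_nonpositive_gm_rejected(self):
        from eidecomp.decomposition import ConductanceTrace
        ct = ConductanceTrace(TB2, np.zeros(11), np.zeros(11))
        with pytest.raises(ParameterError):
            excitability_ratio(ct, 0.0)


def test_qc_linearity_flags_nonlinear_iv():
    tb = TimeBase(0.0, 0.1, 101)
    # strongly rectifying (quadratic) I/V: low r2 for a line
    potentials = (-90.0, -80.0, -70.0, -60.0, -50.0)
    sweeps = [Sweep(tb, np.full(101, (v + 70.0) ** 2), v, Condition.AIP, 0)
              for v in potentials]
    fit = fit_iv_per_timepoint(SweepSet(sweeps, Condition.AIP))
    assert not qc_linearity(fit, r2_min=0.9, window_ms=(0.0, 10.0))
    # and a perfectly linear set passes
    lin = [Sweep(tb, np.full(101, 5.0 * v + 20.0), v, Condition.AIP, 0)
           for v in potentials]
    fit2 = fit_iv_per_timepoint(SweepSet(lin, Condition.AIP))
    assert qc_linearity(fit2, r2_min=0.9, window_ms=(0.0, 10.0))
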