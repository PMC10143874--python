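import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from hp13c import GammaInput, PKParams
from hp13c.kinetics import (
    LAC_X, LAC_Y, LAC_Z, PYR_X, PYR_Y, PYR_Z,
    generator_matrix, propagate_tr, relaxation_exchange_propagator,
    rf_rotation, spoil,
)


class TestPropagator:
    @pytest.mark.parametrize("kpl,t1p,t1l,dt", [
        (0.05, 20.0, 30.0, 1.0),
        (0.0, 15.0, 25.0, 2.5),
        (0.3, 5.0, 5.0, 0.7),       # degenerate a == b branch nearby
        (1.0 / 30.0 - 1.0 / 20.0 + 0.0, 20.0, 30.0, 3.0),
    ])
    def test_matches_matrix_exponential(self, kpl, t1p, t1l, dt):
        """Closed-form propagator equals expm of the generator."""
        p = PKParams(kpl=max(kpl, 0.0), t1_pyr=t1p, t1_lac=t1l)
        A = relaxation_exchange_propagator(p, dt)
        np.testing.assert_allclose(A, expm(generator_matrix(p) * dt),
                                   rtol=0, atol=1e-12)

    def test_matches_ode_integration(self, params):
        """One second of decay from pure pyruvate, against an ODE oracle."""
        def rhs(_, y):
            mp, ml = y
            return [-(params.kpl + params.r1p) * mp,
                    params.kpl * mp - params.r1l * ml]

        sol = solve_ivp(rhs, (0.0, 1.0), [1.0, 0.0], rtol=1e-12, atol=1e-14)
        state = relaxation_exchange_propagator(params, 1.0) @ \
            np.array([0, 0, 1.0, 0, 0, 0])
        assert state[PYR_Z] == pytest.approx(math.exp(-0.1), rel=1e-10)
        assert state[PYR_Z] == pytest.approx(sol.y[0, -1], rel=1e-9)
        assert state[LAC_Z] == pytest.approx(sol.y[1, -1], rel=1e-9)

    def test_identity_at_dt_zero(self, params):
        np.testing.assert_array_equal(
            relaxation_exchange_propagator(params, 0.0), np.eye(6))

    def test_negative_dt_rejected(self, params):
        with pytest.raises(ValueError, match="dt"):
            relaxation_exchange_propagator(params, -1.0)

    def test_pools_decouple_without_exchange(self):
        """kpl = 0: each pool decays with its own T1, no cross-term."""
        p = PKParams(kpl=0.0, t1_pyr=20.0, t1_lac=30.0)
        t = 7.3
        A = relaxation_exchange_propagator(p, t)
        assert A[PYR_Z, PYR_Z] == pytest.approx(math.exp(-t / 20.0), rel=1e-12)
        assert A[LAC_Z, LAC_Z] == pytest.approx(math.exp(-t / 30.0), rel=1e-12)
        assert A[LAC_Z, PYR_Z] == 0.0

    @settings(deadline=None, max_examples=50)
    @given(kpl=st.floats(0.0, 0.5), dt=st.floats(0.0, 60.0),
           mp=st.floats(0.0, 2.0), ml=st.floats(0.0, 2.0))
    def test_mass_conserved_at_infinite_t1(self, kpl, dt, mp, ml):
        """Without relaxation, exchange only moves longitudinal mass."""
        p = PKParams(kpl=kpl, t1_pyr=math.inf, t1_lac=math.inf)
        state = relaxation_exchange_propagator(p, dt) @ \
            np.array([0, 0, mp, 0, 0, ml])
        assert state[PYR_Z] + state[LAC_Z] == pytest.approx(mp + ml, abs=1e-10)

    @settings(deadline=None, max_examples=50)
    @given(a=st.floats(0.0, 20.0), b=st.floats(0.0, 20.0))
    def test_semigroup(self, params, a, b):
        """expm(R a) expm(R b) == expm(R (a+b))."""
        left = relaxation_exchange_propagator(params, a) @ \
            relaxation_exchange_propagator(params, b)
        np.testing.assert_allclose(
            left, relaxation_exchange_propagator(params, a + b),
            rtol=0, atol=1e-10)

    def test_pyruvate_decay_monotone_in_kpl(self):
        mz = [relaxation_exchange_propagator(PKParams(kpl=k), 5.0)[PYR_Z, PYR_Z]
              for k in (0.0, 0.02, 0.05, 0.1, 0.3)]
        assert all(x > y for x, y in zip(mz, mz[1:]))


class TestRotationAndSpoil:
    def test_full_excitation_selective(self):
        state = rf_rotation(90.0, "pyruvate") @ np.array([0, 0, 1.0, 0, 0, 1.0])
        assert state[PYR_Z] == pytest.approx(0.0, abs=1e-12)
        assert math.hypot(state[PYR_X], state[PYR_Y]) == pytest.approx(1.0)
        np.testing.assert_array_equal(state[3:], [0, 0, 1.0])

    def test_zero_flip_is_identity(self):
        np.testing.assert_allclose(rf_rotation(0.0, "both"), np.eye(6),
                                   atol=1e-15)

    def test_small_flip_geometry(self):
        state = rf_rotation(10.0, "pyruvate") @ np.array([0, 0, 1.0, 0, 0, 0])
        assert state[PYR_Z] == pytest.approx(math.cos(math.radians(10)))
        assert math.hypot(state[PYR_X], state[PYR_Y]) == pytest.approx(
            math.sin(math.radians(10)))

    def test_unknown_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            rf_rotation(10.0, "alanine")
        with pytest.raises(ValueError, match="pool"):
            spoil("urea")

    def test_spoil_zeroes_selected_transverse(self):
        state = np.array([0.3, 0.1, 0.5, 0.2, 0.0, 0.7])
        np.testing.assert_array_equal(spoil("both") @ state,
                                      [0, 0, 0.5, 0, 0, 0.7])
        pyr_only = spoil("pyruvate") @ state
        np.testing.assert_array_equal(pyr_only, [0, 0, 0.5, 0.2, 0.0, 0.7])

    def test_spoil_idempotent(self):
        for pool in ("pyruvate", "lactate", "both"):
            s = spoil(pool)
            np.testing.assert_array_equal(s @ s, s)


class TestPropagateTr:
    def test_near_identity_limit(self):
        p = PKParams(kpl=0.0, t1_pyr=1e12, t1_lac=1e12)
        state = np.array([0, 0, 0.8, 0, 0, 0.4])
        out = propagate_tr(state, 0.0, p, 0.0)
        np.testing.assert_allclose(out, state, atol=1e-12)

    def test_cosine_loss_over_repeats(self):
        """No relaxation/exchange: MPz after n pulses is cos(a)^n."""
        p = PKParams(kpl=0.0, t1_pyr=1e12, t1_lac=1e12)
        state = np.array([0, 0, 1.0, 0, 0, 0])
        for _ in range(12):
            state = propagate_tr(state, 25.0, p, 1.0, pool="pyruvate")
        assert state[PYR_Z] == pytest.approx(
            math.cos(math.radians(25.0)) ** 12, rel=1e-10)

    def test_composes_relaxation_and_rotation(self, params):
        """One TR from pure pyruvate: MPz = cos(flip) * exp(-(kpl+R1P) TR)."""
        tr = 0.0664
        out = propagate_tr(np.array([0, 0, 1.0, 0, 0, 0]), 10.0, params, tr,
                           pool="pyruvate")
        expect = math.cos(math.radians(10.0)) * math.exp(-0.1 * tr)
        assert out[PYR_Z] == pytest.approx(expect, rel=1e-12)

    def test_bad_state_shape_rejected(self, params):
        with pytest.raises(ValueError, match="6-vector"):
            propagate_tr(np.zeros(5), 10.0, params, 1.0)


class TestGammaInput:
    def test_measured_fwhm_matches_spec(self, input_fn):
        t = np.linspace(0, 60, 60001)
        y = input_fn.pdf(t)
        above = t[y >= 0.5 * y.max()]
        assert above[-1] - above[0] == pytest.approx(8.0, abs=2e-3)

    def test_zero_before_arrival(self):
        fn = GammaInput(fwhm=8.0, arrival_time=5.0)
        t = np.linspace(0, 4.999, 100)
        assert np.all(fn.pdf(t) == 0)
        assert np.all(fn.sample(t) == 0)

    def test_samples_sum_to_amplitude(self):
        fn = GammaInput(fwhm=8.0, amplitude=3.7)
        total = fn.sample(np.linspace(0.0, 200.0, 2000)).sum()
        assert total == pytest.approx(3.7, rel=1e-3)

    def test_zero_amplitude_all_zero(self):
        fn = GammaInput(amplitude=0.0)
        assert np.all(fn.sample(np.linspace(0, 50, 100)) == 0)

    def test_shape_controls_asymmetry_not_fwhm(self):
        for shape in (2.0, 4.0, 8.0):
            fn = GammaInput(fwhm=8.0, shape=shape)
            t = np.linspace(0, 100, 100001)
            y = fn.pdf(t)
            above = t[y >= 0.5 * y.max()]
            assert above[-1] - above[0] == pytest.approx(8.0, abs=2e-3)

    def test_non_monotone_grid_rejected(self, input_fn):
        with pytest.raises(ValueError, match="non-decreasing"):
            input_fn.sample(np.array([0.0, 2.0, 1.0]))

    def test_json_round_trip(self):
        fn = GammaInput(fwhm=6.0, arrival_time=2.0, amplitude=1.5, shape=3.0)
        again = GammaInput.from_dict(fn.to_dict())
        assert again == fn

    def test_params_validation(self):
        with pytest.raises(ValueError):
            PKParams(kpl=-0.1)
        with pytest.raises(ValueError):
            PKParams(t1_pyr=0.0)
        with pytest.raises(ValueError):
            GammaInput(fwhm=-1.0)
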