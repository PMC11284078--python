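"""Ring network mechanics: connectivity, rate function, integrator."""
import numpy as np
import pytest

from swmsim import (
    IntegrationBlowupError,
    NetworkParams,
    NetworkState,
    TraceRecorder,
    check_operating_regime,
    firing_rate,
    make_connectivity,
    run_dynamics,
    step,
)
from swmsim.protocol import StimulusSpec, stimulus_profile
from swmsim.ring import RingGrid, wrap_orientation


def kernel_scalar(d, j_peak, j_floor, b):
    """Independent scalar evaluation of the connectivity kernel."""
    d = (d + np.pi / 2) % np.pi - np.pi / 2
    cutoff = np.arccos(-j_floor / j_peak)
    return j_peak * np.cos(b * d) if abs(b * d) <= cutoff else j_floor


class TestConnectivity:
    def test_self_connection_equals_peak(self, small_params):
        w = make_connectivity(small_params)
        assert np.allclose(np.diag(w), small_params.j_peak)

    def test_translation_invariant_circulant(self, small_params):
        w = make_connectivity(small_params)
        for k in (1, 7, 23):
            assert np.allclose(w[k], np.roll(w[0], k))
        assert np.allclose(w, w.T)

    def test_matches_scalar_kernel(self):
        # inside-cutoff value J*cos(B*d) with J=1, J0=-0.1, B=2, d=0.5
        p = NetworkParams(j_peak=1.0, j_floor=-0.1, b_width=2.0)
        assert kernel_scalar(0.5, 1.0, -0.1, 2.0) == pytest.approx(
            np.cos(1.0), abs=1e-12)
        grid = p.grid()
        w = make_connectivity(p, grid)
        i = 0
        for j in range(p.n_neurons):
            d = wrap_orientation(grid.thetas[i] - grid.thetas[j])
            assert w[i, j] == pytest.approx(
                kernel_scalar(d, 1.0, -0.1, 2.0), abs=1e-12)

    def test_invalid_floor_ratio_rejected(self):
        with pytest.raises(ValueError, match="arccos"):
            NetworkParams(j_peak=0.5, j_floor=-0.6)


class TestFiringRate:
    def test_asymptotes_and_midpoint(self):
        assert firing_rate(-1e4, 1.5) == pytest.approx(0.0, abs=1e-12)
        assert firing_rate(0.0, 1.5) == pytest.approx(1.5 * np.log(2))
        h = 10 * 1.5
        assert firing_rate(h, 1.5) == pytest.approx(h, rel=1e-4)

    def test_monotone_and_overflow_safe(self):
        h = np.linspace(-1e3, 1e3, 101)
        r = firing_rate(h, 1.5)
        assert np.all(np.isfinite(r)) and np.all(np.diff(r) > 0)

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            firing_rate(0.0, 0.0)


class TestStep:
    def test_silent_network_is_fixed_point(self):
        # with a drive so far below threshold that the excitatory rate
        # underflows to zero, the self-consistent silent state (which
        # includes the inhibitory pool's tonic rate at h_I = 0) is invariant
        p = NetworkParams(n_neurons=32, i0=-200.0, sigma0=0.0)
        conn = make_connectivity(p)
        st = NetworkState.resting(p)
        st.h_e[:] = p.i0 - p.j_ei * firing_rate(0.0, p.alpha)
        st2 = step(st, 0.0, p, conn, rng=None)
        assert np.allclose(st2.h_e, st.h_e, atol=1e-12)
        assert np.allclose(st2.h_i, st.h_i, atol=1e-12)
        assert np.allclose(st2.u, st.u, atol=1e-12)
        assert np.allclose(st2.x, st.x, atol=1e-12)

    def test_stp_relaxation_at_zero_rate(self, small_params):
        # clamp the ring far below threshold: u decays with tau_f, x
        # recovers with tau_d
        p = small_params.replace(sigma0=0.0, i0=-1e4)
        conn = make_connectivity(p)
        st = NetworkState.resting(p)
        st.u[:] = 0.6
        st.x[:] = 0.3
        u_start = st.u.max()
        st = run_dynamics(st, None, 5 * p.tau_f, p, conn)
        assert st.u.max() < 0.01 * u_start
        assert st.x.min() > 0.99

    def test_sustained_input_facilitates_and_depletes(self, default_params):
        p = default_params.replace(sigma0=0.0)
        grid = p.grid()
        conn = make_connectivity(p, grid)
        st = NetworkState.resting(p)
        prof = stimulus_profile(StimulusSpec(30.0, 4.0, center=0.0), grid)
        st = run_dynamics(st, lambda t, g: prof, 0.25, p, conn)
        mid = np.argmin(np.abs(grid.thetas))
        assert st.u[mid] > 0.5      # facilitation built up
        assert st.x[mid] < 0.5      # resources depleted

    def test_u_x_stay_bounded_under_random_drive(self, small_params, rng):
        p = small_params.replace(sigma0=0.5)
        conn = make_connectivity(p)
        st = NetworkState.resting(p)
        for _ in range(400):
            ext = rng.uniform(-5.0, 40.0, p.n_neurons)
            st = step(st, ext, p, conn, rng)
            assert np.all((st.u >= 0) & (st.u <= 1))
            assert np.all((st.x >= 0) & (st.x <= 1))

    def test_blowup_raises_informative_error(self):
        # resource depletion self-limits genuine recurrent runaway, so the
        # non-finite guard is exercised directly with a corrupted state
        p = NetworkParams(n_neurons=32, sigma0=0.0)
        conn = make_connectivity(p)
        st = NetworkState.resting(p)
        st.h_e[3] = np.inf
        with pytest.raises(IntegrationBlowupError, match="t="):
            step(st, 0.0, p, conn, None)


class TestRunDynamics:
    def test_zero_duration_returns_initial_state(self, small_params):
        conn = make_connectivity(small_params)
        st = NetworkState.resting(small_params)
        rec = TraceRecorder(("u", "x"), stride=10)
        out = run_dynamics(st, None, 0.0, small_params, conn, recorders=[rec])
        assert out.t == st.t
        assert rec.traces["u"].shape[0] == 1  # only the initial sample

    def test_deterministic_given_seed(self, small_params):
        conn = make_connectivity(small_params)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            st = NetworkState.resting(small_params)
            st = run_dynamics(st, lambda t, g: 5.0, 0.05, small_params, conn, rng)
            outs.append(st.h_e.copy())
        assert np.array_equal(outs[0], outs[1])

    def test_recording_stride_bookkeeping(self, small_params):
        conn = make_connectivity(small_params)
        st = NetworkState.resting(small_params)
        rec = TraceRecorder(("u",), stride=10)
        duration = 0.05  # 100 steps at dt=0.5 ms
        run_dynamics(st, None, duration, small_params, conn, recorders=[rec])
        expected = int(duration / (10 * small_params.dt)) + 1
        assert rec.traces["u"].shape[0] == expected

    def test_translation_equivariance(self):
        # rotating the stimulus by k grid steps rotates the noise-free
        # response by k steps (circulant connectivity)
        p = NetworkParams(n_neurons=60, j_peak=0.6, j_floor=-0.06, sigma0=0.0)
        grid = p.grid()
        conn = make_connectivity(p, grid)
        k = 9
        profiles = []
        for center in (0.0, k * grid.spacing):
            prof = stimulus_profile(StimulusSpec(20.0, 4.0, center=center), grid)
            st = NetworkState.resting(p)
            st = run_dynamics(st, lambda t, g: prof, 0.1, p, conn)
            profiles.append(firing_rate(st.h_e, p.alpha))
        assert np.allclose(np.roll(profiles[0], k), profiles[1], atol=1e-8)


class TestOperatingRegime:
    def test_calibrated_defaults_satisfy_all_conditions(self, default_params):
        rep = check_operating_regime(default_params)
        assert rep["bump"] and rep["silence"] and rep["reactivation"]
        # silence: activity falls below 1% of the encoding peak
        assert rep["peak_rate_after_settle"] < 0.01 * rep["peak_rate_encode"]

    def test_single_bump_competition(self, default_params):
        # facilitate two distant sites, then apply a spatially uniform weak
        # noisy drive: global inhibition lets exactly one bump reignite
        from swmsim import MeanRateAccumulator

        p = default_params
        grid = p.grid()
        conn = make_connectivity(p, grid)
        rng = np.random.default_rng(3)
        st = NetworkState.resting(p)
        for c in (-np.pi / 4, np.pi / 4):
            prof = stimulus_profile(StimulusSpec(20.0, 6.0, center=c), grid)
            sup = prof > 0
            fn = lambda t, g: prof + 1.0 * sup * g.standard_normal(prof.shape)
            st = run_dynamics(st, fn, 0.25, p, conn, rng)
        st = run_dynamics(st, None, 0.3, p, conn, rng)
        acc = MeanRateAccumulator(st.t, st.t + 0.2 + p.dt, p)
        fn = lambda t, g: 2.0 + 4.0 * g.standard_normal(grid.n)
        run_dynamics(st, fn, 0.2, p, conn, rng, [acc])
        prof = acc.profile
        i1 = np.argmin(np.abs(grid.thetas + np.pi / 4))
        i2 = np.argmin(np.abs(grid.thetas - np.pi / 4))
        r1 = prof[i1 - 4:i1 + 5].max()
        r2 = prof[i2 - 4:i2 + 5].max()
        lo, hi = sorted([r1, r2])
        assert hi > 5.0 * max(lo, 1e-9)

    def test_dt_halving_converges(self, default_params):
        # integrator convergence on a smooth (non-pulsatile) drive: group
        # efficacy at stimulus offset moves by <1% when dt is halved
        vals = {}
        for dt in (5e-4, 2.5e-4):
            p = default_params.replace(dt=dt, sigma0=0.0)
            grid = p.grid()
            conn = make_connectivity(p, grid)
            st = NetworkState.resting(p)
            prof = stimulus_profile(StimulusSpec(4.0, 6.0, center=0.0), grid)
            st = run_dynamics(st, lambda t, g: prof, 0.25, p, conn)
            sel = np.abs(wrap_orientation(grid.thetas)) <= np.deg2rad(8)
            vals[dt] = p.j_peak * np.mean(st.u[sel] * st.x[sel])
        assert vals[2.5e-4] == pytest.approx(vals[5e-4], rel=0.01)
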