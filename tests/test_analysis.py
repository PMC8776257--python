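"""Tests for the place-field ramp quantifications."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from btspsim.analysis import (DeltaRamp, asymmetry_ratio, delta_halfwidth,
                              delta_heatmap, delta_vm, plateau_time_base,
                              smooth_ramp)
from btspsim.ramp import RampTrace, circular_distance
from btspsim.rule import single_spike_heatmap
from btspsim.simulate import InductionSimulator
from btspsim.synth import (InductionProtocol, make_synthetic_cell,
                           make_trajectory)

TL = 185.0


class TestSmoothRamp:
    def test_constant_trace_unchanged(self):
        out = smooth_ramp(RampTrace(values=np.full(100, 3.3)))
        np.testing.assert_allclose(out.values, 3.3)

    def test_impulse_wraps_circularly(self):
        v = np.zeros(100)
        v[0] = 1.0
        out = smooth_ramp(RampTrace(values=v)).values
        assert out[99] != 0.0
        assert out[1] == pytest.approx(out[99], abs=1e-12)

    def test_sinusoid_attenuation_matches_filter_gain(self):
        # closed-form frequency response of the symmetric filter window
        window, order, cycles = 21, 3, 4
        x = np.arange(100)
        v = np.cos(2 * np.pi * cycles * x / 100)
        out = smooth_ramp(RampTrace(values=v), window=window,
                          order=order).values
        coeffs = savgol_coeffs(window, order)
        k = np.arange(window) - window // 2
        gain = float(np.sum(coeffs * np.cos(2 * np.pi * cycles * k / 100)))
        np.testing.assert_allclose(out, gain * v, atol=1e-9)

    def test_mean_preserved(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(100) + 5.0
        out = smooth_ramp(RampTrace(values=v)).values
        assert out.mean() == pytest.approx(v.mean(), rel=0.01)


class TestDeltaVm:
    def test_identical_ramps_give_zero(self):
        r = RampTrace(values=np.arange(100.0))
        np.testing.assert_array_equal(delta_vm(r, r).values, 0.0)

    def test_antisymmetric_under_swap(self):
        a = RampTrace(values=np.sin(np.linspace(0, 6, 100)))
        b = RampTrace(values=np.cos(np.linspace(0, 6, 100)))
        np.testing.assert_allclose(delta_vm(a, b).values,
                                   -delta_vm(b, a).values)

    def test_silent_cell_induction_is_non_negative(self, silent_cell):
        delta = delta_vm(silent_cell.initial_ramp, silent_cell.final_ramp)
        assert delta.values.min() > -0.05  # mV, numerical floor

    def test_translocation_is_bidirectional(self, translocation_cell):
        cell = translocation_cell
        delta = delta_vm(cell.initial_ramp, cell.final_ramp)
        old_peak = cell.initial_ramp.peak_bin
        plateau_bin = int(cell.protocol.plateau_position / 1.85)
        assert delta.values[old_peak] < -1.0
        near = [(plateau_bin + k) % 100 for k in range(-8, 9)]
        assert delta.values[near].max() > 1.0


class TestPlateauTimeBase:
    def test_constant_velocity_kinematics(self):
        traj = make_trajectory(n_laps=1)
        proto = InductionProtocol(plateau_position=92.5, n_laps=1)
        onsets = proto.onset_indices(traj)
        tb = plateau_time_base(traj, onsets)
        # a bin d cm downstream is reached d / v seconds after the plateau
        b0 = int(92.5 / 1.85)
        assert tb[b0 + 10] == pytest.approx(10 * 1.85 / 25.0, abs=0.02)
        assert tb[b0 - 10] == pytest.approx(-10 * 1.85 / 25.0, abs=0.02)

    def test_shortest_delay_across_laps(self):
        # two laps at different speeds: each bin keeps the delay of
        # smaller magnitude
        fast = make_trajectory(n_laps=1, velocity=35.0)
        slow = make_trajectory(n_laps=1, velocity=15.0)
        both = _concat_trajectories(fast, slow)
        proto = InductionProtocol(plateau_position=92.5, n_laps=2)
        tb = plateau_time_base(both, proto.onset_indices(both))
        per_lap = [plateau_time_base(t, InductionProtocol(
            plateau_position=92.5, n_laps=1).onset_indices(t))
            for t in (fast, slow)]
        expected = np.where(np.abs(per_lap[0]) <= np.abs(per_lap[1]),
                            per_lap[0], per_lap[1])
        np.testing.assert_allclose(tb, expected, atol=1e-9)

    def test_agrees_with_brute_force_scan(self):
        traj = make_trajectory(n_laps=3, velocity_jitter=0.3, seed=2,
                               pause=(40.0, 1.0))
        proto = InductionProtocol(plateau_position=100.0, n_laps=3)
        onsets = proto.onset_indices(traj)
        tb = plateau_time_base(traj, onsets)
        # oracle: explicit first-traversal scan per lap, then the
        # smallest-magnitude delay across laps
        edges = traj.lap_edges()
        brute = np.full(100, np.nan)
        for onset in onsets:
            lap = int(np.searchsorted(edges, onset, side="right") - 1)
            seen = set()
            for i in range(int(edges[lap]), int(edges[lap + 1])):
                b = min(int(traj.positions[i] / (TL / 100)), 99)
                if b in seen:
                    continue
                seen.add(b)
                d = traj.times[i] - traj.times[onset]
                if np.isnan(brute[b]) or abs(d) < abs(brute[b]):
                    brute[b] = d
        np.testing.assert_allclose(tb, brute, atol=1e-9)


def _concat_trajectories(a, b):
    from btspsim.synth import Trajectory
    return Trajectory(
        times=np.concatenate([a.times, a.times[-1] + a.dt + b.times]),
        positions=np.concatenate([a.positions, b.positions]),
        lap_boundaries=np.concatenate([a.lap_boundaries,
                                       b.lap_boundaries + a.n_steps]),
        stop_mask=np.concatenate([a.stop_mask, b.stop_mask]),
        dt=a.dt, track_length=a.track_length)


class TestHalfwidthAndAsymmetry:
    def _triangle(self, extent_cm=40.0, plateau=92.5):
        x = (np.arange(100) + 0.5) * 1.85
        d = np.abs(circular_distance(x, plateau, TL))
        return DeltaRamp(values=np.clip(1.0 - d / extent_cm, 0.0, None),
                         time_base=circular_distance(x, plateau, TL) / 25.0)

    def test_symmetric_triangle_halfwidth(self):
        hw = delta_halfwidth(self._triangle(40.0), plateau_position=92.5)
        assert hw["extent_cm"] == pytest.approx(40.0, abs=2 * 1.85)
        assert not hw["truncated"]

    def test_never_decaying_profile_is_flagged(self):
        delta = DeltaRamp(values=np.full(100, 2.0) + 0.01 * np.arange(100))
        hw = delta_halfwidth(delta, plateau_position=92.5)
        assert hw["truncated"]
        assert hw["extent_cm"] == pytest.approx(TL / 2.0)

    def test_halfwidth_grows_linearly_with_running_speed(self,
                                                         network_params,
                                                         pop, scaling):
        # the plasticity window is fixed in time, so faster running maps
        # it onto more track
        c, _ = scaling
        widths, speeds = [], [30.0, 35.0, 40.0, 45.0]
        for v in speeds:
            traj = make_trajectory(velocity=v, n_laps=3)
            proto = InductionProtocol(plateau_position=92.5, n_laps=3)
            sim = InductionSimulator(pop, traj, proto, c)
            _, final = sim.run(network_params)
            delta = DeltaRamp(values=final.values,
                              time_base=plateau_time_base(
                                  traj, proto.onset_indices(traj)))
            widths.append(delta_halfwidth(delta, 92.5)["extent_cm"])
        assert all(b >= a for a, b in zip(widths[:-1], widths[1:]))
        assert widths[-1] > widths[0]
        r = np.corrcoef(speeds, widths)[0, 1]
        assert r ** 2 > 0.9

    def test_time_symmetric_profile_has_unit_ratio(self):
        assert asymmetry_ratio(self._triangle()) == pytest.approx(1.0,
                                                                  abs=0.1)

    def test_one_sided_profile_returns_inf(self):
        tri = self._triangle()
        tri.values[tri.time_base > 0] = 0.0
        assert asymmetry_ratio(tri) == np.inf

    def test_longer_eligibility_trace_widens_pre_plateau_side(
            self, network_params, silent_cell):
        # tau_ET > tau_IS: potentiation reaches further back in time
        assert network_params.tau_ET > network_params.tau_IS
        traj = silent_cell.trajectory
        tb = plateau_time_base(
            traj, silent_cell.protocol.onset_indices(traj))
        delta = DeltaRamp(values=silent_cell.final_ramp.values
                          - silent_cell.initial_ramp.values, time_base=tb)
        assert asymmetry_ratio(delta) > 1.0


class TestDeltaHeatmap:
    def test_interpolates_training_points(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-3, 3, size=(25, 2))
        y = np.sin(X[:, 0]) + 0.3 * X[:, 1]
        samples = np.column_stack([X, y])
        dg, vg, surf = delta_heatmap(samples, delay_grid=X[:5, 0],
                                     vm_grid=X[:5, 1])
        from sklearn.gaussian_process import GaussianProcessRegressor
        # check the posterior mean at the training points themselves
        tgrid, vgrid, s2 = delta_heatmap(samples,
                                         delay_grid=np.array([X[3, 0]]),
                                         vm_grid=np.array([X[3, 1]]))
        assert s2[0, 0] == pytest.approx(y[3], abs=1e-3)

    def test_constant_samples_give_constant_surface(self):
        rng = np.random.default_rng(1)
        samples = np.column_stack([rng.uniform(-2, 2, 20),
                                   rng.uniform(0, 5, 20),
                                   np.full(20, 1.7)])
        _, _, surf = delta_heatmap(samples)
        np.testing.assert_allclose(surf, 1.7, atol=1e-6)

    def test_sign_structure_of_pairing_surface(self, spike_params):
        # model-generated (delay, initial weight, dW) samples: change is
        # positive near zero delay at low weight and negative at
        # intermediate delay and high weight
        delays = np.linspace(-4, 4, 17)
        weights = np.linspace(0.5, 4.5, 9)
        dw, _ = single_spike_heatmap(delays, weights, spike_params, dt=0.01)
        D, W = np.meshgrid(delays, weights)
        samples = np.column_stack([D.ravel(), W.ravel(), dw.ravel()])
        dg, vg, surf = delta_heatmap(samples, delay_grid=delays,
                                     vm_grid=weights, n_restarts=1)
        i_lo = 1   # weight 1.0
        i_hi = 7   # weight 4.0
        j0 = 8     # delay 0
        assert surf[i_lo, j0] > 0.5
        j_mid = 12  # delay +2 s
        assert surf[i_hi, j_mid] < -0.1
        # the GP surface reproduces the sign of the direct model output
        assert np.sign(surf[i_hi, j_mid]) == np.sign(dw[7, 12])
        assert np.sign(surf[i_lo, j0]) == np.sign(dw[1, 8])


class TestInitialStateRelations:
    def test_change_tracks_initial_state_final_does_not(
            self, network_params, pop, scaling):
        # population of place cells with fields at varied offsets from the
        # plateau: dVm correlates strongly and negatively with initial Vm,
        # final Vm only weakly
        c, sw = scaling
        traj = make_trajectory(n_laps=3)
        rows = []
        for k, offset in enumerate((-80.0, -55.0, -30.0, 30.0, 55.0)):
            cell = make_synthetic_cell(
                network_params, pop, ((120.0 + offset) % TL, 6.0),
                InductionProtocol(plateau_position=120.0), traj,
                c=c, sigma_w=sw)
            rows.append((cell.initial_ramp.values,
                         cell.final_ramp.values))
        init = np.concatenate([r[0] for r in rows])
        fin = np.concatenate([r[1] for r in rows])
        slope_delta = np.polyfit(init, fin - init, 1)[0]
        slope_final = np.polyfit(init, fin, 1)[0]
        assert slope_delta < -0.5
        assert abs(slope_final) < 0.5 * abs(slope_delta)
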