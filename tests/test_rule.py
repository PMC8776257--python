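"""Unit and property tests for the bidirectional plasticity rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from btspsim.params import RuleParams, is_scaling
from btspsim.rule import (PlateauEvent, SynapseArray, apply_induction,
                          equilibrium_weight, evolve_eligibility,
                          evolve_instructive, kinetic_lap_update,
                          pairing_charge, scaled_sigmoid,
                          single_spike_heatmap, weight_rate)


class TestScaledSigmoid:
    @pytest.mark.parametrize("alpha,beta", [(0.1, 2.0), (0.5, 4.0),
                                            (0.9, 100.0), (0.0, 44.44)])
    def test_edge_constraints(self, alpha, beta):
        assert scaled_sigmoid(0.0, alpha, beta) == pytest.approx(0.0)
        assert scaled_sigmoid(1.0, alpha, beta) == pytest.approx(1.0)

    def test_midpoint_symmetry(self):
        # with the threshold at 0.5 the rescaled logistic is point-symmetric
        assert scaled_sigmoid(0.5, 0.5, 4.0) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.0, 1.0), st.floats(0.05, 0.95),
           st.floats(0.5, 500.0))
    def test_monotone_and_bounded(self, x, alpha, beta):
        lo = scaled_sigmoid(x, alpha, beta)
        hi = scaled_sigmoid(min(x + 0.01, 1.0), alpha, beta)
        assert 0.0 <= lo <= 1.0
        assert hi >= lo - 1e-12

    def test_domain_error(self):
        with pytest.raises(ValueError):
            scaled_sigmoid(1.5, 0.5, 4.0)


class TestSignalDynamics:
    def test_zero_drive_gives_zero_trace(self, spike_params):
        et = evolve_eligibility(np.zeros(500), spike_params, 0.01)
        assert np.all(et == 0.0)

    def test_spike_sets_trace_to_one_then_exponential_decay(self, spike_params):
        # tau_ET = 2500 ms: one e-fold 2.5 s after the spike
        et = evolve_eligibility([1.0], spike_params, 0.001, kind="spikes",
                                n_steps=5000)
        assert et[1000] == pytest.approx(1.0)
        assert et[3500] == pytest.approx(np.exp(-1.0), rel=1e-3)

    def test_sustained_max_rate_saturates_at_one(self, spike_params):
        # lambda_ET = 1/R_max makes a 40 Hz plateau of drive asymptote at 1
        et = evolve_eligibility(np.full(4000, 40.0), spike_params, 0.01)
        assert et[-1] == pytest.approx(1.0, abs=1e-4)
        assert np.all(et <= 1.0)

    def test_negative_rate_rejected(self, spike_params):
        with pytest.raises(ValueError):
            evolve_eligibility(np.array([-1.0]), spike_params, 0.01)

    def test_instructive_peaks_at_exactly_one_at_plateau_offset(
            self, spike_params):
        # 300 ms plateau, tau_IS = 1500 ms; normalization forces IS = 1
        ist = evolve_instructive([PlateauEvent(onset=1.0, duration=0.3)],
                                 spike_params, 0.001, 6000)
        assert ist[1299] == pytest.approx(1.0, abs=1e-9)
        assert ist[2799] == pytest.approx(np.exp(-1.0), rel=1e-3)

    def test_no_plateau_gives_zero_instructive(self, spike_params):
        assert np.all(evolve_instructive([], spike_params, 0.01, 100) == 0.0)

    def test_overlapping_plateaus_saturate(self, spike_params):
        # back-to-back events: the binary gate (and hence IS) stays <= 1
        ist = evolve_instructive([PlateauEvent(0.5, 0.3),
                                  PlateauEvent(0.6, 0.3)],
                                 spike_params, 0.001, 2000)
        assert ist.max() <= 1.0 + 1e-12


class TestWeightRate:
    def test_zero_overlap_zero_rate(self, spike_params):
        for w in (0.0, 1.0, 5.0):
            assert weight_rate(w, 0.0, spike_params) == 0.0

    def test_signs_at_bounds(self, spike_params):
        overlaps = np.linspace(0.0, 1.0, 21)
        assert np.all(weight_rate(spike_params.W_max, overlaps,
                                  spike_params) <= 0.0)
        assert np.all(weight_rate(0.0, overlaps, spike_params) >= 0.0)

    def test_out_of_bounds_weight_rejected(self, spike_params):
        with pytest.raises(ValueError):
            weight_rate(spike_params.W_max + 1.0, 0.5, spike_params)

    def test_high_weight_nonmonotonic_with_max_depression_midrange(
            self, spike_params):
        # the sigmoidal gains with alpha- < alpha+ make high-weight
        # synapses depress most at intermediate overlap
        overlaps = np.linspace(0.0, 1.0, 101)
        rate = weight_rate(4.0, overlaps, spike_params)
        i_min = int(np.argmin(rate))
        assert rate[i_min] < 0.0
        assert 0 < i_min < 100
        assert rate[-1] > rate[i_min]


class TestEquilibriumWeight:
    def test_no_depression_drive_gives_wmax(self, spike_params):
        assert equilibrium_weight(0.3, 0.0, spike_params) == spike_params.W_max

    def test_balanced_drives_give_half_wmax(self, spike_params):
        dq_dep = spike_params.k_pot * 0.2 / spike_params.k_dep
        assert equilibrium_weight(0.2, dq_dep, spike_params) == pytest.approx(
            spike_params.W_max / 2.0)

    def test_worked_example(self, spike_params):
        # k+ = 1.7, k- = 0.204, Wmax = 5, dQ+ = 0.1, dQ- = 0.5
        assert equilibrium_weight(0.1, 0.5, spike_params) == pytest.approx(
            3.125)

    def test_both_zero_is_undefined(self, spike_params):
        with pytest.raises(ZeroDivisionError):
            equilibrium_weight(0.0, 0.0, spike_params)

    def test_rate_vanishes_at_equilibrium(self, spike_params):
        # integrating the weight rate at Weq over the pairing that defined
        # the drives yields zero net change
        dq_pot, dq_dep = pairing_charge(0.5, spike_params, dt=0.002)
        weq = equilibrium_weight(dq_pot, dq_dep, spike_params)
        net = ((spike_params.W_max - weq) * spike_params.k_pot * dq_pot
               - weq * spike_params.k_dep * dq_dep)
        assert net == pytest.approx(0.0, abs=1e-10)


class TestInduction:
    def test_isolated_activation_leaves_weight_unchanged(self, spike_params):
        # spike > 6 tau away from the plateau: no overlap, no change
        T = 60000
        syn = SynapseArray(weights=np.array([2.0]))
        out = apply_induction(syn, [[1.0]], [PlateauEvent(onset=40.0)],
                              spike_params, dt=0.001, drive_kind="spikes",
                              n_steps=T)
        assert out.weights[0] == pytest.approx(2.0, abs=1e-6)

    def test_repeated_pairings_converge_monotonically_to_weq(
            self, spike_params):
        dq_pot, dq_dep = pairing_charge(0.5, spike_params, dt=0.002)
        weq = equilibrium_weight(dq_pot, dq_dep, spike_params)
        w = np.array([0.2])
        gaps = []
        for _ in range(6):
            w = kinetic_lap_update(w, dq_pot, dq_dep, spike_params)
            gaps.append(abs(w[0] - weq))
        assert all(b < a for a, b in zip(gaps[:-1], gaps[1:]))

    def test_bounds_invariants_over_random_simulations(self, spike_params):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n, T = 8, 4000
            drives = rng.uniform(0, 40, size=(n, T))
            plateaus = [PlateauEvent(onset=float(rng.uniform(0.5, 2.5)))]
            syn = SynapseArray(weights=rng.uniform(0, spike_params.W_max, n))
            out = apply_induction(syn, drives, plateaus, spike_params,
                                  dt=0.001, mode="per_lap")
            assert np.all(out.weights >= 0.0)
            assert np.all(out.weights <= spike_params.W_max)
            assert np.all(out.eligibility >= 0.0)
            assert np.all(out.eligibility <= 1.0)
            assert 0.0 <= out.instructive <= 1.0
            # two-state occupancy conservation
            occ = out.weights / spike_params.W_max
            assert np.all((0.0 <= occ) & (occ <= 1.0))


class TestSingleSpikeHeatmap:
    def test_baseline_weights_only_potentiate(self, spike_params):
        # synapses at or below the baseline weight of 1 undergo only
        # potentiation at every pairing delay
        delays = np.arange(-6.0, 6.01, 0.5)
        dw, _ = single_spike_heatmap(delays, np.array([0.5, 1.0]),
                                     spike_params, dt=0.005)
        assert dw.min() >= 0.0

    def test_far_delays_produce_no_change(self, spike_params):
        dw, _ = single_spike_heatmap(np.array([-30.0, 30.0]),
                                     np.array([0.5, 3.0]), spike_params,
                                     dt=0.01)
        # the depression gain has a soft tail near zero overlap, so the
        # change is not exactly zero; bound it at 0.1% of W_max
        assert np.abs(dw).max() < 1e-3 * spike_params.W_max

    def test_sigmoid_equilibrium_varies_with_delay_linear_does_not(
            self, spike_params):
        delays = np.arange(-4.0, 4.01, 1.0)
        _, weq_sig = single_spike_heatmap(delays, np.array([1.0]),
                                          spike_params, dt=0.005)
        _, weq_lin = single_spike_heatmap(delays, np.array([1.0]),
                                          spike_params, dt=0.005,
                                          variant="linear")
        assert np.ptp(weq_sig) > 0.5
        assert np.ptp(weq_lin) < 1e-9
        # the linear equilibrium is the drive-independent kinetic balance
        expected = spike_params.W_max * spike_params.k_pot / (
            spike_params.k_pot + spike_params.k_dep)
        assert weq_lin[0] == pytest.approx(expected)

    def test_short_timescale_variant_cannot_span_seconds(self):
        # tau = 100 ms signals: no plasticity at delays beyond +/- 1 s
        short = RuleParams(tau_ET=100.0, tau_IS=100.0, alpha_pot=0.5,
                           beta_pot=4.0, alpha_dep=0.01, beta_dep=44.44,
                           k_pot=1.7, k_dep=0.204, W_max=5.0)
        dw, _ = single_spike_heatmap(np.array([-3.0, -1.5, 1.5, 3.0]),
                                     np.array([0.5, 2.0, 4.0]), short,
                                     dt=0.005)
        assert np.abs(dw).max() < 0.01 * short.W_max


def test_is_scaling_matches_fine_integration():
    # lambda_IS solves the filter equation exactly: verify by integration
    lam = is_scaling(0.3, 1500.0)
    dt, tau = 1e-4, 1.5
    y = 0.0
    for _ in range(3000):
        y += dt / tau * (-y + lam)
    assert y == pytest.approx(1.0, abs=1e-3)
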