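"""Forward simulation of a plasticity induction on a trajectory.

Couples the input population and ramp model to the BTSP rule: input rates
are read off the trajectory, filtered into eligibility traces, plateaus
are triggered at position crossings and filtered into the instructive
signal, and the per-lap weight update of the rule is applied.  An
``InductionSimulator`` caches everything that does not depend on the rule
parameters (rates, plateau gate, lap edges) so that a stochastic parameter
search can evaluate thousands of configurations cheaply.
"""

from __future__ import annotations

import numpy as np

from .params import RuleParams
from .ramp import (InputPopulation, RampTrace, background_level,
                   ramp_from_weights, rates_from_trajectory)
from .rule import (GainVariant, exp_filter, gain_functions,
                   kinetic_lap_update)
from .synth import InductionProtocol, Trajectory

__all__ = ["InductionSimulator", "simulate_induction", "background_for"]

_bg_cache: dict[tuple, float] = {}


def background_for(pop: InputPopulation, c: float) -> float:
    """Memoised background depolarization V_b for a population and scale."""
    key = (id(pop), round(c, 12))
    if key not in _bg_cache:
        _bg_cache[key] = background_level(pop, c)
    return _bg_cache[key]


class InductionSimulator:
    """Reusable forward model for one (population, trajectory, protocol).

    Parameters-independent quantities are precomputed once; ``run`` then
    evaluates the rule for arbitrary parameter sets.
    """

    def __init__(self, pop: InputPopulation, traj: Trajectory,
                 protocol: InductionProtocol, c: float,
                 Vb: float | None = None):
        self.pop = pop
        self.traj = traj
        self.protocol = protocol
        self.c = c
        self.Vb = background_for(pop, c) if Vb is None else Vb
        self.dt = traj.dt
        self.rates = rates_from_trajectory(pop, traj)
        self.lap_edges = traj.lap_edges()
        onsets = protocol.onset_indices(traj)
        gate = np.zeros(traj.n_steps)
        n_plat = int(round(protocol.plateau_duration / self.dt))
        for i0 in onsets:
            gate[i0:i0 + n_plat] = 1.0
        self.gate = gate
        self.onset_indices = onsets
        from .ramp import spatial_rate_matrix
        self._A = spatial_rate_matrix(pop)

    def run(self, params: RuleParams, initial_weights=None,
            mode: str = "per_lap", variant: GainVariant = "sigmoid",
            return_traces: bool = False, record_lap_weights: bool = False):
        """Simulate the induction; returns (final_weights, final_ramp).

        With ``record_lap_weights`` the weight vector after each lap is
        collected on ``self.lap_weights``.
        """
        W = (np.ones(self.pop.n_inputs) if initial_weights is None
             else np.asarray(initial_weights, dtype=float).copy())
        dt = self.dt
        et = exp_filter(self.rates, params.tau_ET_s, dt, params.lambda_ET)
        np.clip(et, 0.0, 1.0, out=et)
        is_trace = exp_filter(self.gate, params.tau_IS_s, dt,
                              params.lambda_IS)
        np.clip(is_trace, 0.0, 1.0, out=is_trace)
        q_pot, q_dep = gain_functions(params, variant, checked=False)
        self.lap_weights: list[np.ndarray] = []
        if mode == "per_lap":
            for i0, i1 in zip(self.lap_edges[:-1], self.lap_edges[1:]):
                # skip laps with negligible instructive signal
                if is_trace[i0:i1].max(initial=0.0) >= 1e-9:
                    overlap = et[:, i0:i1] * is_trace[i0:i1]
                    dq_pot = q_pot(overlap).sum(axis=1) * dt
                    dq_dep = q_dep(overlap).sum(axis=1) * dt
                    W = kinetic_lap_update(W, dq_pot, dq_dep, params)
                if record_lap_weights:
                    self.lap_weights.append(W.copy())
        elif mode == "continuous":
            for n in range(self.traj.n_steps):
                if is_trace[n] < 1e-12:
                    continue
                overlap = et[:, n] * is_trace[n]
                W += dt * ((params.W_max - W) * params.k_pot
                           * q_pot(overlap)
                           - W * params.k_dep * q_dep(overlap))
                np.clip(W, 0.0, params.W_max, out=W)
        else:
            raise ValueError(f"unknown mode: {mode!r}")
        ramp = RampTrace(values=self.c * (self._A @ W) - self.Vb,
                         track_length=self.pop.track_length)
        if return_traces:
            return W, ramp, et, is_trace
        return W, ramp


def simulate_induction(initial_weights, params: RuleParams,
                       pop: InputPopulation, traj: Trajectory,
                       protocol: InductionProtocol, c: float,
                       Vb: float | None = None, mode: str = "per_lap",
                       variant: GainVariant = "sigmoid"):
    """One-shot convenience wrapper around :class:`InductionSimulator`."""
    sim = InductionSimulator(pop, traj, protocol, c, Vb)
    return sim.run(params, initial_weights, mode=mode, variant=variant)
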