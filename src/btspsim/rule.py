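"""The weight-dependent bidirectional BTSP learning rule.

Each synapse carries a local eligibility trace (ET) activated by
presynaptic firing, and all synapses share a global instructive signal
(IS) activated by dendritic plateau potentials.  Both decay exponentially
with seconds-long time constants.  The temporal overlap ET*IS drives
saturable potentiation and depression processes through sigmoidal gain
functions q+ and q-, and the net weight change follows a two-state kinetic
scheme in which finite synaptic resources move between an inactive and an
active state:

    dW/dt = (W_max - W) * k+ * q+(ET*IS) - W * k- * q-(ET*IS)

so the direction of plasticity depends on the current weight: low-weight
synapses potentiate, high-weight synapses can depress, and every pairing
timing defines a stable equilibrium weight where the two processes balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.signal import lfilter

from .params import RuleParams

GainVariant = Literal["sigmoid", "linear"]

__all__ = [
    "PlateauEvent",
    "SynapseArray",
    "scaled_sigmoid",
    "exp_filter",
    "evolve_eligibility",
    "evolve_instructive",
    "gain_functions",
    "weight_rate",
    "apply_induction",
    "equilibrium_weight",
    "single_spike_heatmap",
    "pairing_charge",
]


@dataclass
class PlateauEvent:
    """A dendritic plateau potential: onset time and duration, seconds."""

    onset: float
    duration: float = 0.3

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("plateau duration must be > 0")


@dataclass
class SynapseArray:
    """Per-input weights and eligibility traces plus the shared IS scalar."""

    weights: np.ndarray
    eligibility: np.ndarray = field(default=None)  # type: ignore[assignment]
    instructive: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.eligibility is None:
            self.eligibility = np.zeros_like(self.weights)

    @property
    def n_inputs(self) -> int:
        return self.weights.size


def scaled_sigmoid(x, alpha: float, beta: float):
    """Sigmoid rescaled to satisfy the edge constraints s(0)=0, s(1)=1.

    s(x) = (sh(x) - sh(0)) / (sh(1) - sh(0)) with sh(x) = 1/(1+exp(-beta*(x-alpha))).
    Monotonically increasing on the domain [0, 1].
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > 1.0 + 1e-12):
        raise ValueError("signal overlap x must lie in [0, 1]")
    x = np.clip(x, 0.0, 1.0)
    # evaluate logistic in a numerically stable way (beta can be ~1e3)
    s0 = _logistic(beta * (0.0 - alpha))
    s1 = _logistic(beta * (1.0 - alpha))
    out = (_logistic(beta * (x - alpha)) - s0) / (s1 - s0)
    return out if out.ndim else float(out)


def _logistic(z):
    # overflow-safe for arbitrary z without boolean indexing
    z = np.asarray(z, dtype=float)
    e = np.exp(-np.abs(z))
    return np.where(z >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def exp_filter(drive: np.ndarray, tau_s: float, dt: float, lam: float) -> np.ndarray:
    """Integrate tau*dy/dt = -y + lam*drive with the exponential-Euler update.

    The drive is held constant over each step, so the update
    y <- y*a + lam*drive*(1-a), a = exp(-dt/tau), is exact for piecewise
    constant input.  ``out[n]`` is the value at the END of step n.
    Supports 1-D (time,) or 2-D (channels, time) drive.
    """
    drive = np.asarray(drive, dtype=float)
    a = np.exp(-dt / tau_s)
    b = lam * (1.0 - a)
    # first-order IIR: y[n] = a*y[n-1] + b*x[n]
    return lfilter([b], [1.0, -a], drive, axis=-1)


def evolve_eligibility(presynaptic_drive, params: RuleParams, dt: float,
                       kind: Literal["rate", "spikes"] = "rate",
                       n_steps: int | None = None) -> np.ndarray:
    """Eligibility-trace time course for one input (or many).

    Rate inputs are low-pass filtered with scaling lambda_ET = 1/R_max so a
    sustained drive at R_max asymptotes at 1.  Discrete spikes set the trace
    to 1 (saturating, not additive), after which it decays with tau_ET.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if kind == "rate":
        drive = np.asarray(presynaptic_drive, dtype=float)
        if np.any(drive < 0):
            raise ValueError("presynaptic rates must be non-negative")
        et = exp_filter(drive, params.tau_ET_s, dt, params.lambda_ET)
        return np.clip(et, 0.0, 1.0)
    if kind == "spikes":
        if n_steps is None:
            raise ValueError("n_steps is required for spike inputs")
        spike_steps = sorted(int(round(t / dt)) for t in presynaptic_drive)
        et = np.zeros(n_steps)
        a = np.exp(-dt / params.tau_ET_s)
        y = 0.0
        idx = 0
        for n in range(n_steps):
            y *= a
            if idx < len(spike_steps) and spike_steps[idx] == n:
                y = 1.0  # saturating set, never exceeds 1
                idx += 1
            et[n] = y
        return et
    raise ValueError(f"unknown drive kind: {kind!r}")


def plateau_gate(plateaus: Iterable[PlateauEvent], dt: float,
                 n_steps: int) -> np.ndarray:
    """Binary plateau indicator P(t); overlapping events saturate at 1."""
    gate = np.zeros(n_steps)
    for ev in plateaus:
        i0 = int(round(ev.onset / dt))
        i1 = int(round((ev.onset + ev.duration) / dt))
        if i0 >= n_steps:
            raise ValueError("plateau event lies outside the time base")
        gate[max(i0, 0):min(i1, n_steps)] = 1.0
    return gate


def evolve_instructive(plateaus: Iterable[PlateauEvent], params: RuleParams,
                       dt: float, n_steps: int) -> np.ndarray:
    """Instructive-signal time course shared by all synapses.

    The gate is scaled by lambda_IS = 1/(1 - exp(-d/tau_IS)) (d = reference
    plateau duration) so IS peaks at exactly 1 at plateau offset, then
    decays exponentially with tau_IS.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    gate = plateau_gate(plateaus, dt, n_steps)
    is_trace = exp_filter(gate, params.tau_IS_s, dt, params.lambda_IS)
    return np.clip(is_trace, 0.0, 1.0)


def _unchecked_sigmoid(alpha: float, beta: float):
    """Gain callable without domain checks, for pre-clipped inner loops."""
    s0 = float(_logistic(beta * (0.0 - alpha)))
    s1 = float(_logistic(beta * (1.0 - alpha)))
    inv = 1.0 / (s1 - s0)

    def q(x):
        return (_logistic(beta * (x - alpha)) - s0) * inv

    return q


def gain_functions(params: RuleParams, variant: GainVariant = "sigmoid",
                   checked: bool = True):
    """Return the potentiation/depression gains (q+, q-) as callables.

    ``checked=False`` skips the [0, 1] domain validation; used internally
    where the signal overlap is clipped by construction.
    """
    if variant == "sigmoid":
        if not checked:
            return (_unchecked_sigmoid(params.alpha_pot, params.beta_pot),
                    _unchecked_sigmoid(params.alpha_dep, params.beta_dep))
        return (lambda x: scaled_sigmoid(x, params.alpha_pot, params.beta_pot),
                lambda x: scaled_sigmoid(x, params.alpha_dep, params.beta_dep))
    if variant == "linear":
        identity = lambda x: np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
        return identity, identity
    raise ValueError(f"unknown gain variant: {variant!r}")


def weight_rate(W, overlap, params: RuleParams,
                variant: GainVariant = "sigmoid"):
    """Net rate of weight change dW/dt (1/s) at signal overlap ET*IS."""
    W = np.asarray(W, dtype=float)
    if np.any(W < -1e-12) or np.any(W > params.W_max + 1e-12):
        raise ValueError("weight outside [0, W_max]")
    q_pot, q_dep = gain_functions(params, variant)
    rate = ((params.W_max - W) * params.k_pot * q_pot(overlap)
            - W * params.k_dep * q_dep(overlap))
    return rate if np.ndim(rate) else float(rate)


def equilibrium_weight(dQ_pot, dQ_dep, params: RuleParams):
    """Weight at which integrated potentiation and depression balance.

    Weq = W_max * k+ dQ+ / (k+ dQ+ + k- dQ-); undefined when both
    integrated drives vanish.
    """
    dQ_pot = np.asarray(dQ_pot, dtype=float)
    dQ_dep = np.asarray(dQ_dep, dtype=float)
    if np.any(dQ_pot < 0) or np.any(dQ_dep < 0):
        raise ValueError("integrated drives must be >= 0")
    num = params.k_pot * dQ_pot
    den = num + params.k_dep * dQ_dep
    if np.any(den == 0):
        raise ZeroDivisionError(
            "equilibrium weight undefined: both integrated drives are zero")
    out = params.W_max * num / den
    return out if out.ndim else float(out)


def integrated_gains(et: np.ndarray, is_trace: np.ndarray,
                     params: RuleParams, dt: float,
                     variant: GainVariant = "sigmoid"):
    """Integrate q+(ET*IS) and q-(ET*IS) over time -> (dQ+, dQ-).

    ``et`` may be (time,) or (inputs, time); the IS trace is broadcast.
    """
    overlap = et * is_trace
    q_pot, q_dep = gain_functions(params, variant)
    return (q_pot(overlap).sum(axis=-1) * dt,
            q_dep(overlap).sum(axis=-1) * dt)


def apply_induction(synapses: SynapseArray, presynaptic_drives, plateaus,
                    params: RuleParams, dt: float = 0.01,
                    mode: Literal["per_lap", "continuous"] = "per_lap",
                    lap_edges: Sequence[int] | None = None,
                    variant: GainVariant = "sigmoid",
                    drive_kind: Literal["rate", "spikes"] = "rate",
                    n_steps: int | None = None) -> SynapseArray:
    """Run one plasticity induction and return the updated synapse array.

    ``per_lap`` holds weights constant within each lap (segment between
    consecutive ``lap_edges``) and applies the integrated weight change once
    at the lap end; ``continuous`` applies the update every time step.
    Weights are clamped to [0, W_max] after each update (finite synaptic
    resources).
    """
    if drive_kind == "rate":
        drives = np.atleast_2d(np.asarray(presynaptic_drives, dtype=float))
        T = drives.shape[1]
        et = evolve_eligibility(drives, params, dt, kind="rate")
    else:
        if n_steps is None:
            raise ValueError("n_steps required for spike drives")
        T = n_steps
        et = np.vstack([
            evolve_eligibility(sp, params, dt, kind="spikes", n_steps=T)
            for sp in presynaptic_drives])
    if et.shape[0] != synapses.n_inputs:
        raise ValueError("number of drive traces does not match synapses")
    is_trace = evolve_instructive(plateaus, params, dt, T)

    W = synapses.weights.astype(float).copy()
    if mode == "per_lap":
        edges = list(lap_edges) if lap_edges is not None else [0, T]
        if edges[0] != 0:
            edges = [0] + edges
        if edges[-1] != T:
            edges = edges + [T]
        for i0, i1 in zip(edges[:-1], edges[1:]):
            dq_pot, dq_dep = integrated_gains(
                et[:, i0:i1], is_trace[i0:i1], params, dt, variant)
            W = kinetic_lap_update(W, dq_pot, dq_dep, params)
    elif mode == "continuous":
        q_pot, q_dep = gain_functions(params, variant)
        for n in range(T):
            overlap = et[:, n] * is_trace[n]
            W += dt * ((params.W_max - W) * params.k_pot * q_pot(overlap)
                       - W * params.k_dep * q_dep(overlap))
            np.clip(W, 0.0, params.W_max, out=W)
    else:
        raise ValueError(f"unknown update mode: {mode!r}")
    return SynapseArray(weights=W, eligibility=et[:, -1],
                        instructive=float(is_trace[-1]))


def kinetic_lap_update(W, dq_pot, dq_dep, params: RuleParams):
    """Exact two-state kinetic update for one lap with frozen signal path.

    Holding the overlap path (hence the integrated drives dQ+/dQ-) fixed,
    the kinetic scheme dW/dt = Wmax k+ q+ - W (k+ q+ + k- q-) is linear in
    W and integrates exactly to

        W' = Weq + (W - Weq) * exp(-(k+ dQ+ + k- dQ-)),

    with Weq the per-lap equilibrium weight.  This is unconditionally
    stable, converges monotonically toward Weq over repeated identical
    pairings, and reduces to the explicit per-lap update
    W += (Wmax - W) k+ dQ+ - W k- dQ- when the integrated drives are
    small (the regime of the rate-based inductions).
    """
    W = np.asarray(W, dtype=float)
    a = params.k_pot * np.asarray(dq_pot, dtype=float)
    b = params.k_dep * np.asarray(dq_dep, dtype=float)
    s = a + b
    decay = np.exp(-s)
    with np.errstate(invalid="ignore", divide="ignore"):
        weq = np.where(s > 0, params.W_max * a / np.where(s > 0, s, 1.0),
                       W)
    out = weq + (W - weq) * decay
    return np.clip(out, 0.0, params.W_max)


def pairing_charge(delay: float, params: RuleParams, dt: float = 0.001,
                   plateau_duration: float = 0.3,
                   variant: GainVariant = "sigmoid"):
    """Integrated gains (dQ+, dQ-) for one spike/plateau pairing.

    ``delay`` is spike time minus plateau onset, seconds.  The pairing is
    embedded in a window long enough for both signals to decay to ~0.
    """
    span = 7.0 * max(params.tau_ET_s, params.tau_IS_s)
    t0 = span  # place the earlier event at t0
    t_p = t0 + max(0.0, -delay)
    t_s = t0 + max(0.0, delay)
    T = int(round((max(t_p + plateau_duration, t_s) + span) / dt))
    et = evolve_eligibility([t_s], params, dt, kind="spikes", n_steps=T)
    is_trace = evolve_instructive(
        [PlateauEvent(onset=t_p, duration=plateau_duration)], params, dt, T)
    return integrated_gains(et, is_trace, params, dt, variant)


def single_spike_heatmap(spike_delays, initial_weights, params: RuleParams,
                         n_pairings: int = 1, dt: float = 0.01,
                         plateau_duration: float = 0.3,
                         variant: GainVariant = "sigmoid"):
    """Net weight change over a grid of pairing delays and initial weights.

    For each delay (spike time minus plateau onset) the integrated
    potentiation/depression drives are computed once; the per-pairing
    update (weights frozen within a pairing) is then iterated
    ``n_pairings`` times from each initial weight.

    Returns
    -------
    delta_w : ndarray, shape (n_weights, n_delays)
    weq : ndarray, shape (n_delays,)
        Equilibrium weight at each delay (the zero-change contour).
    """
    spike_delays = np.asarray(spike_delays, dtype=float)
    initial_weights = np.asarray(initial_weights, dtype=float)
    n_d = spike_delays.size
    dq_pot = np.empty(n_d)
    dq_dep = np.empty(n_d)
    for j, delay in enumerate(spike_delays):
        dq_pot[j], dq_dep[j] = pairing_charge(
            float(delay), params, dt, plateau_duration, variant)
    weq = equilibrium_weight(np.maximum(dq_pot, 1e-300),
                             dq_dep, params)
    W = np.tile(initial_weights[:, None], (1, n_d)).astype(float)
    for _ in range(n_pairings):
        W = kinetic_lap_update(W, dq_pot[None, :], dq_dep[None, :], params)
    return W - initial_weights[:, None], weq
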