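"""Goal-directed spatial learning in a CA1 population with BTSP.

500 CA1 rate neurons each receive the 200 spatially tuned CA3 inputs of
the ramp model.  Their output rates (rectified ramp depolarization above a
2 mV threshold) drive a single feedback-inhibition term R_INH, which
negatively regulates the probability that any neuron emits a dendritic
plateau potential.  Plateaus trigger the BTSP weight update, so population
activity is self-limiting: fields accumulate until R_INH reaches a target
level and plateau emission shuts off.  A transient goal signal elevates
both the plateau-probability ceiling and the target activity inside a
500 ms window after the animal crosses the goal location, producing an
over-representation of place fields near the goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import RuleParams
from .ramp import (InputPopulation, bin_centers, calibrate_scaling,
                   make_input_population, N_BINS)
from .rule import (exp_filter, gain_functions, kinetic_lap_update,
                   scaled_sigmoid)
from .simulate import background_for
from .synth import asymmetric_field_ramp, make_trajectory

__all__ = [
    "NetworkConfig",
    "SessionRecords",
    "ca1_output_rate",
    "inhibition_level",
    "plateau_probability",
    "reference_lambda",
    "run_session",
    "summarize_population",
]


@dataclass
class NetworkConfig:
    """Constants of the goal-directed network simulation."""

    n_ca1: int = 500
    n_ca3: int = 200
    track_length: float = 185.0
    velocity: float = 25.0            # cm/s
    dt: float = 0.01                  # s
    p_basal: float = 0.0075           # plateau rate per s of running
    alpha_basal: float = 0.5          # target normalized population activity
    beta_basal: float = 8.0           # slope of the descending sigmoid
    p_goal_max: float = 0.035         # per s, inside the goal window
    alpha_goal: float = 1.0
    beta_goal: float = 8.0
    plateau_duration: float = 0.3     # s
    refractory: float = 0.5           # s
    rate_threshold: float = 2.0       # mV subtracted before rectification
    rate_gain: float = 1.0 / 6.0      # normalized rate per mV above threshold
    goal_location: float = 90.0       # cm
    goal_window: float = 0.5          # s of elevated plateau probability
    field_amp_mv: float = 8.0         # reference single-field amplitude
    per_step_literal: bool = False    # if True, use the per-s rate as the
    #                                   per-step probability directly

    def __post_init__(self) -> None:
        if self.alpha_goal <= self.alpha_basal:
            raise ValueError("alpha_goal must exceed alpha_basal")


def ca1_output_rate(ramp_mv, config: NetworkConfig):
    """Normalized CA1 output rate: g * max(0, V - threshold).

    The gain is anchored so the calibrated 8 mV place field peaks at a
    normalized rate of 1.
    """
    v = np.asarray(ramp_mv, dtype=float)
    out = config.rate_gain * np.clip(v - config.rate_threshold, 0.0, None)
    return out if out.ndim else float(out)


def inhibition_level(rates, lambda_norm: float):
    """Feedback inhibition R_INH = lambda * sum_k R_CA1_k."""
    return lambda_norm * float(np.sum(rates))


def reference_lambda(config: NetworkConfig) -> float:
    """Normalization so R_INH = 1 in the uniform-tiling reference state.

    The reference configuration places one calibrated place field (8 mV,
    asymmetric target shape) on every CA1 neuron with peaks uniformly
    tiling the track; lambda is the reciprocal of the mean summed output
    rate across positions.
    """
    peaks = np.arange(config.n_ca1) * config.track_length / config.n_ca1
    total = np.zeros(N_BINS)
    for p in peaks:
        v = asymmetric_field_ramp(p, peak_mv=config.field_amp_mv,
                                  track_length=config.track_length).values
        total += ca1_output_rate(v, config)
    return 1.0 / float(total.mean())


def plateau_probability(R_INH: float, in_goal: bool,
                        config: NetworkConfig) -> float:
    """Per-time-step plateau probability given the inhibition level.

    A descending sigmoid anchored at the maximum rate at R_INH = 0 that
    reaches 0 at the target activity alpha; the per-second rate is
    converted to a per-step probability as rate * dt.
    """
    if R_INH < 0:
        raise ValueError("R_INH must be >= 0")
    alpha = config.alpha_goal if in_goal else config.alpha_basal
    p_max = config.p_goal_max if in_goal else config.p_basal
    if R_INH >= alpha:
        return 0.0
    beta = config.beta_goal if in_goal else config.beta_basal
    rate = p_max * scaled_sigmoid(1.0 - R_INH / alpha, 0.5, beta)
    return float(rate if config.per_step_literal else rate * config.dt)


def _probability_curve(R_INH: np.ndarray, in_goal: np.ndarray,
                       config: NetworkConfig) -> np.ndarray:
    """Vectorized per-step plateau probability over a lap."""
    out = np.zeros(R_INH.size)
    for goal_flag in (False, True):
        m = in_goal == goal_flag
        if not m.any():
            continue
        alpha = config.alpha_goal if goal_flag else config.alpha_basal
        p_max = config.p_goal_max if goal_flag else config.p_basal
        sub = np.clip(1.0 - R_INH[m] / alpha, 0.0, 1.0)
        beta = config.beta_goal if goal_flag else config.beta_basal
        rate = p_max * np.asarray(scaled_sigmoid(sub, 0.5, beta))
        rate[R_INH[m] >= alpha] = 0.0
        out[m] = rate if config.per_step_literal else rate * config.dt
    return out


@dataclass
class SessionRecords:
    """Lap-by-lap records of a network session."""

    config: NetworkConfig
    phases: list[tuple[int, bool]]
    lap_goal_on: np.ndarray            # (n_laps,) bool
    peak_amp: np.ndarray               # (n_laps, n_ca1) ramp peak, mV
    peak_bin: np.ndarray               # (n_laps, n_ca1) int
    pop_rate_map: np.ndarray           # (n_laps, N_BINS) summed output rate
    r_inh_mean: np.ndarray             # (n_laps,)
    plateaus_per_lap: np.ndarray       # (n_laps,)
    plateau_events: list[tuple[int, float, int]]  # (neuron, onset time, lap)
    final_weights: np.ndarray          # (n_ca1, n_ca3)
    final_ramps: np.ndarray            # (n_ca1, N_BINS)

    @property
    def n_laps(self) -> int:
        return self.peak_amp.shape[0]


def run_session(config: NetworkConfig,
                phases: Sequence[tuple[int, bool]] = ((10, False),
                                                      (10, True),
                                                      (5, False)),
                rule_params: RuleParams | None = None,
                seed: int = 0) -> SessionRecords:
    """Run a multi-phase exploration session and return lap-by-lap records.

    Each phase is (n_laps, goal_on).  Weights follow the per-lap BTSP
    update; plateau emission is drawn per 10 ms step from seeded biased
    coin flips, honouring the 300 ms plateau duration and 500 ms
    refractory period.  Deterministic for a fixed seed.
    """
    if rule_params is None:
        rule_params = network_rule_params()
    rng = np.random.default_rng(seed)
    pop = make_input_population(track_length=config.track_length,
                                n_inputs=config.n_ca3)
    c, _sigma_w = calibrate_scaling(pop)
    Vb = background_for(pop, c)
    lam = reference_lambda(config)

    lap_traj = make_trajectory(track_length=config.track_length,
                               velocity=config.velocity, n_laps=1,
                               dt=config.dt)
    n_step = lap_traj.n_steps
    rates_lap = pop.rates_at(lap_traj.positions)          # (n_ca3, n_step)
    pos_bin = np.minimum((lap_traj.positions
                          / (config.track_length / N_BINS)).astype(int),
                         N_BINS - 1)
    from .ramp import spatial_rate_matrix
    A = spatial_rate_matrix(pop)                          # (N_BINS, n_ca3)

    # eligibility traces are shared by all neurons (same presynaptic drive);
    # use the lap-periodic steady state
    et = exp_filter(np.tile(rates_lap, 3), rule_params.tau_ET_s,
                    config.dt, rule_params.lambda_ET)[:, -n_step:]
    np.clip(et, 0.0, 1.0, out=et)

    goal_cross = int(np.searchsorted(lap_traj.positions,
                                     config.goal_location))
    n_goal = int(round(config.goal_window / config.dt))
    n_plat = int(round(config.plateau_duration / config.dt))
    n_ref = int(round(config.refractory / config.dt))

    q_pot, q_dep = gain_functions(rule_params)
    a_is = np.exp(-config.dt / rule_params.tau_IS_s)
    b_is = rule_params.lambda_IS * (1.0 - a_is)

    n = config.n_ca1
    W = np.ones((n, config.n_ca3))
    IS = np.zeros(n)
    plateau_left = np.zeros(n, dtype=int)   # steps remaining in plateau
    refract_left = np.zeros(n, dtype=int)

    lap_goal = np.concatenate([np.full(nl, bool(g))
                               for nl, g in phases]).astype(bool)
    n_laps = lap_goal.size
    peak_amp = np.zeros((n_laps, n))
    peak_bin = np.zeros((n_laps, n), dtype=int)
    pop_map = np.zeros((n_laps, N_BINS))
    r_inh_mean = np.zeros(n_laps)
    plateaus_per_lap = np.zeros(n_laps, dtype=int)
    events: list[tuple[int, float, int]] = []

    for lap in range(n_laps):
        # ramps and rates for this lap (weights frozen within the lap)
        V = c * (W @ rates_lap) - Vb                      # (n, n_step)
        R = ca1_output_rate(V, config)
        R_INH = lam * R.sum(axis=0)                       # (n_step,)
        r_inh_mean[lap] = R_INH.mean()

        in_goal = np.zeros(n_step, dtype=bool)
        if lap_goal[lap]:
            in_goal[goal_cross:goal_cross + n_goal] = True
        p_step = _probability_curve(R_INH, in_goal, config)

        gate = np.zeros((n, n_step))
        is_lap = np.empty((n, n_step))
        for t in range(n_step):
            eligible = (plateau_left == 0) & (refract_left == 0)
            if p_step[t] > 0 and eligible.any():
                fire = eligible & (rng.random(n) < p_step[t])
                idx = np.nonzero(fire)[0]
                if idx.size:
                    plateau_left[idx] = n_plat
                    plateaus_per_lap[lap] += idx.size
                    t_abs = (lap * n_step + t) * config.dt
                    events.extend((int(k), t_abs, lap) for k in idx)
            active = plateau_left > 0
            gate[active, t] = 1.0
            ending = active & (plateau_left == 1)
            plateau_left[active] -= 1
            refract_left[refract_left > 0] -= 1
            refract_left[ending] = n_ref
            IS = IS * a_is + b_is * gate[:, t]
            is_lap[:, t] = IS
        np.clip(is_lap, 0.0, 1.0, out=is_lap)

        # per-lap BTSP weight update for neurons with instructive signal
        touched = np.nonzero(is_lap.max(axis=1) > 1e-9)[0]
        for k in touched:
            overlap = et * is_lap[k]                      # (n_ca3, n_step)
            dq_pot = q_pot(overlap).sum(axis=1) * config.dt
            dq_dep = q_dep(overlap).sum(axis=1) * config.dt
            W[k] = kinetic_lap_update(W[k], dq_pot, dq_dep, rule_params)

        # record the post-lap population state (what a lap-by-lap raster
        # of the session shows)
        ramps = c * (W @ A.T) - Vb                        # (n, N_BINS)
        peak_amp[lap] = ramps.max(axis=1)
        peak_bin[lap] = ramps.argmax(axis=1)
        pop_map[lap] = ca1_output_rate(ramps, config).sum(axis=0)

    final_ramps = c * (W @ A.T) - Vb
    return SessionRecords(config=config, phases=list(phases),
                          lap_goal_on=lap_goal, peak_amp=peak_amp,
                          peak_bin=peak_bin, pop_rate_map=pop_map,
                          r_inh_mean=r_inh_mean,
                          plateaus_per_lap=plateaus_per_lap,
                          plateau_events=events, final_weights=W,
                          final_ramps=final_ramps)


def summarize_population(records: SessionRecords,
                         through_lap: int | None = None,
                         goal_halfwidth: float = 18.5) -> dict:
    """Place-field census after ``through_lap`` laps (default: whole session).

    A neuron expresses a place field when its ramp peak exceeds the 2 mV
    output-rate threshold.  ``n_acquired`` counts neurons that crossed
    that criterion on any lap so far (fields can subsequently weaken or
    translocate); ``n_silent`` is its complement — neurons that never
    acquired a field.  The goal over-representation index is the fraction
    of currently expressed field peaks within +/- ``goal_halfwidth`` cm
    of the goal, relative to the uniform expectation (1 = uniform).
    """
    cfg = records.config
    k = records.n_laps if through_lap is None else int(through_lap)
    if not (1 <= k <= records.n_laps):
        raise ValueError("through_lap out of range")
    amp = records.peak_amp[k - 1]
    pk = records.peak_bin[k - 1]
    acquired = (records.peak_amp[:k] > cfg.rate_threshold).any(axis=0)
    has_field = amp > cfg.rate_threshold
    bw = cfg.track_length / N_BINS
    peak_pos = (pk + 0.5) * bw
    d = np.abs((peak_pos - cfg.goal_location + cfg.track_length / 2)
               % cfg.track_length - cfg.track_length / 2)
    in_goal = has_field & (d <= goal_halfwidth)
    n_fields = int(has_field.sum())
    uniform_frac = 2 * goal_halfwidth / cfg.track_length
    index = ((in_goal.sum() / n_fields) / uniform_frac
             if n_fields else np.nan)
    return {
        "n_fields": n_fields,
        "n_acquired": int(acquired.sum()),
        "n_silent": int((~acquired).sum()),
        "peak_positions": peak_pos[has_field],
        "goal_overrepresentation_index": float(index),
    }


def network_rule_params() -> RuleParams:
    """Rule parameters calibrated against the synthetic target ramp set.

    Loaded from the frozen fixture shipped with the package (produced by
    the bounded stochastic search in ``analysis/03_calibrate_network_rule.py``)
    so network simulations do not depend on optimizer stochasticity.
    """
    import json
    from importlib import resources

    with resources.files("btspsim.data").joinpath(
            "network_rule_params.json").open() as fh:
        d = json.load(fh)
    return RuleParams.from_dict(d["params"] if "params" in d else d)
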