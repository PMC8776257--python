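"""Synthetic inputs for every pipeline stage.

Generates animal run trajectories on the circular track, plateau-induction
protocols, synthetic "recorded cells" whose ground-truth rule parameters
are known, and the four-condition calibration target set used to pin down
the rule parameters for the network model.  Everything is deterministic
given a seed, so no recorded data are required anywhere in the test
surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import RuleParams
from .ramp import (InputPopulation, RampTrace, TRACK_LENGTH, N_BINS,
                   bin_centers, circular_distance, calibrate_scaling,
                   gaussian_weight_profile, make_input_population,
                   ramp_from_weights, spatial_rate_matrix)

__all__ = [
    "Trajectory",
    "InductionProtocol",
    "SyntheticCell",
    "CalibrationTarget",
    "make_trajectory",
    "make_synthetic_cell",
    "make_calibration_targets",
    "asymmetric_field_ramp",
]


@dataclass
class Trajectory:
    """Run trajectory sampled at a fixed step (default 10 ms).

    positions are in [0, track_length); lap_boundaries holds the index of
    the first step of each lap; stop_mask marks steps where the animal is
    stationary (input firing is silenced there).
    """

    times: np.ndarray
    positions: np.ndarray
    lap_boundaries: np.ndarray
    stop_mask: np.ndarray
    dt: float
    track_length: float = TRACK_LENGTH

    @property
    def n_steps(self) -> int:
        return self.times.size

    @property
    def n_laps(self) -> int:
        return self.lap_boundaries.size

    def lap_edges(self) -> np.ndarray:
        """Lap segment edges including the final endpoint."""
        return np.append(self.lap_boundaries, self.n_steps)

    def lap_slice(self, lap: int) -> slice:
        edges = self.lap_edges()
        return slice(int(edges[lap]), int(edges[lap + 1]))


def make_trajectory(track_length: float = TRACK_LENGTH,
                    velocity: float = 25.0,
                    n_laps: int = 1,
                    pause: tuple[float, float] | None = None,
                    dt: float = 0.01,
                    velocity_jitter: float = 0.0,
                    seed: int | None = None) -> Trajectory:
    """Constant-velocity circular laps with optional per-lap pauses.

    ``pause`` is an optional (position_cm, duration_s) stop inserted each
    lap at the first crossing of that position.  ``velocity_jitter`` draws
    an independent per-lap velocity factor (lognormal-ish, seeded).
    """
    if velocity <= 0 and pause is None:
        raise ValueError("velocity must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(seed)
    positions: list[np.ndarray] = []
    stops: list[np.ndarray] = []
    lap_starts: list[int] = []
    n_total = 0
    for lap in range(n_laps):
        v = velocity
        if velocity_jitter > 0:
            v = velocity * float(np.exp(velocity_jitter
                                        * rng.standard_normal()))
        n_run = int(round(track_length / (v * dt)))
        pos = (np.arange(n_run) * v * dt) % track_length
        stop = np.zeros(n_run, dtype=bool)
        if pause is not None:
            p_pos, p_dur = pause
            n_pause = int(round(p_dur / dt))
            idx = int(np.searchsorted(pos, p_pos % track_length))
            pos = np.concatenate([pos[:idx],
                                  np.full(n_pause, pos[min(idx, n_run - 1)]),
                                  pos[idx:]])
            stop = np.concatenate([stop[:idx],
                                   np.ones(n_pause, dtype=bool),
                                   stop[idx:]])
        lap_starts.append(n_total)
        n_total += pos.size
        positions.append(pos)
        stops.append(stop)
    positions_arr = np.concatenate(positions)
    times = np.arange(n_total) * dt
    return Trajectory(times=times, positions=positions_arr,
                      lap_boundaries=np.asarray(lap_starts, dtype=int),
                      stop_mask=np.concatenate(stops), dt=dt,
                      track_length=track_length)


@dataclass
class InductionProtocol:
    """Position-triggered plateau induction: one plateau per induction lap.

    The plateau onset in each lap is the first time step at which the
    animal reaches ``plateau_position`` (mirroring position-triggered
    current injection); ``n_laps`` limits the number of induction laps.
    """

    plateau_position: float
    plateau_duration: float = 0.3
    n_laps: int = 3

    def onset_indices(self, traj: Trajectory) -> np.ndarray:
        if not 0.0 <= self.plateau_position < traj.track_length:
            raise ValueError("plateau position lies outside the track")
        edges = traj.lap_edges()
        onsets = []
        for lap in range(min(self.n_laps, traj.n_laps)):
            seg = traj.positions[edges[lap]:edges[lap + 1]]
            hit = np.nonzero(seg >= self.plateau_position)[0]
            if hit.size == 0:
                raise ValueError("plateau position never reached in lap")
            onsets.append(int(edges[lap] + hit[0]))
        return np.asarray(onsets, dtype=int)

    def onset_times(self, traj: Trajectory) -> np.ndarray:
        return traj.times[self.onset_indices(traj)]


@dataclass
class SyntheticCell:
    """A synthetic 'recorded' induction with known ground truth."""

    ground_truth_params: RuleParams
    pop: InputPopulation
    trajectory: Trajectory
    protocol: InductionProtocol
    initial_weights: np.ndarray
    initial_ramp: RampTrace
    final_ramp: RampTrace           # noiseless forward-model output
    observed_final_ramp: RampTrace  # with additive bin noise (if any)
    c: float
    Vb: float
    noise_mv: float = 0.0
    seed: int = 0


def make_synthetic_cell(params: RuleParams,
                        pop: InputPopulation | None = None,
                        initial_field: tuple[float, float] | None = None,
                        protocol: InductionProtocol | None = None,
                        traj: Trajectory | None = None,
                        noise_mv: float = 0.0,
                        seed: int = 0,
                        c: float | None = None,
                        sigma_w: float | None = None) -> SyntheticCell:
    """Build a synthetic cell and run the forward model to its final ramp.

    ``initial_field`` is an optional (peak position cm, amplitude mV) of a
    pre-existing place field, realised as a Gaussian weight profile of the
    calibrated reference width scaled to the requested amplitude; silent
    cells start with all weights at 1.
    """
    from .simulate import simulate_induction, background_for

    if pop is None:
        pop = make_input_population()
    if c is None or sigma_w is None:
        c, sigma_w = calibrate_scaling(pop)
    if traj is None:
        traj = make_trajectory(track_length=pop.track_length, n_laps=3)
    if protocol is None:
        protocol = InductionProtocol(plateau_position=pop.track_length / 2.0)
    Vb = background_for(pop, c)
    if initial_field is None:
        w0 = np.ones(pop.n_inputs)
    else:
        center, amp = initial_field
        unit = gaussian_weight_profile(pop, center, sigma_w,
                                       w_min=0.0, w_max=1.0)
        unit_amp = ramp_from_weights(1.0 + unit, pop, c, Vb).amplitude
        w0 = 1.0 + unit * (amp / unit_amp)
    initial_ramp = ramp_from_weights(w0, pop, c, Vb)
    w_final, final_ramp = simulate_induction(w0, params, pop, traj,
                                             protocol, c, Vb)
    rng = np.random.default_rng(seed)
    observed = RampTrace(values=final_ramp.values
                         + noise_mv * rng.standard_normal(N_BINS),
                         track_length=pop.track_length)
    return SyntheticCell(ground_truth_params=params, pop=pop,
                         trajectory=traj, protocol=protocol,
                         initial_weights=w0, initial_ramp=initial_ramp,
                         final_ramp=final_ramp, observed_final_ramp=observed,
                         c=c, Vb=Vb, noise_mv=noise_mv, seed=seed)


def asymmetric_field_ramp(peak_position: float, peak_mv: float = 8.0,
                          rise_cm: float = 75.0, decay_cm: float = 35.0,
                          track_length: float = TRACK_LENGTH,
                          shape_factor: float = 2.0) -> RampTrace:
    """Asymmetric place-field target ramp.

    Piecewise truncated Gaussian that peaks at ``peak_mv`` and returns to
    baseline exactly ``rise_cm`` before and ``decay_cm`` after the peak
    (along the running direction).  ``shape_factor`` = extent / sigma of
    each half-Gaussian.
    """
    x = bin_centers(track_length)
    d = circular_distance(x, peak_position, track_length)
    vals = np.zeros(N_BINS)
    for side, extent in ((d < 0, rise_cm), (d >= 0, decay_cm)):
        sig = extent / shape_factor
        g = np.exp(-0.5 * (d[side] / sig) ** 2)
        g0 = np.exp(-0.5 * (extent / sig) ** 2)
        vals[side] = peak_mv * np.clip((g - g0) / (1.0 - g0), 0.0, None)
    vals[(d < -rise_cm) | (d > decay_cm)] = 0.0
    return RampTrace(values=vals, track_length=track_length)


def save_cell(cell: SyntheticCell, path) -> None:
    """Serialize a synthetic cell to a named-array archive (.npz)."""
    import json

    meta = {
        "params": cell.ground_truth_params.to_dict(),
        "protocol": {"plateau_position": cell.protocol.plateau_position,
                     "plateau_duration": cell.protocol.plateau_duration,
                     "n_laps": cell.protocol.n_laps},
        "pop": {"track_length": cell.pop.track_length,
                "n_inputs": cell.pop.n_inputs,
                "floor_width": 6.0 * cell.pop.sigma,
                "R_max": cell.pop.R_max},
        "c": cell.c, "Vb": cell.Vb,
        "noise_mv": cell.noise_mv, "seed": cell.seed,
        "dt": cell.trajectory.dt,
        "track_length": cell.trajectory.track_length,
    }
    np.savez(path,
             times=cell.trajectory.times,
             positions=cell.trajectory.positions,
             lap_boundaries=cell.trajectory.lap_boundaries,
             stop_mask=cell.trajectory.stop_mask,
             initial_weights=cell.initial_weights,
             initial_ramp=cell.initial_ramp.values,
             final_ramp=cell.final_ramp.values,
             observed_final_ramp=cell.observed_final_ramp.values,
             meta=np.array(json.dumps(meta)))


def load_cell(path) -> SyntheticCell:
    """Inverse of :func:`save_cell`; the round trip is lossless."""
    import json

    from .ramp import RampTrace

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        traj = Trajectory(times=z["times"], positions=z["positions"],
                          lap_boundaries=z["lap_boundaries"],
                          stop_mask=z["stop_mask"], dt=meta["dt"],
                          track_length=meta["track_length"])
        tl = meta["track_length"]
        return SyntheticCell(
            ground_truth_params=RuleParams.from_dict(meta["params"]),
            pop=make_input_population(**meta["pop"]),
            trajectory=traj,
            protocol=InductionProtocol(**meta["protocol"]),
            initial_weights=z["initial_weights"],
            initial_ramp=RampTrace(values=z["initial_ramp"],
                                   track_length=tl),
            final_ramp=RampTrace(values=z["final_ramp"], track_length=tl),
            observed_final_ramp=RampTrace(values=z["observed_final_ramp"],
                                          track_length=tl),
            c=meta["c"], Vb=meta["Vb"], noise_mv=meta["noise_mv"],
            seed=meta["seed"])


@dataclass
class CalibrationTarget:
    """One calibration condition: protocol plus target ramp and features."""

    condition: str
    protocol: InductionProtocol
    trajectory: Trajectory
    target_ramp: RampTrace
    features: dict = field(default_factory=dict)


def make_calibration_targets(track_length: float = TRACK_LENGTH,
                             velocity: float = 25.0,
                             plateau_position: float = 120.0,
                             dt: float = 0.01) -> list[CalibrationTarget]:
    """The synthetic target set for calibrating the network's rule parameters.

    Condition 1-3 (de novo): three laps at constant velocity with one
    300 ms plateau per lap in a silent cell must produce an asymmetric
    ramp (~75 cm rise, ~35 cm decay) with 8 mV peak.  Condition 4
    (translocation): three further laps with plateaus 3 s of running
    behind the induced peak must depress the old peak by 5 mV and raise
    an 8 mV peak at the new position.
    """
    traj = make_trajectory(track_length=track_length, velocity=velocity,
                           n_laps=3, dt=dt)
    de_novo_peak = plateau_position
    target1 = asymmetric_field_ramp(de_novo_peak, peak_mv=8.0,
                                    rise_cm=75.0, decay_cm=35.0,
                                    track_length=track_length)
    proto1 = InductionProtocol(plateau_position=plateau_position,
                               plateau_duration=0.3, n_laps=3)
    new_plateau = (de_novo_peak - 3.0 * velocity) % track_length
    target2 = asymmetric_field_ramp(new_plateau, peak_mv=8.0,
                                    rise_cm=75.0, decay_cm=35.0,
                                    track_length=track_length)
    proto2 = InductionProtocol(plateau_position=new_plateau,
                               plateau_duration=0.3, n_laps=3)
    return [
        CalibrationTarget(
            condition="de_novo", protocol=proto1, trajectory=traj,
            target_ramp=target1,
            features={"peak_mv": 8.0, "rise_cm": 75.0, "decay_cm": 35.0}),
        CalibrationTarget(
            condition="translocation", protocol=proto2, trajectory=traj,
            target_ramp=target2,
            features={"old_peak_position": de_novo_peak,
                      "old_peak_decrement_mv": 5.0, "new_peak_mv": 8.0}),
    ]
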