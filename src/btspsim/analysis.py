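"""Place-field ramp quantifications.

Implements the standard measurements applied to spatially binned Vm ramps
and their plasticity-induced changes: circular Savitzky-Golay smoothing,
amplitude (peak minus the mean of the 10% most hyperpolarized bins),
bin-wise ramp differences under a shared baseline, the shortest-delay time
base that maps spatial bins to time from plateau onset, half-width and
asymmetry of the change profile, and a Gaussian-process interpolation of
the (delay, initial Vm) -> dVm surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (ConstantKernel,
                                              RationalQuadratic, WhiteKernel)

from .ramp import N_BINS, RampTrace, circular_distance, ramp_amplitude
from .synth import Trajectory

__all__ = [
    "DeltaRamp",
    "smooth_ramp",
    "ramp_amplitude",
    "delta_vm",
    "plateau_time_base",
    "delta_halfwidth",
    "asymmetry_ratio",
    "delta_heatmap",
    "boxcar_display",
]


@dataclass
class DeltaRamp:
    """Bin-wise change in the Vm ramp (after minus before), mV.

    ``time_base`` optionally assigns each spatial bin a signed delay (s)
    from plateau onset (negative = traversed before the plateau).
    """

    values: np.ndarray
    time_base: np.ndarray | None = None
    plateau_bin: int | None = None
    track_length: float = 185.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != N_BINS:
            raise ValueError(f"delta ramp must have {N_BINS} bins")
        if self.time_base is not None:
            self.time_base = np.asarray(self.time_base, dtype=float)
            if self.time_base.size != N_BINS:
                raise ValueError("time base must match the 100 bins")


def smooth_ramp(ramp: RampTrace | np.ndarray, window: int = 21,
                order: int = 3) -> RampTrace:
    """Savitzky-Golay smoothing with circular wrap-around."""
    values = ramp.values if isinstance(ramp, RampTrace) else np.asarray(ramp)
    tl = ramp.track_length if isinstance(ramp, RampTrace) else 185.0
    sm = savgol_filter(values, window_length=window, polyorder=order,
                       mode="wrap")
    return RampTrace(values=sm, track_length=tl)


def delta_vm(before: RampTrace, after: RampTrace,
             time_base: np.ndarray | None = None,
             plateau_bin: int | None = None) -> DeltaRamp:
    """Bin-wise after-minus-before difference under the shared baseline.

    Model ramps are expressed relative to the silent-cell background, so
    the pre-induction baseline convention is shared by construction and
    the difference is taken bin by bin.
    """
    if before.values.size != after.values.size:
        raise ValueError("ramps must share the same binning")
    return DeltaRamp(values=after.values - before.values,
                     time_base=time_base, plateau_bin=plateau_bin,
                     track_length=before.track_length)


def plateau_time_base(traj: Trajectory, onset_indices: Sequence[int]
                      ) -> np.ndarray:
    """Shortest signed delay (s) from plateau onset to each spatial bin.

    For each induction lap, each bin is assigned the time of its first
    traversal in that lap minus the plateau onset time; across laps the
    delay of smallest magnitude is kept.  Bins never traversed get NaN.
    """
    if len(onset_indices) == 0:
        raise ValueError("at least one induction lap is required")
    bw = traj.track_length / N_BINS
    bins = np.minimum((traj.positions / bw).astype(int), N_BINS - 1)
    edges = traj.lap_edges()
    best = np.full(N_BINS, np.nan)
    for onset in onset_indices:
        lap = int(np.searchsorted(edges, onset, side="right") - 1)
        i0, i1 = int(edges[lap]), int(edges[lap + 1])
        seg_bins = bins[i0:i1]
        # first traversal of each bin within the lap
        first = np.full(N_BINS, -1)
        uniq, first_idx = np.unique(seg_bins, return_index=True)
        first[uniq] = first_idx
        seen = first >= 0
        delay = np.full(N_BINS, np.nan)
        delay[seen] = traj.times[i0 + first[seen]] - traj.times[onset]
        better = seen & (np.isnan(best) | (np.abs(delay) < np.abs(best)))
        best[better] = delay[better]
    return best


def delta_halfwidth(delta: DeltaRamp, plateau_position: float,
                    criterion_frac: float = 0.25) -> dict:
    """Half-width of the change profile: plateau to the final decay point.

    Following the trace away from the plateau on each side, the half-width
    is the distance (cm) and time (s) to the final crossing below the
    return criterion (zero, operationalised as ``criterion_frac`` of the
    trace minimum, which is a small positive floor if the trace never goes
    negative).  If neither side reaches criterion the measurement is
    flagged as a truncated underestimate spanning the half track.
    """
    v = delta.values
    peak = v.max()
    if peak <= 0:
        raise ValueError("delta ramp has no positive lobe")
    # return criterion: a quarter of the depression trough when the trace
    # goes meaningfully negative, otherwise a small positive floor (pure
    # potentiation profiles decay to baseline, not below it)
    vmin = v.min()
    thr = (criterion_frac * vmin if vmin < -0.05 * peak
           else 0.02 * peak)
    tl = delta.track_length
    bw = tl / N_BINS
    centers = (np.arange(N_BINS) + 0.5) * bw
    p_bin = int(plateau_position / bw) % N_BINS

    best = None
    for direction in (+1, -1):
        order = [(p_bin + direction * k) % N_BINS for k in range(N_BINS // 2)]
        vals = v[order]
        below = vals <= thr
        cross = np.nonzero(~below[:-1] & below[1:])[0]
        if cross.size == 0:
            continue
        k = int(cross[-1] + 1)  # final return on this side
        dist = k * bw
        t = (np.abs(delta.time_base[order[k]])
             if delta.time_base is not None else np.nan)
        if best is None or dist > best["extent_cm"]:
            best = {"extent_cm": dist, "extent_s": float(t),
                    "side": "after" if direction > 0 else "before",
                    "truncated": False}
    if best is None:
        t = (np.nanmax(np.abs(delta.time_base))
             if delta.time_base is not None else np.nan)
        return {"extent_cm": tl / 2.0, "extent_s": float(t),
                "side": "none", "truncated": True}
    return best


def asymmetry_ratio(delta: DeltaRamp, peak_frac: float = 0.1) -> float:
    """Ratio of potentiation duration before vs after plateau onset.

    Durations are measured on the time base as the span over which the
    positive change exceeds ``peak_frac`` of its peak on each side of the
    plateau onset (the 10% peak-amplitude times).  Returns inf when the
    positive lobe is entirely pre-plateau (one-sided).
    """
    if delta.time_base is None:
        raise ValueError("a time base is required")
    v = delta.values
    peak = v.max()
    if peak <= 0:
        raise ValueError("delta ramp has no positive lobe")
    thr = peak_frac * peak
    t = delta.time_base
    ok = ~np.isnan(t) & (v >= thr)
    before = ok & (t < 0)
    after = ok & (t > 0)
    dur_before = float(-t[before].min()) if before.any() else 0.0
    dur_after = float(t[after].max()) if after.any() else 0.0
    if dur_after == 0.0:
        return np.inf
    return dur_before / dur_after


def delta_heatmap(samples, delay_grid=None, vm_grid=None,
                  noise_level: float = 1e-6, seed: int = 0,
                  n_restarts: int = 2):
    """Gaussian-process surface of dVm over (delay, initial Vm).

    ``samples`` is an (n, 3) array of (delay s, initial Vm mV, dVm mV)
    triplets.  A rational-quadratic covariance is fit by marginal
    likelihood and the posterior mean evaluated on a regular grid.

    Returns (delay_grid, vm_grid, surface) with surface shaped
    (len(vm_grid), len(delay_grid)).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError("samples must be an (n, 3) array")
    if samples.shape[0] < 10:
        raise ValueError("at least 10 samples are required")
    X, y = samples[:, :2], samples[:, 2]
    scale = np.maximum(X.std(axis=0), 1e-9)
    Xn = X / scale
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RationalQuadratic(
        length_scale=1.0, alpha=1.0,
        length_scale_bounds=(1e-2, 1e2), alpha_bounds=(1e-2, 1e3))
    if noise_level > 1e-6:
        kernel = kernel + WhiteKernel(noise_level, (1e-10, 1e1))
    gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-6,
                                  normalize_y=True,
                                  n_restarts_optimizer=n_restarts,
                                  random_state=seed)
    gp.fit(Xn, y)
    if delay_grid is None:
        delay_grid = np.linspace(X[:, 0].min(), X[:, 0].max(), 50)
    if vm_grid is None:
        vm_grid = np.linspace(X[:, 1].min(), X[:, 1].max(), 50)
    TT, VV = np.meshgrid(delay_grid, vm_grid)
    Xq = np.column_stack([TT.ravel(), VV.ravel()]) / scale
    surface = gp.predict(Xq).reshape(TT.shape)
    return np.asarray(delay_grid), np.asarray(vm_grid), surface


def boxcar_display(values: np.ndarray, width: int = 5) -> np.ndarray:
    """Five-point boxcar smoothing used only for displaying dVm traces."""
    kernel = np.ones(width) / width
    padded = np.concatenate([values[-(width // 2):], values,
                             values[:width // 2]])
    return np.convolve(padded, kernel, mode="valid")
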