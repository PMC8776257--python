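"""CA3 input population and the linear Vm-ramp summation model.

A CA1 place cell is modelled as a weighted sum of 200 spatially tuned CA3
inputs whose Gaussian firing fields tile a ~185 cm circular track:

    R_i(x) = R_max * exp(-((y_i - x) / sigma)^2 / 2)      (circular distance)
    V(x)   = c * sum_i W_i * R_i(x) - V_b

V_b is the background depolarization produced when all weights equal 1, so
a naive (silent) cell has a flat, zero ramp.  The voltage scale c and the
reference Gaussian weight-profile width are calibrated so that weights
spanning 1 to 2.5 produce a 6 mV, 108 cm wide place-field ramp.  The
inverse problem (weights from a measured ramp) is solved by non-negative
least squares with a small ridge pulling unconstrained directions toward
the baseline weight of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import brentq, lsq_linear

if TYPE_CHECKING:  # pragma: no cover
    from .synth import Trajectory

N_BINS = 100
TRACK_LENGTH = 185.0

__all__ = [
    "InputPopulation",
    "RampTrace",
    "make_input_population",
    "rates_from_trajectory",
    "spatial_rate_matrix",
    "calibrate_scaling",
    "ramp_from_weights",
    "infer_initial_weights",
    "ramp_amplitude",
    "ramp_width",
    "gaussian_weight_profile",
]


def circular_distance(a, b, track_length: float):
    """Signed shortest distance a - b on a circular track."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % track_length
    return np.where(d > track_length / 2.0, d - track_length, d)


@dataclass
class InputPopulation:
    """Spatially tuned CA3 place-cell inputs with circular Gaussian fields."""

    track_length: float
    n_inputs: int
    sigma: float
    R_max: float
    peak_locations: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_inputs < 2:
            raise ValueError("need at least 2 inputs")
        if self.sigma <= 0 or self.R_max <= 0 or self.track_length <= 0:
            raise ValueError("population parameters must be positive")
        if self.peak_locations is None:
            self.peak_locations = (np.arange(self.n_inputs)
                                   * self.spacing) % self.track_length
        self.peak_locations = np.asarray(self.peak_locations, dtype=float)

    @property
    def spacing(self) -> float:
        return self.track_length / self.n_inputs

    def rates_at(self, x) -> np.ndarray:
        """Firing rate of every input at position(s) x (Hz).

        Returns shape (n_inputs,) for scalar x, else (n_inputs, len(x)).
        """
        x_arr = np.atleast_1d(np.asarray(x, dtype=float))
        d = circular_distance(self.peak_locations[:, None], x_arr[None, :],
                              self.track_length)
        r = self.R_max * np.exp(-0.5 * (d / self.sigma) ** 2)
        return r[:, 0] if np.ndim(x) == 0 else r


def make_input_population(track_length: float = TRACK_LENGTH,
                          n_inputs: int = 200,
                          floor_width: float = 90.0,
                          R_max: float = 40.0) -> InputPopulation:
    """Uniformly tiled population; sigma = full floor width (6*sigma) / 6."""
    if min(track_length, floor_width, R_max) <= 0:
        raise ValueError("arguments must be positive")
    return InputPopulation(track_length=track_length, n_inputs=n_inputs,
                           sigma=floor_width / 6.0, R_max=R_max)


@dataclass
class RampTrace:
    """Spatially binned Vm ramp: 100 bins spanning the track, mV.

    Values are depolarizations relative to the silent-cell background, so
    the trace of a naive cell is ~0 everywhere.  ``baseline`` follows the
    convention "mean of the 10% most hyperpolarized bins".
    """

    values: np.ndarray
    track_length: float = TRACK_LENGTH

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != N_BINS:
            raise ValueError(f"ramp must have exactly {N_BINS} bins")

    @property
    def bin_width(self) -> float:
        return self.track_length / N_BINS

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(N_BINS) + 0.5) * self.bin_width

    @property
    def baseline(self) -> float:
        k = N_BINS // 10
        return float(np.mean(np.sort(self.values)[:k]))

    @property
    def amplitude(self) -> float:
        return float(self.values.max() - self.baseline)

    @property
    def peak_bin(self) -> int:
        return int(np.argmax(self.values))

    @property
    def peak_position(self) -> float:
        return float(self.bin_centers[self.peak_bin])


def bin_centers(track_length: float = TRACK_LENGTH,
                n_bins: int = N_BINS) -> np.ndarray:
    return (np.arange(n_bins) + 0.5) * (track_length / n_bins)


def spatial_rate_matrix(pop: InputPopulation,
                        n_bins: int = N_BINS) -> np.ndarray:
    """Input rates evaluated at spatial bin centers, shape (n_bins, n_inputs)."""
    x = bin_centers(pop.track_length, n_bins)
    return pop.rates_at(x).T


def rates_from_trajectory(pop: InputPopulation, traj: "Trajectory") -> np.ndarray:
    """Per-input rate traces R_i(t), shape (n_inputs, n_steps).

    Rates are set to zero during stop intervals (place-cell firing is
    suppressed when the animal is not running).
    """
    r = pop.rates_at(traj.positions)
    if traj.stop_mask is not None:
        r = r * (~traj.stop_mask)[None, :]
    return r


def background_level(pop: InputPopulation, c: float,
                     n_bins: int = N_BINS) -> float:
    """Background depolarization V_b: spatial mean of c*sum_i R_i with unit weights."""
    A = spatial_rate_matrix(pop, n_bins)
    return float(c * A.sum(axis=1).mean())


def ramp_from_weights(weights, pop: InputPopulation, c: float,
                      Vb: float | None = None) -> RampTrace:
    """Forward model: V(x) = c * sum_i W_i R_i(x) - V_b on 100 bins."""
    weights = np.asarray(weights, dtype=float)
    if weights.size != pop.n_inputs:
        raise ValueError("weight vector length must equal n_inputs")
    if Vb is None:
        Vb = background_level(pop, c)
    A = spatial_rate_matrix(pop)
    return RampTrace(values=c * (A @ weights) - Vb,
                     track_length=pop.track_length)


def ramp_amplitude(ramp: RampTrace | np.ndarray) -> float:
    """Peak minus baseline (mean of the 10% most hyperpolarized bins), mV."""
    if not isinstance(ramp, RampTrace):
        ramp = RampTrace(values=ramp)
    return ramp.amplitude


def ramp_width(ramp: RampTrace | np.ndarray, criterion: float = 0.1) -> float:
    """Spatial extent (cm) over which the ramp exceeds baseline + criterion*amplitude.

    The contiguous circular segment containing the peak is measured, with
    threshold crossings located by linear interpolation between bin centers
    (sub-bin resolution).
    """
    left, right = _width_edges(ramp, criterion)
    if not isinstance(ramp, RampTrace):
        ramp = RampTrace(values=ramp)
    return float((right - left) % ramp.track_length or ramp.track_length)


def _width_edges(ramp: RampTrace | np.ndarray,
                 criterion: float = 0.1) -> tuple[float, float]:
    """Positions (cm) where the ramp crosses the width threshold around its peak."""
    if not isinstance(ramp, RampTrace):
        ramp = RampTrace(values=ramp)
    v = ramp.values
    thr = ramp.baseline + criterion * ramp.amplitude
    above = v > thr
    n = v.size
    peak = ramp.peak_bin
    if above.all():
        return 0.0, ramp.track_length
    if not above[peak]:  # degenerate flat ramp
        p = ramp.peak_position
        return p, p
    centers = ramp.bin_centers
    bw = ramp.bin_width

    def interp_cross(i_out, i_in):
        # linear interpolation of the crossing between adjacent bin centers
        v0, v1 = v[i_out], v[i_in]
        frac = (thr - v0) / (v1 - v0) if v1 != v0 else 0.5
        x0 = centers[i_out]
        step = circular_distance(centers[i_in], centers[i_out],
                                 ramp.track_length)
        return (x0 + frac * step) % ramp.track_length

    i = peak
    while above[(i - 1) % n]:
        i = (i - 1) % n
    left = interp_cross((i - 1) % n, i)
    j = peak
    while above[(j + 1) % n]:
        j = (j + 1) % n
    right = interp_cross((j + 1) % n, j)
    return float(left), float(right)


def gaussian_weight_profile(pop: InputPopulation, center: float,
                            sigma_w: float, w_min: float = 1.0,
                            w_max: float = 2.5) -> np.ndarray:
    """Synaptic weights as a circular Gaussian of place-field location."""
    d = circular_distance(pop.peak_locations, center, pop.track_length)
    return w_min + (w_max - w_min) * np.exp(-0.5 * (d / sigma_w) ** 2)


def calibrate_scaling(pop: InputPopulation,
                      weight_range: tuple[float, float] = (1.0, 2.5),
                      target_width: float = 108.0,
                      target_peak: float = 6.0,
                      width_criterion: float = 0.1,
                      center: float | None = None) -> tuple[float, float]:
    """Calibrate the voltage scale c and reference weight-profile width.

    Finds the Gaussian weight-profile width sigma_w for which the resulting
    ramp has the target spatial width (the width criterion is independent of
    c by linearity), then sets c so the ramp amplitude equals the target
    peak.  Returns (c, sigma_w).
    """
    if target_width <= 0 or target_peak <= 0:
        raise ValueError("calibration targets must be positive")
    if target_width >= pop.track_length:
        raise ValueError("target width must be smaller than the track")
    if center is None:
        center = pop.track_length / 2.0
    A = spatial_rate_matrix(pop)
    bg = A.sum(axis=1).mean()

    def width_of(sigma_w: float) -> float:
        w = gaussian_weight_profile(pop, center, sigma_w, *weight_range)
        ramp = RampTrace(values=A @ w - bg, track_length=pop.track_length)
        return ramp_width(ramp, width_criterion)

    lo, hi = 1.0, pop.track_length / 2.0
    if not (width_of(lo) < target_width < width_of(hi)):
        raise ValueError("target width unattainable for this population")
    sigma_w = brentq(lambda s: width_of(s) - target_width, lo, hi,
                     xtol=1e-6)
    w = gaussian_weight_profile(pop, center, sigma_w, *weight_range)
    raw_amp = ramp_amplitude(
        RampTrace(values=A @ w - bg, track_length=pop.track_length))
    c = target_peak / raw_amp
    return float(c), float(sigma_w)


def infer_initial_weights(ramp: RampTrace, pop: InputPopulation, c: float,
                          Vb: float, W_max: float | None = None,
                          ridge: float = 1e-6) -> np.ndarray:
    """Infer synaptic weights from a measured ramp by bounded least squares.

    Solves min ||c*A w - (ramp + Vb)||^2 + ridge*||w - 1||^2 subject to
    0 <= w <= W_max.  The population (200 inputs on 100 bins) is
    underdetermined, so the ridge pulls null-space components toward the
    baseline weight of 1; a flat zero ramp therefore recovers w = 1 exactly.
    """
    A = c * spatial_rate_matrix(pop)
    b = ramp.values + Vb
    s = np.sqrt(ridge) * np.linalg.norm(A) / np.sqrt(A.shape[1])
    A_aug = np.vstack([A, s * np.eye(pop.n_inputs)])
    b_aug = np.concatenate([b, s * np.ones(pop.n_inputs)])
    ub = np.inf if W_max is None else float(W_max)
    res = lsq_linear(A_aug, b_aug, bounds=(0.0, ub), tol=1e-12,
                     max_iter=300)
    if not res.success and res.status <= 0:
        raise RuntimeError(f"weight inference failed: {res.message}")
    return res.x
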