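"""Parameters of the weight-dependent BTSP learning rule.

The rule has nine free parameters: two signal time constants (eligibility
trace and instructive signal), threshold/slope pairs for the sigmoidal
potentiation and depression gains, two kinetic rate constants, and the
maximum synaptic weight.  Two derived scaling constants normalise the peak
amplitudes of the eligibility trace and instructive signal to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

#: canonical order of the nine free parameters
FREE_PARAM_NAMES = (
    "tau_ET",
    "tau_IS",
    "alpha_pot",
    "beta_pot",
    "alpha_dep",
    "beta_dep",
    "k_pot",
    "k_dep",
    "W_max",
)


@dataclass
class RuleParams:
    """The nine free parameters of the bidirectional BTSP rule.

    Parameters
    ----------
    tau_ET : float
        Decay time constant of the synapse-local eligibility trace, ms.
    tau_IS : float
        Decay time constant of the plateau-evoked instructive signal, ms.
    alpha_pot, beta_pot : float
        Threshold (in [0, 1]) and slope (> 0) of the sigmoidal potentiation
        gain applied to the ET*IS signal overlap.
    alpha_dep, beta_dep : float
        Threshold and slope of the sigmoidal depression gain.
    k_pot, k_dep : float
        Kinetic rate constants for the inactive->active (potentiation) and
        active->inactive (depression) transitions, 1/s.
    W_max : float
        Maximum synaptic weight (active-state occupancy of 1), > 1.
    lambda_ET : float
        Derived scaling so that the eligibility trace peaks at <= 1.  For
        rate inputs this is 1/R_max; for discrete spikes it is unused
        (a spike sets ET to 1).
    lambda_IS : float
        Derived scaling so that the instructive signal peaks at exactly 1
        at the offset of a plateau of the protocol's reference duration.
    """

    tau_ET: float = 2500.0
    tau_IS: float = 1500.0
    alpha_pot: float = 0.5
    beta_pot: float = 4.0
    alpha_dep: float = 0.01
    beta_dep: float = 44.44
    k_pot: float = 1.7
    k_dep: float = 0.204
    W_max: float = 5.0
    lambda_ET: float = field(default=1.0 / 40.0)
    lambda_IS: float = field(default=0.0)

    #: reference plateau duration used to derive lambda_IS, s
    plateau_duration_ref: float = 0.3

    def __post_init__(self) -> None:
        if self.tau_ET <= 0 or self.tau_IS <= 0:
            raise ValueError("time constants must be > 0")
        if not (0.0 <= self.alpha_pot <= 1.0 and 0.0 <= self.alpha_dep <= 1.0):
            raise ValueError("gain thresholds alpha must lie in [0, 1]")
        if self.beta_pot <= 0 or self.beta_dep <= 0:
            raise ValueError("gain slopes beta must be > 0")
        if self.k_pot < 0 or self.k_dep < 0:
            raise ValueError("rate constants must be >= 0")
        if self.W_max <= 1.0:
            raise ValueError("W_max must exceed the baseline weight of 1")
        if self.lambda_IS == 0.0:
            self.lambda_IS = is_scaling(self.plateau_duration_ref, self.tau_IS)
        if not (math.isfinite(self.lambda_ET) and self.lambda_ET > 0):
            raise ValueError("lambda_ET must be finite and > 0")
        if not (math.isfinite(self.lambda_IS) and self.lambda_IS > 0):
            raise ValueError("lambda_IS must be finite and > 0")

    # -- convenience -------------------------------------------------
    @property
    def tau_ET_s(self) -> float:
        return self.tau_ET / 1000.0

    @property
    def tau_IS_s(self) -> float:
        return self.tau_IS / 1000.0

    def free_values(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in FREE_PARAM_NAMES)

    @classmethod
    def from_free_values(cls, values, R_max: float = 40.0,
                         plateau_duration: float = 0.3) -> "RuleParams":
        kwargs = dict(zip(FREE_PARAM_NAMES, map(float, values)))
        return cls(lambda_ET=1.0 / R_max,
                   plateau_duration_ref=plateau_duration, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RuleParams":
        d = dict(d)
        d.setdefault("lambda_IS", 0.0)
        return cls(**{k: d[k] for k in d
                      if k in cls.__dataclass_fields__})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RuleParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def is_scaling(duration_s: float, tau_IS_ms: float) -> float:
    """Scaling of the plateau gate so IS peaks at exactly 1 at plateau offset.

    Integrating tau*dIS/dt = -IS + lambda*P from 0 with P = 1 for
    ``duration_s`` seconds gives IS(d) = lambda * (1 - exp(-d/tau)); solving
    IS(d) = 1 yields lambda = 1 / (1 - exp(-d/tau)).
    """
    if duration_s <= 0:
        raise ValueError("plateau duration must be > 0")
    tau_s = tau_IS_ms / 1000.0
    return 1.0 / (1.0 - math.exp(-duration_s / tau_s))


def single_spike_reference_params() -> RuleParams:
    """Reference parameter set used for single-spike pairing simulations."""
    return RuleParams(tau_ET=2500.0, tau_IS=1500.0, alpha_pot=0.5,
                      beta_pot=4.0, alpha_dep=0.01, beta_dep=44.44,
                      k_pot=1.7, k_dep=0.204, W_max=5.0)
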