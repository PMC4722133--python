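"""Candidate forgetting functions for the decay of perceived roll tilt.

During sustained centrifugation the sensation of body tilt — measured as
the subjective visual horizontal (SVH), in degrees, right tilt positive —
declines toward an individual asymptote.  Two three-parameter families are
the classical candidates for such retention curves:

* exponential:  ``SVH(t) = A * exp(-b * t) + C``
* power:        ``SVH(t) = A * t**(-b) + C``

with amplitude ``A`` (degrees, or degrees * s**b for the power family),
decay rate / exponent ``b`` and asymptote ``C`` (degrees).  A third family,
the single-trace fragility function

* wickelgren:   ``m(t) = lam * (1 + beta*t)**(-psi) * exp(-pi_rate*t)``

combines a power-like time-decay channel with an exponential interference
channel; it is supported for evaluation only.

The power function diverges as ``t -> 0+``, so model comparisons are
restricted to an observation interval, by default [4, 360] seconds after
reaching the G plateau — the span over which line settings exist.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Family",
    "DecayParams",
    "ObservationInterval",
    "eval_model",
    "interval_extremes",
    "time_constant",
]


class Family(str, enum.Enum):
    """Model family for a retention curve."""

    EXPONENTIAL = "exponential"
    POWER = "power"
    WICKELGREN = "wickelgren"


def _as_family(family: "Family | str") -> Family:
    return Family(family)


@dataclass(frozen=True)
class DecayParams:
    """Parameters of one decay model.

    Exactly one parameter set is populated, per family: ``(A, b, C)`` for
    the exponential and power families, ``(lam, beta, psi, pi_rate)`` for
    the wickelgren family.  ``b > 0`` is enforced for the exponential and
    power families so that the curve decays toward ``C``; the sign of the
    tilt is carried by ``A``.
    """

    family: Family
    A: float | None = None
    b: float | None = None
    C: float | None = None
    lam: float | None = None
    beta: float | None = None
    psi: float | None = None
    pi_rate: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", _as_family(self.family))
        abc = (self.A, self.b, self.C)
        wick = (self.lam, self.beta, self.psi, self.pi_rate)
        if self.family is Family.WICKELGREN:
            if any(v is None for v in wick) or any(v is not None for v in abc):
                raise ValueError(
                    "wickelgren family requires (lam, beta, psi, pi_rate) "
                    "and no (A, b, C)"
                )
            if self.beta < 0 or self.pi_rate < 0:
                raise ValueError("wickelgren requires beta >= 0 and pi_rate >= 0")
        else:
            if any(v is None for v in abc) or any(v is not None for v in wick):
                raise ValueError(
                    f"{self.family.value} family requires (A, b, C) and no "
                    "wickelgren parameters"
                )
            if not self.b > 0:
                raise ValueError(
                    f"decay rate b must be > 0 (got {self.b}); the sign of "
                    "the tilt is carried by A"
                )


@dataclass(frozen=True)
class ObservationInterval:
    """Time span [t_min, t_max] (seconds) over which fits are compared.

    The default (4, 360) covers the span of the centrifuge protocol: no
    line settings occur before 4 s, and the recording at the G plateau
    lasts 6 minutes.  t_min must be positive so that the power family is
    evaluable at both endpoints.
    """

    t_min: float = 4.0
    t_max: float = 360.0

    def __post_init__(self) -> None:
        if not 0 < self.t_min < self.t_max:
            raise ValueError(
                f"require 0 < t_min < t_max, got ({self.t_min}, {self.t_max})"
            )


def eval_model(params: DecayParams, t):
    """Evaluate a decay model at time(s) ``t`` (seconds after plateau onset).

    Returns degrees of SVH tilt.  Accepts scalars or arrays.  The power
    family requires ``t > 0`` (the function diverges as t approaches zero
    from the right); the other families require ``t >= 0``.
    """
    t_arr = np.asarray(t, dtype=float)
    if params.family is Family.POWER:
        if np.any(t_arr <= 0):
            raise ValueError(
                "power family is defined only for t > 0 "
                "(the function approaches infinity as t goes to zero)"
            )
        out = params.A * t_arr ** (-params.b) + params.C
    elif params.family is Family.EXPONENTIAL:
        if np.any(t_arr < 0):
            raise ValueError("exponential family requires t >= 0")
        out = params.A * np.exp(-params.b * t_arr) + params.C
    else:  # wickelgren
        if np.any(t_arr < 0):
            raise ValueError("wickelgren family requires t >= 0")
        out = (
            params.lam
            * (1.0 + params.beta * t_arr) ** (-params.psi)
            * np.exp(-params.pi_rate * t_arr)
        )
    if np.ndim(t) == 0:
        return float(out)
    return out


def interval_extremes(
    params: DecayParams, interval: ObservationInterval | None = None
) -> tuple[float, float]:
    """Function values at the observation-interval endpoints, (F(t_min), F(t_max)).

    For the monotone exponential and power families these are the extreme
    values the fitted curve assumes on the interval.
    """
    interval = interval or ObservationInterval()
    return (
        float(eval_model(params, interval.t_min)),
        float(eval_model(params, interval.t_max)),
    )


def time_constant(b: float) -> float:
    """e-folding time T = 1/b (seconds) of an exponential decay with rate ``b``."""
    if not b > 0:
        raise ValueError(f"time constant requires b > 0, got {b}")
    return 1.0 / b


def _require_abc(params: DecayParams) -> None:
    if params.family is Family.WICKELGREN:
        raise ValueError("operation defined for (A, b, C) families only")


def initial_value(params: DecayParams) -> float:
    """Value at t = 0 for the exponential family (A + C); the perceived
    initial tilt implied by the fit."""
    _require_abc(params)
    if params.family is not Family.EXPONENTIAL:
        raise ValueError("initial value at t=0 is defined for the exponential family")
    return params.A + params.C


def is_monotone_decreasing(params: DecayParams) -> bool:
    """Whether the curve decreases toward C on t > 0 (A > 0, b > 0)."""
    _require_abc(params)
    return params.A > 0
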