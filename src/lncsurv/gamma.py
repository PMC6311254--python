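"""The Γ operation: windowed bitwise mutation of a candidate-selection vector.

The search state is a binary inclusion vector X over the P-ranked candidate
transcripts (bit j = 1 means ranked transcript G_j is active).  Each
iteration d of the search flips every bit inside a moving window:

* the *variation center* sweeps symmetrically around the vector midpoint,
  alternating sides with growing offset, so that over D iterations the
  centers cover the index line evenly;
* the *decay coefficient* xi shrinks from near 1 down to a floor of 0.1,
  so early windows span most of the vector (global exploration) and late
  windows are narrow (local refinement);
* the *variation range* is the window of half-width xi*C/2 around the
  center, rounded to integer positions and clipped to [1, C];
* *Γ correction* then caps the active set at theta one-bits, keeping the
  one-bits of smallest index — i.e. the candidates of smallest
  differential-expression P, since positions are P-ascending.

Positions are 1-based throughout this module, matching the ranked-candidate
indexing G_1..G_C; selection vectors are numpy uint8 arrays of length C.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateRangeError

__all__ = [
    "GammaConfig",
    "variation_center",
    "decay_coefficient",
    "variation_range",
    "gamma_operate",
    "gamma_correct",
]

logger = logging.getLogger(__name__)

#: floor of the decay schedule at the final iteration
XI_FLOOR = 0.1


@dataclass(frozen=True)
class GammaConfig:
    """Iteration budget and retention cap of the Γ search.

    Parameters
    ----------
    D
        Maximal number of Γ iterations (default 10).
    theta
        Retention cap: the maximum number of one-bits surviving a
        Γ correction.  ``None`` means "set from the initial selection's
        population count" (done by the search at initialization).
    schedule
        Decay-schedule variant: ``"tanh"`` (default, tanh(2(D-d)/(D+1))),
        ``"literal"`` (tanh(0.75(D-d)/(D+1))), or an explicit per-iteration
        mapping {d: xi}.
    init_threshold
        P-value cutoff seeding the initial selection vector.
    """

    D: int = 10
    theta: int | None = None
    schedule: str | Mapping[int, float] = "tanh"
    init_threshold: float = 1e-12

    def validate(self, C: int | None = None) -> None:
        if self.D < 0:
            raise ConfigurationError(f"D must be >= 0, got {self.D}")
        if self.theta is not None:
            if self.theta < 1:
                raise ConfigurationError(f"theta must be >= 1, got {self.theta}")
            if C is not None and self.theta > C:
                raise ConfigurationError(f"theta={self.theta} exceeds vector length C={C}")
        if isinstance(self.schedule, str) and self.schedule not in ("tanh", "literal"):
            raise ConfigurationError(f"unknown decay schedule {self.schedule!r}")


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def variation_center(C: int, D: int, d: int) -> float:
    """Variation center of iteration ``d`` for a vector of length ``C``.

    The first iteration starts at the midpoint C/2; subsequent iterations
    alternate around it with offset (C/D)*floor(d/2), covering both halves
    of the index line evenly over D iterations.
    """
    if not 1 <= d <= D:
        raise ValueError(f"iteration d={d} outside [1, D={D}]")
    if d == 1:
        return C / 2
    return C / 2 + (C / D) * (-1) ** (d - 1) * (d // 2)


def decay_coefficient(D: int, d: int, schedule: str | Mapping[int, float] = "tanh") -> float:
    """Decay coefficient xi of iteration ``d``; controls the window width.

    At d >= 10 the schedule is the constant floor 0.1; for 1 <= d <= 9 the
    default is tanh(2(D-d)/(D+1)), which starts near 1 (0.9270 at d=1 for
    D=10) and decays strictly to 0.1798 at d=9.
    """
    if d < 1:
        raise ValueError(f"iteration d={d} must be >= 1")
    if isinstance(schedule, Mapping):
        try:
            return float(schedule[d])
        except KeyError as exc:
            raise ConfigurationError(f"decay lookup has no entry for d={d}") from exc
    if d >= min(D, 10):  # the floor holds at the final iteration for any D
        return XI_FLOOR
    u = (D - d) / (D + 1)
    if schedule == "tanh":
        return math.tanh(2.0 * u)
    if schedule == "literal":
        return math.tanh(0.75 * u)
    raise ConfigurationError(f"unknown decay schedule {schedule!r}")


def variation_range(center: float, xi: float, C: int) -> tuple[int, int]:
    """Inclusive 1-based index window of half-width ``xi * C / 2``.

    The raw window is [center - xi*C/2, center + xi*C/2 - 1]; endpoints are
    rounded half-up (C/2 is fractional for odd C, so a rounding convention
    is required) and the window is clipped to [1, C].
    """
    if not 0.0 < xi <= 1.0:
        raise ValueError(f"xi must lie in (0, 1], got {xi}")
    half = xi * C / 2
    lo = max(_round_half_up(center - half), 1)
    hi = min(_round_half_up(center + half - 1), C)
    if lo > hi:
        raise DegenerateRangeError(
            f"variation range empty after clipping: center={center}, xi={xi}, C={C}"
        )
    return lo, hi


def gamma_operate(x: np.ndarray, index_range: tuple[int, int]) -> np.ndarray:
    """Flip every bit of ``x`` inside the inclusive 1-based ``index_range``."""
    lo, hi = index_range
    if not (1 <= lo <= hi <= x.size):
        raise ValueError(f"range {index_range} outside [1, {x.size}]")
    out = x.copy()
    out[lo - 1 : hi] ^= 1
    return out


def gamma_correct(x: np.ndarray, theta: int) -> np.ndarray:
    """Cap the active set at ``theta`` one-bits, keeping the smallest indices.

    Positions are P-ascending, so the retained bits are the candidates most
    significant in the differential screen.  Idempotent; never increases
    the population count.
    """
    if theta < 1:
        raise ValueError(f"theta must be >= 1, got {theta}")
    ones = np.flatnonzero(x)
    if ones.size <= theta:
        return x.copy()
    out = np.zeros_like(x)
    out[ones[:theta]] = 1
    return out


def as_selection_vector(bits: Sequence[int] | np.ndarray) -> np.ndarray:
    """Coerce to a uint8 0/1 vector, validating the alphabet."""
    arr = np.asarray(bits, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError("selection vector must be one-dimensional")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("selection vector bits must be 0 or 1")
    return arr
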