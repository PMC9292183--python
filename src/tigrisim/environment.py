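"""Disturbance schedules for periodically and stochastically fluctuating environments.

A disturbance regime is defined by a mean periodicity (3 days = "Fast",
14 days = "Slow" for the *Tigriopus californicus* system) and by whether
events recur deterministically at exact multiples of the period or at
uniformly random days.  Stochastic schedules are event-count matched to
their deterministic analogue so that total disturbance-induced mortality
is comparable between regimes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DisturbanceSchedule",
    "make_deterministic_schedule",
    "make_stochastic_schedule",
]

DETERMINISTIC = "deterministic"
STOCHASTIC = "stochastic"


@dataclass(frozen=True)
class DisturbanceSchedule:
    """Set of integer time-steps (days) at which a juvenile disturbance fires.

    Parameters
    ----------
    event_times
        Strictly increasing integer days, each in ``[1, horizon]``.
    period
        Mean periodicity in days (3 = Fast, 14 = Slow).
    horizon
        Simulation length T in days.
    regime_label
        ``"deterministic"`` or ``"stochastic"``.
    """

    event_times: tuple[int, ...]
    period: int
    horizon: int
    regime_label: str
    _event_set: frozenset = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.regime_label not in (DETERMINISTIC, STOCHASTIC):
            raise ValueError(f"unknown regime_label {self.regime_label!r}")
        times = tuple(int(t) for t in self.event_times)
        if len(set(times)) != len(times):
            raise ValueError("event times must be unique")
        if any(not 1 <= t <= self.horizon for t in times):
            raise ValueError("event times must lie in [1, horizon]")
        if list(times) != sorted(times):
            raise ValueError("event times must be strictly increasing")
        expected = self.horizon // self.period
        if len(times) != expected:
            raise ValueError(
                f"count matching violated: {len(times)} events, "
                f"expected floor(horizon/period) = {expected}"
            )
        object.__setattr__(self, "event_times", times)
        object.__setattr__(self, "_event_set", frozenset(times))

    @property
    def n_events(self) -> int:
        return len(self.event_times)

    def __contains__(self, t: int) -> bool:
        return t in self._event_set

    def to_dict(self) -> dict:
        return {
            "regime_label": self.regime_label,
            "period": self.period,
            "horizon": self.horizon,
            "event_times": list(self.event_times),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DisturbanceSchedule":
        return cls(
            event_times=tuple(d["event_times"]),
            period=int(d["period"]),
            horizon=int(d["horizon"]),
            regime_label=d["regime_label"],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DisturbanceSchedule":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _check_params(period: int, horizon: int) -> None:
    if period < 1:
        raise ValueError(f"period must be a positive integer, got {period}")
    if horizon < 1:
        raise ValueError(f"horizon must be a positive integer, got {horizon}")


def make_deterministic_schedule(period: int, horizon: int) -> DisturbanceSchedule:
    """Events at every integer multiple of ``period`` not exceeding ``horizon``.

    The first disturbance fires after one full period has elapsed, i.e. at
    ``t = period``, never at ``t = 0``.
    """
    _check_params(period, horizon)
    times = tuple(range(period, horizon + 1, period))
    return DisturbanceSchedule(times, period, horizon, DETERMINISTIC)


def make_stochastic_schedule(
    period: int, horizon: int, rng: np.random.Generator | int
) -> DisturbanceSchedule:
    """Event-count-matched stochastic analogue of the deterministic schedule.

    Draws exactly ``floor(horizon / period)`` distinct integer days uniformly
    without replacement from ``{1, ..., horizon}``.  The simulator advances in
    whole-day steps, so sampling on the integer grid without replacement makes
    two events in one step impossible and the count matching exact.
    """
    _check_params(period, horizon)
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n_events = horizon // period
    times = rng.choice(np.arange(1, horizon + 1), size=n_events, replace=False)
    return DisturbanceSchedule(tuple(sorted(int(t) for t in times)), period, horizon, STOCHASTIC)
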