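"""Thermal-inactivation curves and the half-activity retention temperature.

Residual activity after heat treatment is derived from hemagglutination
titers (serial two-fold dilutions) relative to an unheated control; the
half-activity retention temperature T_m is read off the curve at the 0.5
crossing by linear interpolation, without any model fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "HemagglutinationSeries",
    "InactivationCurve",
    "HalfActivityTemperature",
    "NoCrossingError",
    "residual_activity_curve",
    "half_activity_temperature",
]


class NoCrossingError(ValueError):
    """The curve never crosses 50% residual activity within its range."""


@dataclass(frozen=True)
class HemagglutinationSeries:
    """Per-temperature titers plus the unheated control titer.

    A titer is the last two-fold dilution step still agglutinating
    (non-negative integer); ``None`` means no agglutination at any dilution.
    """

    temperatures: tuple[float, ...]
    titers: tuple[int | None, ...]
    control_titer: int

    def __post_init__(self) -> None:
        if self.control_titer is None or self.control_titer <= 0:
            raise ValueError("control titer must be a positive integer")
        if len(self.temperatures) != len(self.titers):
            raise ValueError("temperatures and titers differ in length")
        if any(t is not None and t < 0 for t in self.titers):
            raise ValueError("titers must be non-negative")


@dataclass(frozen=True)
class InactivationCurve:
    """Residual activity (fraction of unheated control) vs temperature."""

    temperatures: tuple[float, ...]
    activities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.temperatures) != len(self.activities):
            raise ValueError("temperatures and activities differ in length")
        if len(self.temperatures) < 2:
            raise ValueError("need at least two points")
        t = np.asarray(self.temperatures)
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        a = np.asarray(self.activities)
        if np.any((a < 0) | (a > 1)):
            raise ValueError("activities must lie in [0, 1]")


@dataclass(frozen=True)
class HalfActivityTemperature:
    t_m: float
    method: str


def residual_activity_curve(series: HemagglutinationSeries) -> InactivationCurve:
    """Convert titers to residual activities 2^(titer - control), capped at 1."""
    activities = []
    for titer in series.titers:
        if titer is None:
            activities.append(0.0)
        else:
            activities.append(min(1.0, 2.0 ** (titer - series.control_titer)))
    return InactivationCurve(tuple(series.temperatures), tuple(activities))


def _isotonic_decreasing(values: np.ndarray) -> np.ndarray:
    # pool-adjacent-violators for a non-increasing fit
    y = list(-values)
    # blocks of (sum, count)
    blocks: list[list[float]] = []
    for v in y:
        blocks.append([v, 1.0])
        while len(blocks) > 1 and blocks[-2][0] / blocks[-2][1] > blocks[-1][0] / blocks[-1][1]:
            s, c = blocks.pop()
            blocks[-1][0] += s
            blocks[-1][1] += c
    out: list[float] = []
    for s, c in blocks:
        out.extend([s / c] * int(c))
    return -np.asarray(out)


def half_activity_temperature(
    curve: InactivationCurve,
    threshold: float = 0.5,
    smooth: bool = False,
) -> HalfActivityTemperature:
    """Temperature of the downward crossing of ``threshold``.

    The crossing is taken after the last sampled temperature whose activity
    is >= threshold (robust to non-monotone assay noise), with linear
    interpolation between the flanking points. A sample exactly at the
    threshold returns its own temperature. With ``smooth=True`` the curve is
    first projected onto a non-increasing fit (pool-adjacent-violators).

    Raises
    ------
    NoCrossingError
        If the curve lies entirely above or entirely below the threshold;
        no extrapolation is ever attempted.
    """
    temps = np.asarray(curve.temperatures, dtype=float)
    acts = np.asarray(curve.activities, dtype=float)
    method = "linear-interpolation/last-crossing"
    if smooth:
        acts = _isotonic_decreasing(acts)
        method = "isotonic+" + method

    above = np.nonzero(acts >= threshold)[0]
    if above.size == 0:
        raise NoCrossingError("activity below threshold over the whole range")
    i = above[-1]
    if acts[i] == threshold:
        return HalfActivityTemperature(float(temps[i]), method)
    if i == len(temps) - 1:
        raise NoCrossingError("activity never drops below threshold in range")
    a0, a1 = acts[i], acts[i + 1]
    t0, t1 = temps[i], temps[i + 1]
    t_m = t0 + (a0 - threshold) / (a0 - a1) * (t1 - t0)
    return HalfActivityTemperature(float(t_m), method)
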