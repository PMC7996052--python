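"""Class-specific root elongation curves.

Each root class elongates along an emergence → peak → decline rate profile:
the rate ramps up smoothly (quintic) from zero to the class peak over
``rise_days`` (default 2 d, so the maximum is reached at the early edge of
the observed 2–10 day window), holds the peak, and then falls linearly to
zero over ``decline_window`` days.  The onset of the decline is solved so
that the lifetime integral of the rate equals the class maximum length —
the published maximum lengths and peak rates therefore pin the whole curve
(e.g. the 45 cm fast nodal root excavated at an estimated age of 21 days,
whose mean rate 45/21 = 2.14 cm day⁻¹ is the class peak).

A per-axis lognormal multiplier scales the rate (and hence the final
length) without changing the timing of the phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import RootClassParams

__all__ = ["GrowthCurve", "elongation_rate", "mean_growth_rate"]


def mean_growth_rate(length_cm: float, age_days: float) -> float:
    """Average elongation rate of a root of known length and age (cm/day)."""
    if age_days <= 0:
        raise ValueError("age must be > 0")
    return length_cm / age_days


@dataclass(frozen=True)
class GrowthCurve:
    """Deterministic elongation profile of one root class (multiplier 1)."""

    peak: float          # cm day⁻¹
    max_length: float    # cm
    rise: float = 2.0    # days
    window: float = 1.0  # days

    @classmethod
    def for_class(cls, p: RootClassParams) -> "GrowthCurve":
        return cls(peak=p.peak_growth_rate, max_length=p.max_length,
                   rise=p.rise_days, window=p.decline_window)

    @property
    def decline_start(self) -> float:
        # rise loses rise/6 day-equivalents of peak growth, the decline
        # window loses window/2; solved so the lifetime integral is max_length
        td = self.max_length / self.peak + self.rise / 6.0 - self.window / 2.0
        if td < self.rise:
            raise ValueError(
                "max_length too short for the rise phase; shorten rise_days")
        return td

    @property
    def lifetime(self) -> float:
        return self.decline_start + self.window

    def rate(self, age, multiplier=1.0):
        """Elongation rate (cm day⁻¹) at axis age (days)."""
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("axis age must be >= 0")
        td = self.decline_start
        up = np.where(age < self.rise, 1.0 - (1.0 - np.minimum(age, self.rise) / self.rise) ** 5, 1.0)
        down = np.clip(1.0 - (age - td) / self.window, 0.0, 1.0)
        out = self.peak * up * down * multiplier
        return float(out) if out.ndim == 0 else out

    def cumulative(self, age, multiplier=1.0):
        """Length grown by axis age (cm); piecewise-analytic integral."""
        age = np.asarray(age, dtype=float)
        td = self.decline_start
        w = self.window
        r = self.rise
        a = np.clip(age, 0.0, None)
        # rise phase integral: p*(a - r/6*(1-(1-a/r)^6))
        a_r = np.minimum(a, r)
        cum = a_r - (r / 6.0) * (1.0 - (1.0 - a_r / r) ** 6)
        # plateau
        cum = cum + np.clip(np.minimum(a, td) - r, 0.0, None)
        # decline: integral of (1-(a-td)/w) from td
        a_d = np.clip(np.minimum(a, td + w) - td, 0.0, None)
        cum = cum + a_d - a_d ** 2 / (2.0 * w)
        out = self.peak * cum * multiplier
        return float(out) if out.ndim == 0 else out

    def inverse_cumulative(self, length, multiplier=1.0):
        """Axis age (days) at which the grown length reaches ``length``.

        Lengths beyond the lifetime total map to ``inf``.
        """
        length = np.asarray(length, dtype=float)
        grid_t, grid_l = _inverse_grid(self)
        total = grid_l[-1] * multiplier
        out = np.interp(length / multiplier, grid_l, grid_t)
        out = np.where(length > total, np.inf, out)
        return out if out.ndim else float(out)


from functools import lru_cache


@lru_cache(maxsize=64)
def _inverse_grid(curve: GrowthCurve) -> tuple[np.ndarray, np.ndarray]:
    t = np.linspace(0.0, curve.lifetime, 4096)
    return t, curve.cumulative(t, 1.0)


def elongation_rate(class_params: RootClassParams, axis_age: float,
                    multiplier: float = 1.0) -> float:
    """Elongation rate (cm day⁻¹) of an axis of ``class_params`` at an age."""
    if axis_age < 0:
        raise ValueError("axis age must be >= 0")
    return float(GrowthCurve.for_class(class_params).rate(axis_age, multiplier))
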