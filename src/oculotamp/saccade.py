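"""Saccadic eye-rotation waveform.

The angular displacement during a saccade is modeled as a quintic
polynomial theta(t) = c0 + c1 t + ... + c5 t^5 on [0, T], after which the eye
is held fixed for one further window of length T so the fluid's deceleration
can be observed.  The published coefficient set covers c0..c4 (degrees and
powers of seconds); the quintic term is recovered from the requirement that
the eye is at rest when the rotation ends, d(theta)/dt(T) = 0, which together
with c0 = c1 = 0 makes displacement, velocity and acceleration continuous
across both endpoints of the motion.

Default waveform: 50 deg amplitude, T = 0.137 s, peak angular velocity
~547 deg/s reached ~0.034 s after onset — a large, fast human saccade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .geometry import SUPERIOR

#: Published quintic coefficients c0..c4 [deg, deg/s, ..., deg/s^4].
DEFAULT_COEFFICIENTS = (0.0, 0.0, 2.01e4, -3.29e5, 2.30e6)
DEFAULT_DURATION = 0.137  # s
DEFAULT_AMPLITUDE = 50.0  # deg


def complete_coefficients(coeffs: tuple[float, ...], duration: float) -> float:
    """Return c5 such that the angular velocity vanishes at t = duration.

    d(theta)/dt(T) = c1 + 2 c2 T + 3 c3 T^2 + 4 c4 T^3 + 5 c5 T^4 = 0.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    c0, c1, c2, c3, c4 = coeffs
    T = duration
    return -(c1 + 2 * c2 * T + 3 * c3 * T**2 + 4 * c4 * T**3) / (5 * T**4)


@dataclass
class SaccadeWave:
    """Quintic saccade waveform with kinematic evaluators.

    Angles in degrees, times in seconds.  ``theta`` is held at its final
    value on (T, 2T]; velocity and acceleration are zero there.
    """

    coefficients: tuple[float, ...] = DEFAULT_COEFFICIENTS
    duration: float = DEFAULT_DURATION
    post_saccade_window: float | None = None
    rotation_axis: np.ndarray = field(default_factory=lambda: SUPERIOR.copy())

    def __post_init__(self) -> None:
        if len(self.coefficients) == 5:
            c5 = complete_coefficients(tuple(self.coefficients), self.duration)
            self.coefficients = tuple(self.coefficients) + (c5,)
        elif len(self.coefficients) != 6:
            raise ValueError("expected 5 (c0..c4) or 6 (c0..c5) coefficients")
        if self.post_saccade_window is None:
            self.post_saccade_window = self.duration
        self.rotation_axis = np.asarray(self.rotation_axis, dtype=float)
        self.rotation_axis /= np.linalg.norm(self.rotation_axis)
        self._poly = np.polynomial.Polynomial(self.coefficients)
        self._dpoly = self._poly.deriv()
        self._ddpoly = self._dpoly.deriv()

    # -- evaluators --------------------------------------------------------
    @property
    def total_time(self) -> float:
        return self.duration + self.post_saccade_window

    @property
    def amplitude(self) -> float:
        """Total angular displacement theta(T) [deg]."""
        return float(self._poly(self.duration))

    def _check_domain(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-12) or np.any(t > self.total_time + 1e-12):
            raise ValueError(f"time outside [0, {self.total_time:.4f}] s")
        return t

    def theta(self, t):
        """Angular displacement [deg]."""
        t = self._check_domain(t)
        out = np.where(t <= self.duration, self._poly(np.minimum(t, self.duration)), self.amplitude)
        return out if out.ndim else float(out)

    def omega(self, t):
        """Angular velocity [deg/s]."""
        t = self._check_domain(t)
        out = np.where(t <= self.duration, self._dpoly(np.minimum(t, self.duration)), 0.0)
        return out if out.ndim else float(out)

    def alpha(self, t):
        """Angular acceleration [deg/s^2]."""
        t = self._check_domain(t)
        out = np.where(t <= self.duration, self._ddpoly(np.minimum(t, self.duration)), 0.0)
        return out if out.ndim else float(out)

    def peak_velocity(self) -> tuple[float, float]:
        """(t_peak [s], omega_peak [deg/s]): global maximum of omega on [0, T].

        Located by bracketing sign changes of the acceleration on a dense
        grid and polishing each with a root find.
        """
        tt = np.linspace(0.0, self.duration, 2049)
        aa = self._ddpoly(tt)
        candidates = [0.0, self.duration]
        sign_change = np.nonzero(np.diff(np.sign(aa)) != 0)[0]
        for i in sign_change:
            if aa[i] == 0.0:
                candidates.append(tt[i])
            else:
                candidates.append(brentq(self._ddpoly, tt[i], tt[i + 1]))
        vals = [float(self._dpoly(t)) for t in candidates]
        k = int(np.argmax(vals))
        return float(candidates[k]), vals[k]

    def time_grid(self, dt: float = 1e-3) -> np.ndarray:
        """Uniform sampling of [0, 2T] with step dt (endpoint included)."""
        n = int(round(self.total_time / dt))
        return np.linspace(0.0, n * dt, n + 1)

    def table(self, dt: float = 1e-3) -> "pd.DataFrame":
        """Tidy kinematics table: t, theta, omega, alpha."""
        import pandas as pd

        t = self.time_grid(dt)
        return pd.DataFrame(
            {"time_s": t, "theta_deg": self.theta(t), "omega_deg_s": self.omega(t), "alpha_deg_s2": self.alpha(t)}
        )
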