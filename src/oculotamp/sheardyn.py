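"""Reduced-order saccadic wall shear: per-vertex unsteady Stokes layers.

During a saccade the eye wall rotates while the tamponade lags, shearing the
fluid layer at the wall.  Instead of a two-phase Navier-Stokes solve, each
wall vertex is treated as an impulsively moved flat plate under the locally
contacting fluid (oil where the static equilibrium wets the wall, aqueous
elsewhere), a good approximation while the viscous diffusion length
sqrt(nu * T) stays small against the chamber radius.  The wall traction
follows from Duhamel superposition over the Rayleigh (Stokes-first-problem)
step response:

    tau(t) = sqrt(rho * mu / pi) * int_0^t  U'(s) / sqrt(t - s) ds,

evaluated with a product-integration rule that integrates the endpoint
singularity exactly on every step.  Because the wall speed is separable,
U(x, t) = omega(t) * d(x), a single convolution of the angular-velocity
history serves every vertex.

The traction vector lies along the local wall-velocity direction and opposes
the wall during acceleration; after the stop the convolution keeps a
same-signed tail as the fluid's momentum drags the now-immobile wall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .equilibrium import EquilibriumState, FluidPair
from .geometry import EyeGeometry
from .saccade import SaccadeWave

MM = 1e-3  # mm -> m


class ConsistencyError(ValueError):
    """Raised when a mesh and an equilibrium state do not belong together."""


@dataclass
class FluidAssignment:
    """Per-vertex fluid properties frozen for the saccade duration."""

    viscosity: np.ndarray  # Pa s
    density: np.ndarray  # kg/m^3
    is_oil: np.ndarray  # bool

    @staticmethod
    def from_equilibrium(state: EquilibriumState, fluids: FluidPair) -> "FluidAssignment":
        wet = np.asarray(state.wet, dtype=bool)
        mu = np.where(wet, fluids.oil_viscosity, fluids.aqueous_viscosity) * 1e-3
        rho = np.where(wet, fluids.oil_density, fluids.aqueous_density)
        return FluidAssignment(viscosity=mu, density=rho, is_oil=wet)


@dataclass
class TractionSeries:
    """Wall traction sampled on a uniform time grid.

    ``signed_magnitude[n, v]`` is the traction component [Pa] along the unit
    ``direction[v]`` (the local wall-velocity direction); the full vector is
    their product.  ``viscosity`` records the per-vertex fluid used, for
    shear-rate conversion.
    """

    times: np.ndarray  # (nt,) s
    signed_magnitude: np.ndarray  # (nt, nv) Pa
    direction: np.ndarray  # (nv, 3)
    viscosity: np.ndarray  # (nv,) Pa s
    density: np.ndarray  # (nv,) kg/m^3

    @property
    def n_vertices(self) -> int:
        return self.signed_magnitude.shape[1]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.signed_magnitude)

    def vectors(self, time_index: int) -> np.ndarray:
        return self.signed_magnitude[time_index][:, None] * self.direction


def wall_velocity_series(
    geom: EyeGeometry, wave: SaccadeWave, dt: float = 1e-3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-vertex wall speed history for a rigid rotation about the wave axis.

    Returns ``(times, speed, direction)`` with speed in m/s: speed(x, t) =
    omega(t) [rad/s] * distance-to-axis(x) [m]; direction = axis x position,
    tangent to the wall, zero on the rotation axis.
    """
    axis = wave.rotation_axis
    times = wave.time_grid(dt)
    omega = np.radians(wave.omega(times))  # rad/s
    x = geom.vertices * MM
    perp = x - np.outer(x @ axis, axis)
    d = np.linalg.norm(perp, axis=1)
    tangent = np.cross(np.broadcast_to(axis, x.shape), x)
    norm = np.linalg.norm(tangent, axis=1)
    direction = np.zeros_like(tangent)
    on_axis = norm < 1e-12
    direction[~on_axis] = tangent[~on_axis] / norm[~on_axis, None]
    return times, np.outer(omega, d), direction


def _duhamel_convolution(du: np.ndarray, dt: float) -> np.ndarray:
    """Product-integration convolution of a rate history with 1/sqrt(t-s).

    ``du`` holds per-step increments of the velocity (piecewise-linear U);
    returns g with g[n] = int_0^{t_n} U'(s) (t_n - s)^{-1/2} ds, the endpoint
    singularity integrated exactly on each step.
    """
    n = len(du) + 1
    m = np.arange(n)
    kernel = 2.0 * (np.sqrt((m + 1) * dt) - np.sqrt(m * dt)) / dt
    g = np.zeros(n)
    full = np.convolve(du, kernel)[: n - 1]
    g[1:] = full
    return g


def stokes_wall_stress(
    u_history: np.ndarray, dt: float, viscosity: float, density: float
) -> np.ndarray:
    """Traction-magnitude history [Pa] of a semi-infinite Stokes layer.

    ``u_history`` is the wall speed on a uniform grid with ``u[0] = 0``.
    For a step to U0 this reproduces U0*sqrt(rho*mu/(pi*t)); for a long
    sinusoid, amplitude U0*sqrt(rho*mu*omega) with a 45 deg phase lead.
    """
    u = np.asarray(u_history, dtype=float)
    if abs(u[0]) > 0:
        raise ValueError("wall speed history must start from rest")
    g = _duhamel_convolution(np.diff(u), dt)
    return np.sqrt(density * viscosity / np.pi) * g


def finite_slab_wall_stress(
    u_history: np.ndarray,
    dt: float,
    viscosity: float,
    density: float,
    gap: float,
    n_cells: int = 80,
) -> np.ndarray:
    """Wall stress from 1D diffusion across a finite fluid gap [Pa].

    Backward-Euler time stepping of du/dt = nu d2u/dy2 on [0, gap] with the
    moving wall at y=0 and a stress-free far boundary; a sensitivity variant
    of the semi-infinite model for vertices close to the rotation axis.
    """
    u = np.asarray(u_history, dtype=float)
    nu = viscosity / density
    dy = gap / n_cells
    r = nu * dt / dy**2
    n = n_cells  # interior + far nodes; wall node is a boundary condition
    ab = np.zeros((3, n))
    ab[0, 1:] = -r
    ab[1, :] = 1.0 + 2.0 * r
    ab[1, -1] = 1.0 + r  # stress-free: ghost node mirrors
    ab[2, :-1] = -r
    field = np.zeros(n)
    tau = np.zeros(len(u))
    for k in range(1, len(u)):
        rhs = field.copy()
        rhs[0] += r * u[k]
        field = solve_banded((1, 1), ab, rhs)
        tau[k] = viscosity * (u[k] - field[0]) / dy
    return tau


def simulate_saccade_shear(
    geom: EyeGeometry,
    equilibrium: EquilibriumState,
    fluids: FluidPair,
    wave: SaccadeWave,
    dt: float = 1e-3,
) -> TractionSeries:
    """Wall-traction time series for one oil/fill/posture configuration.

    The fluid seen by each vertex is frozen from the equilibrium wet map;
    the separable wall kinematics let one Duhamel convolution of the
    angular-velocity history serve all vertices.
    """
    if len(equilibrium.wet) != len(geom.vertices):
        raise ConsistencyError("equilibrium state does not match this mesh")
    assign = FluidAssignment.from_equilibrium(equilibrium, fluids)
    times = wave.time_grid(dt)
    omega = np.radians(wave.omega(times))
    g = _duhamel_convolution(np.diff(omega), dt)  # rad/s per sqrt(s)
    axis = wave.rotation_axis
    x = geom.vertices * MM
    d = np.linalg.norm(x - np.outer(x @ axis, axis), axis=1)
    _, _, direction = wall_velocity_series(geom, wave, dt)
    prefac = np.sqrt(assign.density * assign.viscosity / np.pi) * d
    signed = -np.outer(g, prefac)  # opposes the wall during acceleration
    return TractionSeries(
        times=times,
        signed_magnitude=signed,
        direction=direction,
        viscosity=assign.viscosity,
        density=assign.density,
    )
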