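"""Seeded synthetic fixtures with built-in analytic oracles.

Every generator returns, alongside the data, the closed-form values any
downstream metric must reproduce, so each pipeline stage is testable without
external data.  The traction fixture emulates the separable space-time
structure of saccadic wall shear, tau(x, t) = A(x) b(t) e(x): a smooth
positive seeded amplitude field (low-order spherical harmonics, so extrema
are stable under meshing), a shared time profile, and the tangential
direction field of a rigid rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibrium import _flat_cap_ratio
from .geometry import HEMISPHERES, SUPERIOR, EyeGeometry
from .metrics import _mask
from .sheardyn import TractionSeries


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible fixture request: same spec + seed, same bytes."""

    seed: int
    kind: str  # separable_traction | unit_sphere | analytic_cap | posture_sweep
    parameters: dict = field(default_factory=dict)


def _real_spherical_harmonics(points: np.ndarray, lmax: int) -> np.ndarray:
    """Real low-order harmonic basis evaluated on unit directions, (n, nbasis)."""
    from scipy.special import sph_harm_y

    u = points / np.linalg.norm(points, axis=1)[:, None]
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.arctan2(u[:, 1], u[:, 0])
    cols = []
    for ell in range(lmax + 1):
        for m in range(0, ell + 1):
            y = sph_harm_y(ell, m, theta, phi)
            cols.append(y.real)
            if m > 0:
                cols.append(y.imag)
    return np.column_stack(cols)


def two_bump_profile(times: np.ndarray, centers=(0.03, 0.145), widths=(0.012, 0.015), amps=(1.0, 0.8)) -> np.ndarray:
    """Time profile with exactly two well-separated Gaussian maxima."""
    t = np.asarray(times)
    out = np.zeros_like(t)
    for c, w, a in zip(centers, widths, amps):
        out += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    return out


def separable_traction_fixture(
    geom: EyeGeometry,
    seed: int = 0,
    dt: float = 1e-3,
    t_end: float = 0.274,
    profile: np.ndarray | None = None,
    lmax: int = 3,
    viscosity: float = 1.0,
    density: float = 980.0,
    vertical_axis: np.ndarray = SUPERIOR,
) -> tuple[TractionSeries, dict]:
    """Seeded separable traction series plus the closed-form metric oracle.

    The amplitude field is A(x) = exp(0.5 f(x)) with f a seeded combination
    of real spherical harmonics up to degree ``lmax`` — strictly positive and
    smooth, so regional maxima are well defined.  Oracle values follow from
    the factorization: IMSS_r(t) = max_r(A) |b(t)|, PMSS(x) = A(x) max|b|,
    ARSS_r(t) = area-mean_r(A) |b(t)|, IMSR_r(t) = IMSS_r(t)/viscosity, and
    VASS(x) = A(x) mean(b) (e(x)·vertical).
    """
    rng = np.random.default_rng(seed)
    n = int(round(t_end / dt))
    times = np.linspace(0.0, n * dt, n + 1)
    b = two_bump_profile(times) if profile is None else np.asarray(profile, dtype=float)
    if len(b) != len(times):
        raise ValueError("profile must be sampled on the fixture time grid")

    basis = _real_spherical_harmonics(geom.vertices, lmax)
    coeffs = rng.normal(size=basis.shape[1]) / np.sqrt(basis.shape[1])
    amplitude = np.exp(0.5 * (basis @ coeffs))

    axis = np.asarray(SUPERIOR, dtype=float)
    tangent = np.cross(np.broadcast_to(axis, geom.vertices.shape), geom.vertices)
    norm = np.linalg.norm(tangent, axis=1)
    direction = np.zeros_like(tangent)
    ok = norm > 1e-12
    direction[ok] = tangent[ok] / norm[ok, None]
    amplitude[~ok] = 0.0  # no defined tangential direction on the axis

    series = TractionSeries(
        times=times,
        signed_magnitude=np.outer(b, amplitude),
        direction=direction,
        viscosity=np.full(len(amplitude), float(viscosity)),
        density=np.full(len(amplitude), float(density)),
    )

    v = np.asarray(vertical_axis, dtype=float)
    v = v / np.linalg.norm(v)
    weights = geom.vertex_areas()
    oracle: dict = {
        "amplitude": amplitude,
        "profile": b,
        "pmss": amplitude * np.abs(b).max(),
        "vass": amplitude * b.mean() * (direction @ v),
        "imss": {},
        "arss": {},
        "imsr": {},
    }
    for region in ("macula", "postequatorial", "preequatorial", "retina"):
        for hemi in ("both",) + HEMISPHERES:
            m = _mask(geom, region, hemi)
            w = weights[m] / weights[m].sum()
            oracle["imss"][(region, hemi)] = amplitude[m].max() * np.abs(b)
            oracle["arss"][(region, hemi)] = float(amplitude[m] @ w) * np.abs(b)
            oracle["imsr"][(region, hemi)] = amplitude[m].max() * np.abs(b) / viscosity
    return series, oracle


def analytic_cap_fixture(fill_list, eye_radius: float = 12.0) -> pd.DataFrame:
    """Closed-form flat-interface table: fill, plane height, covered fraction.

    For a lens-free sphere the oil cap of height ratio x = h/R satisfies
    x^2 (3 - x) = 4 fill; coverage = x/2 and the plane sits at R (1 - x).
    """
    rows = []
    for fill in fill_list:
        x = _flat_cap_ratio(float(fill))
        rows.append(
            {
                "fill": float(fill),
                "plane_height_mm": eye_radius * (1.0 - x),
                "covered_fraction": 0.5 * x,
            }
        )
    return pd.DataFrame(rows)


OILS = (1000.0, 5000.0)
FILLS = (0.80, 0.85, 0.90, 0.95, 1.00)
POSTURE_NAMES = ("standing", "tilt45", "supine")


def posture_sweep_fixture(
    oils=OILS, fills=FILLS, postures=POSTURE_NAMES
) -> pd.DataFrame:
    """The full experimental grid: oils x fills x postures (30 by default)."""
    rows = [
        {"oil_mPa_s": o, "fill": f, "posture": p}
        for o in oils
        for f in fills
        for p in postures
    ]
    return pd.DataFrame(rows)


def static_equilibrium_grid(fills=FILLS, postures=POSTURE_NAMES) -> pd.DataFrame:
    """Unique static solves: equilibrium is viscosity-independent (15 rows)."""
    return posture_sweep_fixture(oils=(None,), fills=fills, postures=postures).drop(
        columns="oil_mPa_s"
    )
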