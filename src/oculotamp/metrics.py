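"""Wall-shear summary metrics over anatomical regions.

Five summary statistics condense a traction time series:

* IMSS — instantaneous maximum shear stress: per-instant maximum of the
  traction magnitude over a region [Pa].
* PMSS — pointwise maximum shear stress: per-vertex maximum over time [Pa].
* VASS — vertical average shear stress: per-vertex time average of the
  traction component along the vertical (anti-gravity) axis [Pa, signed].
* ARSS — average regional shear stress: per-instant area-weighted mean of
  the traction magnitude over a region [Pa].
* IMSR — instantaneous maximum shear rate: like IMSS but on the shear-rate
  field traction/(factor * viscosity) [1/s]; ``rate_convention_factor`` of 2
  selects the strain-rate-tensor-magnitude convention instead of the
  engineering rate.

Spatial means are area-weighted with barycentric vertex areas, never plain
vertex counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import HEMISPHERES, RETINA_REGIONS, EyeGeometry
from .sheardyn import TractionSeries


class EmptyRegionError(ValueError):
    """Raised when a metric is requested over a region with no vertices."""


def _mask(geom: EyeGeometry, region: str, hemisphere: str) -> np.ndarray:
    m = geom.region_mask(region, hemisphere)
    if not np.any(m):
        raise EmptyRegionError(f"region {region}/{hemisphere} has no vertices")
    return m


def imss(series: TractionSeries, geom: EyeGeometry, region: str, hemisphere: str = "both") -> np.ndarray:
    """Per-instant max traction magnitude over the region [Pa], shape (nt,)."""
    return series.magnitude()[:, _mask(geom, region, hemisphere)].max(axis=1)


def pmss(series: TractionSeries) -> np.ndarray:
    """Per-vertex max traction magnitude over time [Pa], shape (nv,)."""
    return series.magnitude().max(axis=0)


def vass(series: TractionSeries, vertical_axis: np.ndarray) -> np.ndarray:
    """Per-vertex signed time-mean of the vertical traction component [Pa]."""
    v = np.asarray(vertical_axis, dtype=float)
    v = v / np.linalg.norm(v)
    vertical_component = series.signed_magnitude * (series.direction @ v)[None, :]
    return vertical_component.mean(axis=0)


def arss(series: TractionSeries, geom: EyeGeometry, region: str, hemisphere: str = "both") -> np.ndarray:
    """Per-instant area-weighted mean traction magnitude over the region [Pa]."""
    m = _mask(geom, region, hemisphere)
    w = geom.vertex_areas()[m]
    return series.magnitude()[:, m] @ (w / w.sum())


def imsr(
    series: TractionSeries,
    geom: EyeGeometry,
    region: str,
    hemisphere: str = "both",
    rate_convention_factor: float = 1.0,
) -> np.ndarray:
    """Per-instant max shear rate over the region [1/s]."""
    if np.any(series.viscosity <= 0):
        raise ValueError("per-vertex viscosity must be positive")
    rate = series.magnitude() / (rate_convention_factor * series.viscosity)[None, :]
    return rate[:, _mask(geom, region, hemisphere)].max(axis=1)


@dataclass
class MetricsBundle:
    """All five metrics for one configuration.

    ``timeseries`` is tidy: time_s, region, hemisphere, imss_Pa, arss_Pa,
    imsr_per_s.  ``pmss`` and ``vass`` are per-vertex fields.
    """

    timeseries: pd.DataFrame
    pmss: np.ndarray
    vass: np.ndarray


DEFAULT_REGIONS = RETINA_REGIONS + ("ora", "lens", "retina")


def compute_metrics(
    series: TractionSeries,
    geom: EyeGeometry,
    vertical_axis: np.ndarray,
    regions: tuple[str, ...] = DEFAULT_REGIONS,
    hemispheres: tuple[str, ...] = ("both",) + HEMISPHERES,
    rate_convention_factor: float = 1.0,
) -> MetricsBundle:
    """Evaluate every metric; regions without vertices are skipped silently
    (a lens-free build has no lens region)."""
    frames = []
    for region in regions:
        for hemi in hemispheres:
            try:
                s_max = imss(series, geom, region, hemi)
            except EmptyRegionError:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": series.times,
                        "region": region,
                        "hemisphere": hemi,
                        "imss_Pa": s_max,
                        "arss_Pa": arss(series, geom, region, hemi),
                        "imsr_per_s": imsr(series, geom, region, hemi, rate_convention_factor),
                    }
                )
            )
    return MetricsBundle(
        timeseries=pd.concat(frames, ignore_index=True),
        pmss=pmss(series),
        vass=vass(series, vertical_axis),
    )


def count_local_maxima(values: np.ndarray, prominence_fraction: float = 0.1) -> int:
    """Number of interior local maxima above a fraction of the global peak.

    Used to verify the bimodal (start/stop) shape of IMSS and IMSR histories.
    """
    v = np.asarray(values, dtype=float)
    peak = v.max()
    if peak <= 0:
        return 0
    inner = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]) & (v[1:-1] > prominence_fraction * peak)
    return int(np.count_nonzero(inner))
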