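"""Configuration and orchestration of the full tamponade sweep.

A run couples one geometry with the grid of oils x fills x postures (30
dynamic configurations by default, sharing 15 viscosity-independent static
equilibria), producing tidy contact-fraction and shear-metric tables plus a
machine-readable manifest.  All defaults reproduce the published study
configuration; any override travels through :class:`RunConfig` and is
logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import fixtures
from .equilibrium import (
    EquilibriumState,
    FluidPair,
    Posture,
    contact_fractions,
    solve_capillary_interface,
    solve_flat_interface,
)
from .geometry import build_chamber_mesh, segment_regions
from .metrics import compute_metrics
from .saccade import SaccadeWave
from .sheardyn import simulate_saccade_shear

log = logging.getLogger("oculotamp")


@dataclass
class GeometryConfig:
    eye_radius: float = 12.0
    lens_radius: float | None = 5.5
    lens_center_offset: float | None = 13.0
    resolution: float = 0.45
    macula_half_angle: float = 20.0
    ora_limit_angle: float = 40.0


@dataclass
class FluidsConfig:
    oil_density: float = 980.0
    aqueous_density: float = 1000.0
    aqueous_viscosity: float = 1.0
    interfacial_tension: float = 0.044
    static_contact_angle: float = 16.2
    advancing_contact_angle: float = 21.2
    receding_contact_angle: float = 11.2
    contact_angle_convention: str = "aqueous"


@dataclass
class SaccadeConfig:
    coefficients: tuple = (0.0, 0.0, 2.01e4, -3.29e5, 2.30e6)
    duration: float = 0.137
    dt: float = 1e-3
    rotation_axis: tuple = (0.0, 1.0, 0.0)


@dataclass
class EquilibriumConfig:
    mode: str = "capillary"  # flat | capillary
    tolerance: float = 1e-4
    fills: tuple = fixtures.FILLS
    postures: tuple = fixtures.POSTURE_NAMES


@dataclass
class MetricsConfig:
    rate_convention_factor: float = 1.0
    regions: tuple = ("macula", "postequatorial", "preequatorial", "ora", "lens", "retina")


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    fluids: FluidsConfig = field(default_factory=FluidsConfig)
    saccade: SaccadeConfig = field(default_factory=SaccadeConfig)
    equilibrium: EquilibriumConfig = field(default_factory=EquilibriumConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    oils: tuple = fixtures.OILS
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for name, cls in (
            ("geometry", GeometryConfig),
            ("fluids", FluidsConfig),
            ("saccade", SaccadeConfig),
            ("equilibrium", EquilibriumConfig),
            ("metrics", MetricsConfig),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = cls(**{k: _tupled(v) for k, v in kwargs[name].items()})
        for k in ("oils",):
            if k in kwargs:
                kwargs[k] = _tupled(kwargs[k])
        return RunConfig(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def fluid_pair(self, oil_viscosity: float = 1000.0) -> FluidPair:
        f = self.fluids
        return FluidPair(
            oil_density=f.oil_density,
            aqueous_density=f.aqueous_density,
            oil_viscosity=oil_viscosity,
            aqueous_viscosity=f.aqueous_viscosity,
            interfacial_tension=f.interfacial_tension,
            static_contact_angle=f.static_contact_angle,
            advancing_contact_angle=f.advancing_contact_angle,
            receding_contact_angle=f.receding_contact_angle,
            contact_angle_convention=f.contact_angle_convention,
        )


def _tupled(v):
    return tuple(v) if isinstance(v, list) else v


def build_geometry(cfg: RunConfig):
    g = cfg.geometry
    geom = build_chamber_mesh(g.eye_radius, g.lens_radius, g.lens_center_offset, g.resolution)
    return segment_regions(geom, g.macula_half_angle, g.ora_limit_angle)


def sweep_configurations(cfg: RunConfig) -> pd.DataFrame:
    """Dynamic sweep grid (oil, fill, posture); 30 rows with defaults."""
    return fixtures.posture_sweep_fixture(cfg.oils, cfg.equilibrium.fills, cfg.equilibrium.postures)


def solve_equilibrium(cfg: RunConfig, geom, fill: float, posture_name: str) -> EquilibriumState:
    posture = Posture.from_name(posture_name)
    if cfg.equilibrium.mode == "flat":
        return solve_flat_interface(geom, fill, posture, cfg.equilibrium.tolerance)
    return solve_capillary_interface(geom, fill, posture, cfg.fluid_pair(), cfg.equilibrium.tolerance)


@dataclass
class PipelineResult:
    config: RunConfig
    contact: pd.DataFrame
    metrics_timeseries: pd.DataFrame
    peak_summary: pd.DataFrame
    failures: list


def run_pipeline(cfg: RunConfig, write: bool = True) -> PipelineResult:
    """Execute geometry -> equilibrium -> saccade -> shear -> metrics.

    Static equilibria are solved once per (fill, posture) and shared by both
    oils.  A failing configuration is logged and skipped; the sweep
    continues.
    """
    logging.basicConfig(level=cfg.log_level)
    geom = build_geometry(cfg)
    wave = SaccadeWave(
        coefficients=tuple(cfg.saccade.coefficients),
        duration=cfg.saccade.duration,
        rotation_axis=np.asarray(cfg.saccade.rotation_axis, dtype=float),
    )
    contact_rows, metric_rows, peak_rows, failures = [], [], [], []
    states: dict[tuple, EquilibriumState] = {}

    for posture_name in cfg.equilibrium.postures:
        for fill in cfg.equilibrium.fills:
            try:
                st = solve_equilibrium(cfg, geom, fill, posture_name)
                states[(posture_name, fill)] = st
                contact_rows.append(contact_fractions(st, geom))
            except Exception as exc:  # keep sweeping
                log.error("equilibrium failed (%s, %s): %s", posture_name, fill, exc)
                failures.append({"stage": "equilibrium", "posture": posture_name, "fill": fill, "error": str(exc)})

    for _, row in sweep_configurations(cfg).iterrows():
        key = (row.posture, row.fill)
        if key not in states:
            continue
        try:
            fluids = cfg.fluid_pair(row.oil_mPa_s)
            series = simulate_saccade_shear(geom, states[key], fluids, wave, cfg.saccade.dt)
            posture = Posture.from_name(row.posture)
            bundle = compute_metrics(
                series,
                geom,
                vertical_axis=posture.up,
                regions=tuple(cfg.metrics.regions),
                rate_convention_factor=cfg.metrics.rate_convention_factor,
            )
            ts = bundle.timeseries.assign(oil_mPa_s=row.oil_mPa_s, fill=row.fill, posture=row.posture)
            metric_rows.append(ts)
            peak = (
                ts.groupby(["region", "hemisphere"], sort=False)
                .agg(peak_imss_Pa=("imss_Pa", "max"), peak_arss_Pa=("arss_Pa", "max"), peak_imsr_per_s=("imsr_per_s", "max"))
                .reset_index()
                .assign(oil_mPa_s=row.oil_mPa_s, fill=row.fill, posture=row.posture)
            )
            peak_rows.append(peak)
        except Exception as exc:
            log.error("dynamics failed (%s): %s", dict(row), exc)
            failures.append({"stage": "dynamics", **{k: row[k] for k in row.index}, "error": str(exc)})

    result = PipelineResult(
        config=cfg,
        contact=pd.concat(contact_rows, ignore_index=True) if contact_rows else pd.DataFrame(),
        metrics_timeseries=pd.concat(metric_rows, ignore_index=True) if metric_rows else pd.DataFrame(),
        peak_summary=pd.concat(peak_rows, ignore_index=True) if peak_rows else pd.DataFrame(),
        failures=failures,
    )
    if write:
        write_results(result)
    return result


def write_results(result: PipelineResult) -> None:
    cfg = result.config
    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    result.contact.to_csv(os.path.join(out, "contact_fractions.csv"), index=False)
    result.peak_summary.to_csv(os.path.join(out, "shear_peak_summary.csv"), index=False)
    result.metrics_timeseries.to_csv(os.path.join(out, "metrics_timeseries.csv"), index=False)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_contact_rows": int(len(result.contact)),
        "n_metric_rows": int(len(result.metrics_timeseries)),
        "failures": result.failures,
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)


def report_tables(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Figure-companion tables: contact vs fill per posture, and per-region
    metric time series; every value traces to a run in the result."""
    tables = {}
    if len(result.contact):
        tables["contact_by_posture"] = result.contact.pivot_table(
            index=["posture", "region", "hemisphere"], columns="fill", values="fraction"
        ).reset_index()
    if len(result.metrics_timeseries):
        tables["metrics_timeseries"] = result.metrics_timeseries
    if len(result.peak_summary):
        tables["peak_summary"] = result.peak_summary
    return tables
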