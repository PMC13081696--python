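"""Config-driven orchestration of the three analyses on fixture geometry.

Each run builds (or loads) geometry, constructs the requested sensor
arrays, assembles lead fields, and writes structured outputs (CSV/JSON)
plus a resolved copy of its configuration with provenance.  All randomness
flows from the single global seed, so a rerun with the same config
reproduces the output files byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .arrays import (DEFAULT_STANDOFF, SensorArray, helmet_layout,
                     make_uniform_array, mean_neighbor_distance)
from .forward import LeadField, assemble_leadfield, exclude_near_boundary
from .geometry import (FixtureConfig, GeometryFixture, concatenate_spaces,
                       make_head_fixture)
from .infocap import (NoiseModel, calibrate_source_variance,
                      information_capacity, itot_sweep, whiten)
from .metrics import (normalize_per_sensor, region_sensitivity_ratio,
                      sensitivity_map, summarize_density)
from .subspace import (geodesic_patches, high_correlation_fraction,
                       patch_to_patch_map, patch_to_whole_map)

log = logging.getLogger("cerebmeg")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

def _default_array_specs() -> list:
    """The six-array comparison set: SQUID helmets and their scalp-projected
    single-axis / triaxial OPM counterparts."""
    return [
        dict(name="squid102", type="squid_mag", n_sensors=102,
             channel_mode="single_axis", standoff=0.022),
        dict(name="squid275", type="squid_axial_grad", n_sensors=275,
             channel_mode="single_axis", standoff=0.022),
        dict(name="opm102", type="opm", n_sensors=102,
             channel_mode="single_axis", standoff=0.005),
        dict(name="opm275", type="opm", n_sensors=275,
             channel_mode="single_axis", standoff=0.005),
        dict(name="triaxial_opm102", type="opm", n_sensors=102,
             channel_mode="triaxial", standoff=0.005),
        dict(name="triaxial_opm275", type="opm", n_sensors=275,
             channel_mode="triaxial", standoff=0.005),
    ]


@dataclass
class RunConfig:
    seed: int = 0
    fixture: dict = field(default_factory=dict)      # FixtureConfig overrides
    arrays: list = field(default_factory=_default_array_specs)
    dipole_moment: float = 1e-7                      # A·m (100 nAm)
    boundary_exclusion: float = 0.003                # m
    patch_radius: float = 0.010                      # m
    seed_spacing: float = 0.015                      # m
    opm_noise_levels_ft: tuple = (10.0, 15.0)        # fT/sqrt(Hz)
    squid_noise_ft: float = 3.0
    bandwidth_hz: float = 1.0
    sensor_counts: tuple = (10, 25, 50, 100, 150, 200)
    n_basis: int = 100
    candidate_vertices: int = 2000
    out_dir: str = "results"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**data)
        cfg.opm_noise_levels_ft = tuple(cfg.opm_noise_levels_ft)
        cfg.sensor_counts = tuple(cfg.sensor_counts)
        return cfg

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write_provenance(cfg: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    payload = dict(config=cfg.resolved(), config_hash=cfg.digest(),
                   package_version=__version__, seed=cfg.seed)
    (outdir / "run_config.json").write_text(json.dumps(payload, indent=2,
                                                       default=str) + "\n")


# --------------------------------------------------------------------------
# Shared construction
# --------------------------------------------------------------------------

@dataclass
class PreparedGeometry:
    fixture: GeometryFixture
    cortex: object
    cerebellum: object
    whole: object


def prepare_geometry(cfg: RunConfig) -> PreparedGeometry:
    t0 = time.perf_counter()
    fixture = make_head_fixture(FixtureConfig(**cfg.fixture), seed=cfg.seed)
    cortex = exclude_near_boundary(fixture.cortex_space, fixture.inner_boundary,
                                   cfg.boundary_exclusion)
    cerebellum = exclude_near_boundary(fixture.cerebellum_space,
                                       fixture.inner_boundary,
                                       cfg.boundary_exclusion)
    whole = concatenate_spaces([cortex, cerebellum])
    log.info("geometry: cortex %d, cerebellum %d sources (%.1fs)",
             len(cortex), len(cerebellum), time.perf_counter() - t0)
    return PreparedGeometry(fixture=fixture, cortex=cortex,
                            cerebellum=cerebellum, whole=whole)


def build_array(fixture: GeometryFixture, spec: dict) -> SensorArray:
    return helmet_layout(fixture.scalp, n_sensors=spec["n_sensors"],
                         standoff=spec.get("standoff",
                                           DEFAULT_STANDOFF[spec["type"]]),
                         sensor_type=spec["type"],
                         channel_mode=spec.get("channel_mode", "single_axis"),
                         name=spec["name"])


def _noise_for(spec: dict, n_channels: int, cfg: RunConfig,
               opm_level_ft: float) -> NoiseModel:
    ft = cfg.squid_noise_ft if spec["type"].startswith("squid") else opm_level_ft
    return NoiseModel.homoscedastic(n_channels, ft * 1e-15, cfg.bandwidth_hz)


# --------------------------------------------------------------------------
# Experiments
# --------------------------------------------------------------------------

def run_sensitivity(cfg: RunConfig, outdir=None) -> dict:
    """Sensitivity maps, density summaries and region ratios for each array."""
    outdir = Path(outdir or cfg.out_dir) / "sensitivity"
    geo = prepare_geometry(cfg)
    summary: dict = {"arrays": {}}
    maps = {}
    for spec in cfg.arrays:
        t0 = time.perf_counter()
        array = build_array(geo.fixture, spec)
        entry = {}
        for region, space in (("cortex", geo.cortex), ("cerebellum", geo.cerebellum)):
            lf = assemble_leadfield(array, space, geo.fixture.sphere_center)
            smap = sensitivity_map(lf, cfg.dipole_moment, array_name=spec["name"])
            per_sensor = normalize_per_sensor(smap, array.n_sensors)
            dens = summarize_density(smap.values)
            entry[region] = dict(
                mean_pT=smap.mean() * 1e12,
                p95_pT=dens.percentile_95 * 1e12,
                density_peak_pT=dens.mode_of_density * 1e12,
                per_sensor_mean_pT=per_sensor.mean() * 1e12,
            )
            maps[(spec["name"], region)] = smap
            from .io import write_overlay

            outdir.mkdir(parents=True, exist_ok=True)
            write_overlay(smap.values, outdir / f"{spec['name']}_{region}.csv",
                          vertex_ids=space.vertex_ids)
        entry["cortex_to_cerebellum_ratio"] = region_sensitivity_ratio(
            maps[(spec["name"], "cortex")], maps[(spec["name"], "cerebellum")])
        summary["arrays"][spec["name"]] = entry
        log.info("sensitivity %s: %.1fs", spec["name"], time.perf_counter() - t0)
    # pairwise cerebellar gains relative to the first array (reference)
    ref = cfg.arrays[0]["name"]
    summary["cerebellar_gain_vs_" + ref] = {
        spec["name"]: region_sensitivity_ratio(maps[(spec["name"], "cerebellum")],
                                               maps[(ref, "cerebellum")])
        for spec in cfg.arrays}
    _write_provenance(cfg, outdir)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def _designated_cortical_patch(patches, cortex, fixture):
    """Cortical seed patch closest to the cerebellum (posterior-most)."""
    cb_dir = np.array([0.0, -1.0, -1.0]) / np.sqrt(2.0)
    ids = {p.seed: i for i, p in enumerate(patches)}
    seed_pos = np.array([cortex.positions[p.seed] for p in patches])
    proj = seed_pos @ cb_dir
    return patches[int(np.argmax(proj))]


def run_correlation(cfg: RunConfig, outdir=None) -> dict:
    """Subspace-correlation maps between cortex and cerebellum per array."""
    outdir = Path(outdir or cfg.out_dir) / "correlation"
    outdir.mkdir(parents=True, exist_ok=True)
    geo = prepare_geometry(cfg)
    ctx_patches = geodesic_patches(geo.cortex, cfg.patch_radius, cfg.seed_spacing)
    cb_patches = geodesic_patches(geo.cerebellum, cfg.patch_radius, cfg.seed_spacing)
    seed_patch = _designated_cortical_patch(ctx_patches, geo.cortex, geo.fixture)
    summary: dict = {"n_cortical_patches": len(ctx_patches),
                     "n_cerebellar_patches": len(cb_patches),
                     "arrays": {}}
    for spec in cfg.arrays:
        t0 = time.perf_counter()
        array = build_array(geo.fixture, spec)
        lf_ctx = assemble_leadfield(array, geo.cortex, geo.fixture.sphere_center)
        lf_cb = assemble_leadfield(array, geo.cerebellum, geo.fixture.sphere_center)
        p2p = patch_to_patch_map(lf_ctx, seed_patch, lf_cb, cb_patches,
                                 cfg.seed_spacing)
        vmap, patch_values, results = patch_to_whole_map(
            lf_ctx, ctx_patches, lf_cb, cfg.seed_spacing)
        frac = high_correlation_fraction(results, threshold=0.5)
        summary["arrays"][spec["name"]] = dict(
            patch_to_patch_mean=p2p.mean(),
            patch_to_whole_mean=float(np.mean(patch_values)),
            high_correlation_percent_mean=float(np.mean(frac)),
        )
        from .io import write_overlay

        write_overlay(p2p.values, outdir / f"{spec['name']}_patch_to_patch.csv",
                      vertex_ids=p2p.location_ids)
        write_overlay(patch_values, outdir / f"{spec['name']}_patch_values.csv",
                      vertex_ids=np.array([p.seed for p in ctx_patches]))
        log.info("correlation %s: %.1fs", spec["name"], time.perf_counter() - t0)
    _write_provenance(cfg, outdir)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def run_infocap(cfg: RunConfig, outdir=None) -> dict:
    """Fixed-array Itot grid plus the sensor-count sweep for uniform arrays."""
    outdir = Path(outdir or cfg.out_dir) / "infocap"
    outdir.mkdir(parents=True, exist_ok=True)
    geo = prepare_geometry(cfg)
    regions = {"cerebellum": geo.cerebellum, "cortex": geo.cortex,
               "whole_brain": geo.whole}
    max_count = max(cfg.sensor_counts)

    # reference for q2: largest uniform SQUID array, whole brain, SQUID noise
    helmet = helmet_layout(geo.fixture.scalp, n_sensors=102, standoff=0.022,
                           sensor_type="squid_mag")
    t0 = time.perf_counter()
    uni_squid = make_uniform_array(geo.fixture.scalp, helmet.positions, max_count,
                                   sensor_type="squid_mag", n_basis=cfg.n_basis,
                                   target_vertices=cfg.candidate_vertices)
    uni_opm = make_uniform_array(geo.fixture.scalp, helmet.positions, max_count,
                                 sensor_type="opm", n_basis=cfg.n_basis,
                                 target_vertices=cfg.candidate_vertices)
    uni_tri = SensorArray(sensors=uni_opm.sensors, channel_mode="triaxial",
                          name=uni_opm.name + "_triaxial")
    log.info("uniform layouts (%d sensors): %.1fs", max_count,
             time.perf_counter() - t0)

    lf_ref = assemble_leadfield(uni_squid, geo.whole, geo.fixture.sphere_center)
    noise_ref = NoiseModel.homoscedastic(lf_ref.n_channels,
                                         cfg.squid_noise_ft * 1e-15,
                                         cfg.bandwidth_hz)
    q2 = calibrate_source_variance(whiten(lf_ref, noise_ref))
    summary: dict = {"q2": q2, "reference": f"uniform_squid_{max_count}",
                     "fixed_arrays": {}, }

    # Table-style grid for the fixed comparison arrays
    for spec in cfg.arrays:
        array = build_array(geo.fixture, spec)
        levels = ([cfg.squid_noise_ft] if spec["type"].startswith("squid")
                  else list(cfg.opm_noise_levels_ft))
        entry: dict = {}
        for region, space in regions.items():
            lf = assemble_leadfield(array, space, geo.fixture.sphere_center)
            entry[region] = {}
            for lvl in levels:
                noise = NoiseModel.homoscedastic(lf.n_channels, lvl * 1e-15,
                                                 cfg.bandwidth_hz)
                res = information_capacity(lf, noise, q2, region=region)
                entry[region][f"{lvl:g}fT"] = res.itot
        summary["fixed_arrays"][spec["name"]] = entry

    # count sweep on nested uniform arrays
    tables = []
    for array, levels, label in (
            (uni_squid, [cfg.squid_noise_ft], "squid"),
            (uni_opm, list(cfg.opm_noise_levels_ft), "opm"),
            (uni_tri, list(cfg.opm_noise_levels_ft), "triaxial_opm")):
        lfs = {region: assemble_leadfield(array, space, geo.fixture.sphere_center)
               for region, space in regions.items()}
        table = itot_sweep(lfs, array, cfg.sensor_counts,
                           [l * 1e-15 for l in levels], q2, cfg.bandwidth_hz)
        table.insert(0, "family", label)
        tables.append(table)
    import pandas as pd

    sweep = pd.concat(tables, ignore_index=True)
    sweep.to_csv(outdir / "itot_sweep.csv", index=False)
    summary["sweep_rows"] = len(sweep)
    _write_provenance(cfg, outdir)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
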