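"""Configuration, run orchestration, and file export.

Run configurations are YAML (JSON accepted) with a strict schema: unknown
keys are rejected by name, defaults are filled in, and a write-then-read
round trip is the identity.  Outputs are plain-text formats: legacy-VTK
ASCII structured grids for field checkpoints, RFC-4180 CSV for zone time
series, JSON for summaries and resolved-run metadata, and PNG renderings
(inspection only; nothing numeric is read back from images).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .errors import ConfigError
from .flow import FluidProperties, FlowState, SolverConfig, TwoPhaseSolver
from .geometry import (DomainGeometry, TextureSpec, assign_zones,
                       apply_texture_to_profile, build_implant_profile,
                       rasterize)

__all__ = [
    "TextureConfig", "GeometryConfig", "FluidsConfig", "SolverBlock",
    "SpeciesBlock", "ZonesBlock", "OutputBlock", "RunConfig",
    "load_config", "save_config", "run_from_config", "RunResult",
    "export_outputs", "write_vtk", "read_vtk", "write_series_csv",
    "read_series_csv", "render_alpha_png", "render_vector_png",
]


# ---------------------------------------------------------------------------
# Config schema
# ---------------------------------------------------------------------------

@dataclass
class TextureConfig:
    kind: str = "amorphous"
    spike_height_um: float = 40.0
    spike_width_um: float = 50.0
    nodule_height_nm: float = 300.0
    nodule_width_nm: float = 300.0
    nano_representation: str = "effective_wetting"

    def to_spec(self, seed: int = 0) -> TextureSpec:
        return TextureSpec(kind=self.kind,
                           spike_height_um=self.spike_height_um,
                           spike_width_um=self.spike_width_um,
                           nodule_height_nm=self.nodule_height_nm,
                           nodule_width_nm=self.nodule_width_nm,
                           nano_representation=self.nano_representation,
                           seed=seed)


@dataclass
class GeometryConfig:
    length_mm: float = 11.0
    diameter_mm: float = 4.0
    gap_mm: float = 0.3
    thread_count: int = 3
    thread_depth_mm: float = 0.35
    thread_pitch_mm: float = 1.2
    h_um: float = 25.0
    texture: TextureConfig = field(default_factory=TextureConfig)

    def validate(self) -> None:
        if min(self.length_mm, self.diameter_mm, self.gap_mm, self.h_um) <= 0:
            raise ConfigError("geometry dimensions must be positive")


@dataclass
class FluidsConfig:
    """Fluid properties block; defaults are the desk-scale study set."""

    rho_liquid: float = 1025.0
    mu_liquid: float = 1.4e-3
    rho_gas: float = 20.0
    mu_gas: float = 1.8e-5
    sigma: float = 1.0e-4
    contact_angle_deg: float = 70.0

    def to_props(self) -> FluidProperties:
        return FluidProperties(rho_liquid=self.rho_liquid,
                               mu_liquid=self.mu_liquid,
                               rho_gas=self.rho_gas, mu_gas=self.mu_gas,
                               sigma=self.sigma,
                               contact_angle_deg=self.contact_angle_deg)

    def validate(self) -> None:
        self.to_props()  # FluidProperties performs the physical checks


@dataclass
class SolverBlock:
    end_time: float = 3.0
    cfl: float = 0.4
    inlet_speed_mm_s: float = 0.65
    gravity: Tuple[float, float] = (0.0, 0.0)
    checkpoint_times: Tuple[float, ...] = (1.0, 2.0, 3.0)
    series_interval: float = 0.05
    vent_rate: float = 0.3
    layer_vent_rate: float = 5.0
    p_tol: float = 1.0e-8

    def validate(self) -> None:
        pass  # SolverConfig performs the checks on resolution


@dataclass
class SpeciesBlock:
    enabled: bool = True
    diffusivity_m2_s: float = 2.0e-11

    def validate(self) -> None:
        if self.diffusivity_m2_s < 0:
            raise ConfigError("species diffusivity must be non-negative")


@dataclass
class ZonesBlock:
    interface_thickness_um: float = 100.0

    def validate(self) -> None:
        if self.interface_thickness_um <= 0:
            raise ConfigError("interface thickness must be positive")


@dataclass
class OutputBlock:
    directory: str = "runs"
    formats: Tuple[str, ...] = ("vtk", "csv", "json")
    render_png: bool = False

    def validate(self) -> None:
        for f in self.formats:
            if f not in ("vtk", "csv", "json", "png"):
                raise ConfigError(f"unknown output format {f!r}")


@dataclass
class RunConfig:
    """Complete, strictly validated run configuration."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    fluids: FluidsConfig = field(default_factory=FluidsConfig)
    solver: SolverBlock = field(default_factory=SolverBlock)
    species: SpeciesBlock = field(default_factory=SpeciesBlock)
    zones: ZonesBlock = field(default_factory=ZonesBlock)
    output: OutputBlock = field(default_factory=OutputBlock)
    seed: int = 0

    def validate(self) -> "RunConfig":
        for blk in (self.geometry, self.fluids, self.solver, self.species,
                    self.zones, self.output):
            blk.validate()
        if self.zones.interface_thickness_um >= self.geometry.gap_mm * 1000:
            raise ConfigError("interface thickness must be below the gap width")
        return self

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name))
                        for f in dc_fields(obj)}
            if isinstance(obj, tuple):
                return [conv(x) for x in obj]
            return obj
        return conv(self)

    @classmethod
    def from_dict(cls, data: Optional[dict]) -> "RunConfig":
        return _build_dataclass(cls, data or {}, path="config").validate()

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build_dataclass(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in dc_fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"{path}: unknown key {key!r}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        value = data[name]
        if dataclasses.is_dataclass(f.type) or \
                (isinstance(f.type, type) and dataclasses.is_dataclass(f.type)):
            kwargs[name] = _build_dataclass(f.type, value, f"{path}.{name}")
            continue
        ftype = f.type
        if isinstance(ftype, str):
            # postponed annotations: resolve the handful of names we use
            ftype = {"float": float, "int": int, "bool": bool, "str": str,
                     }.get(ftype, None)
        if ftype is None:
            # tuples and other containers: accept lists, coerce to tuple
            kwargs[name] = tuple(value) if isinstance(value, list) else value
            continue
        if ftype in (float, int):
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(
                    f"{path}.{name}: expected a number, got {value!r}")
            kwargs[name] = ftype(value)
        elif ftype is bool:
            if not isinstance(value, bool):
                raise ConfigError(
                    f"{path}.{name}: expected a boolean, got {value!r}")
            kwargs[name] = value
        elif ftype is str:
            if not isinstance(value, str):
                raise ConfigError(
                    f"{path}.{name}: expected a string, got {value!r}")
            kwargs[name] = value
        else:
            kwargs[name] = tuple(value) if isinstance(value, list) else value
    return cls(**kwargs)


# Resolve dataclass field types that the dataclass machinery stored as
# strings (because of ``from __future__ import annotations``).
def _resolve_field_types() -> None:
    ns = globals()
    for cls in (TextureConfig, GeometryConfig, FluidsConfig, SolverBlock,
                SpeciesBlock, ZonesBlock, OutputBlock, RunConfig):
        for f in dc_fields(cls):
            if isinstance(f.type, str):
                f.type = ns.get(f.type, {"float": float, "int": int,
                                         "bool": bool, "str": str}.get(
                                             f.type, f.type))


_resolve_field_types()


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration, filling defaults strictly."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# Run orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    config: RunConfig
    geom: DomainGeometry
    checkpoints: List[FlowState]
    series: "object"
    diagnostics: dict


def build_geometry(cfg: RunConfig) -> DomainGeometry:
    g = cfg.geometry
    profile = build_implant_profile(
        length_mm=g.length_mm, diameter_mm=g.diameter_mm,
        thread_count=g.thread_count, thread_depth_mm=g.thread_depth_mm,
        thread_pitch_mm=g.thread_pitch_mm)
    spec = g.texture.to_spec(seed=cfg.seed)
    if spec.has_meso and g.h_um <= spec.spike_width_um / 4.0:
        profile = apply_texture_to_profile(profile, spec)
    else:
        profile = dataclasses.replace(profile, texture=spec)
    geom = rasterize(profile, gap_mm=g.gap_mm, h_um=g.h_um)
    assign_zones(geom, interface_thickness_um=cfg.zones.interface_thickness_um)
    return geom


def solver_from_config(cfg: RunConfig, geom: DomainGeometry) -> TwoPhaseSolver:
    s = cfg.solver
    config = SolverConfig(
        end_time=s.end_time, cfl=s.cfl,
        inlet_speed=s.inlet_speed_mm_s * 1e-3,
        gravity=tuple(s.gravity),
        checkpoint_times=tuple(s.checkpoint_times),
        series_interval=s.series_interval, vent_rate=s.vent_rate,
        layer_vent_rate=s.layer_vent_rate,
        p_tol=s.p_tol, track_species=cfg.species.enabled,
        species_diffusivity=cfg.species.diffusivity_m2_s)
    return TwoPhaseSolver(geom, cfg.fluids.to_props(), config)


def run_from_config(cfg: RunConfig) -> RunResult:
    """Build the domain, run the solver, return everything in memory."""
    cfg.validate()
    geom = build_geometry(cfg)
    solver = solver_from_config(cfg, geom)
    checkpoints, series, diagnostics = solver.run()
    return RunResult(cfg, geom, checkpoints, series, diagnostics)


# ---------------------------------------------------------------------------
# Legacy-VTK ASCII structured grid
# ---------------------------------------------------------------------------

def write_vtk(path, geom: DomainGeometry, state: Optional[FlowState] = None,
              comment: str = "periflow fields") -> None:
    """Write cell data (masks, zones, and optionally fields) as legacy VTK."""
    nx, ny, h = geom.nx, geom.ny, geom.h_m
    lines = ["# vtk DataFile Version 3.0", comment, "ASCII",
             "DATASET STRUCTURED_POINTS",
             f"DIMENSIONS {nx + 1} {ny + 1} 2",
             "ORIGIN 0 0 0",
             f"SPACING {h:.9e} {h:.9e} {h:.9e}",
             f"CELL_DATA {nx * ny}"]

    def scalars(name: str, arr: np.ndarray, fmt: str = "%.9e") -> None:
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(fmt % v for v in np.asarray(arr, float).ravel())

    scalars("implant", geom.implant_mask.astype(float), "%.1f")
    scalars("bone", geom.bone_mask.astype(float), "%.1f")
    if geom.zone is not None:
        scalars("zone", geom.zone.astype(float), "%.1f")
    if state is not None:
        scalars("alpha", state.alpha)
        scalars("pressure", state.p)
        if state.c is not None:
            scalars("fibrinogen", state.c)
        uc, vc = state.cell_velocity()
        lines.append("VECTORS velocity float")
        lines.extend(f"{u:.9e} {v:.9e} 0.0"
                     for u, v in zip(uc.ravel(), vc.ravel()))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path) -> Dict[str, np.ndarray]:
    """Read back cell data written by :func:`write_vtk` (round-trip aid)."""
    tokens = Path(path).read_text().splitlines()
    dims = None
    ncell = None
    out: Dict[str, np.ndarray] = {}
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("DIMENSIONS"):
            _, a, b, _c = line.split()
            dims = (int(b) - 1, int(a) - 1)  # (ny, nx)
        elif line.startswith("CELL_DATA"):
            ncell = int(line.split()[1])
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            vals = []
            j = i + 2  # skip LOOKUP_TABLE
            while len(vals) < ncell:
                vals.extend(float(x) for x in tokens[j].split())
                j += 1
            out[name] = np.array(vals).reshape(dims)
            i = j - 1
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            vals = []
            j = i + 1
            while len(vals) < ncell:
                vals.append([float(x) for x in tokens[j].split()])
                j += 1
            arr = np.array(vals).reshape(dims + (3,))
            out[name + "_x"] = arr[:, :, 0]
            out[name + "_y"] = arr[:, :, 1]
            i = j - 1
        i += 1
    return out


# ---------------------------------------------------------------------------
# CSV time series and JSON summaries
# ---------------------------------------------------------------------------

def write_series_csv(path, series, topography: Optional[str] = None) -> None:
    """Zone time series as RFC-4180 CSV (header always written)."""
    import pandas as pd

    if series is None:
        from .metrics import ZoneTimeSeries

        cols = ["time", "zone"] + (["topography"] if topography else [])
        df = pd.DataFrame(columns=cols + list(ZoneTimeSeries.METRICS))
    else:
        df = series.to_dataframe(topography)
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def read_series_csv(path):
    import pandas as pd

    from .metrics import ZoneTimeSeries

    df = pd.read_csv(path)
    return ZoneTimeSeries.from_dataframe(df)


def export_outputs(result: RunResult, outdir) -> List[Path]:
    """Write checkpoints, series, summary and optional renderings.

    Fails fast with an I/O error if the directory cannot be created.
    Returns the list of files written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}")

    written: List[Path] = []
    cfg = result.config
    formats = set(cfg.output.formats)
    if cfg.output.render_png:
        formats.add("png")

    meta = {
        "config": cfg.to_dict(),
        "config_hash": cfg.content_hash(),
        "diagnostics": {k: (float(v) if isinstance(v, (int, float)) else v)
                        for k, v in result.diagnostics.items()},
        "scheme": {
            "vof": "dimensionally-split MUSCL/superbee with "
                   "divergence correction",
            "surface_tension": "CSF with contact-angle wall treatment",
            "projection": "ILU-preconditioned conjugate gradients",
        },
        "seed": cfg.seed,
    }
    p = out / "run_metadata.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True))
    written.append(p)

    if "vtk" in formats:
        for st in result.checkpoints:
            p = out / f"fields_t{st.t:.3f}.vtk"
            write_vtk(p, result.geom, st, comment=f"periflow t={st.t:.6f}")
            written.append(p)
    if "csv" in formats:
        p = out / "zone_series.csv"
        write_series_csv(p, result.series,
                         topography=cfg.geometry.texture.kind)
        written.append(p)
    if "png" in formats:
        for st in result.checkpoints:
            p = out / f"alpha_t{st.t:.3f}.png"
            render_alpha_png(p, result.geom, st)
            written.append(p)
        p = out / "vectors_final.png"
        render_vector_png(p, result.geom, result.checkpoints[-1])
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# PNG renderings (inspection only)
# ---------------------------------------------------------------------------

def _mpl():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def render_alpha_png(path, geom: DomainGeometry, state: FlowState) -> None:
    """Plasma-density style color map of the liquid volume fraction."""
    plt = _mpl()
    img = np.ma.masked_where(~geom.fluid_mask, state.alpha)
    fig, ax = plt.subplots(figsize=(4, 8))
    ax.imshow(img, origin="lower", cmap="RdYlBu_r", vmin=0, vmax=1,
              extent=[0, geom.nx * geom.h_m * 1e3, 0, geom.ny * geom.h_m * 1e3])
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(f"liquid fraction, t = {state.t:.2f} s")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def render_vector_png(path, geom: DomainGeometry, state: FlowState,
                      stride: int = 4) -> None:
    """Velocity arrows colored by magnitude over the fluid region."""
    plt = _mpl()
    uc, vc = state.cell_velocity()
    sp = np.hypot(uc, vc)
    X, Y = np.meshgrid(geom.x_centers_m * 1e3, geom.y_centers_m * 1e3)
    mask = geom.fluid_mask
    fig, ax = plt.subplots(figsize=(4, 8))
    s = stride
    sel = mask[::s, ::s]
    q = ax.quiver(X[::s, ::s][sel], Y[::s, ::s][sel],
                  uc[::s, ::s][sel], vc[::s, ::s][sel],
                  sp[::s, ::s][sel], cmap="jet", scale_units="xy")
    fig.colorbar(q, ax=ax, label="|u| (m/s)")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(f"velocity, t = {state.t:.2f} s")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
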