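"""Synthetic benchmark cases: closed-form solver validation and the
coarse three-topography implant experiment.

Every case generates its own geometry and configuration, so the whole
pipeline is testable without external data:

- ``poiseuille``: body-force-driven plane channel; parabolic closed form.
- ``static_droplet``: 2D circular liquid drop; Young-Laplace pressure jump
  sigma / R.
- ``gaussian_diffusion``: point release in quiescent liquid; radial second
  moment 4 D t.
- ``capillary_channel``: wetting-driven imbibition between plates;
  Lucas-Washburn penetration sqrt(sigma W cos(theta) t / (3 mu)).
- ``mini_implant``: the coarse 2D implant domain (3 threads, 0.3 mm gap)
  run end-to-end; its "error" metric is the liquid mass-balance defect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .errors import BenchmarkError
from .flow import FluidProperties, FlowState, SolverConfig, TwoPhaseSolver
from .geometry import (DomainGeometry, TextureSpec, assign_zones,
                       build_implant_profile, rasterize)

__all__ = [
    "BenchmarkCase",
    "make_case",
    "run_benchmark",
    "mini_implant_geometry",
    "run_topography",
    "default_experiment",
    "CASE_NAMES",
]

CASE_NAMES = ("poiseuille", "static_droplet", "gaussian_diffusion",
              "capillary_channel", "mini_implant")


def _box_geometry(width_m: float, height_m: float, h_m: float,
                  boundary: Dict[str, str]) -> DomainGeometry:
    """All-fluid rectangular domain with the given edge conditions."""
    nx = max(int(round(width_m / h_m)), 2)
    ny = max(int(round(height_m / h_m)), 2)
    return DomainGeometry(
        h_m=h_m, nx=nx, ny=ny,
        implant_mask=np.zeros((ny, nx), dtype=bool),
        bone_mask=np.zeros((ny, nx), dtype=bool),
        gap_mm=width_m * 1000.0, apex_clearance_mm=0.0,
        boundary=dict(boundary), profile=None)


@dataclass
class BenchmarkCase:
    """A runnable validation case with an evaluable reference solution."""

    name: str
    description: str
    runner: Callable[[int], Dict[str, float]]
    reference: str
    default_resolution: int
    convergence: bool = True

    def run(self, resolution: Optional[int] = None) -> Dict[str, float]:
        return self.runner(resolution or self.default_resolution)


# ---------------------------------------------------------------------------
# Poiseuille channel
# ---------------------------------------------------------------------------

def _run_poiseuille(n_across: int) -> Dict[str, float]:
    W = 1.0e-3
    h = W / n_across
    g = 0.01  # m/s^2 upward body force
    props = FluidProperties(rho_liquid=1000.0, mu_liquid=0.01,
                            rho_gas=1000.0, mu_gas=0.01, sigma=0.0,
                            contact_angle_deg=90.0)
    geom = _box_geometry(W, 2 * W, h, {"left": "wall", "right": "wall",
                                       "bottom": "outlet", "top": "outlet"})
    cfg = SolverConfig(end_time=1.0, cfl=0.4, inlet_speed=0.0,
                       gravity=(0.0, g), checkpoint_times=(),
                       vent_rate=0.0, dt_max=1e-3)
    solver = TwoPhaseSolver(geom, props, cfg)
    state = solver.initialize_state()
    state.alpha[:] = 1.0
    solver.apply_boundary_conditions(state)
    nu = props.mu_liquid / props.rho_liquid
    t_relax = W * W / nu
    t = 0.0
    prev = None
    while t < 3.0 * t_relax:
        dt = solver.compute_dt(state)
        solver.step(state, dt)
        t += dt
        if prev is not None and t > 0.5 * t_relax:
            dv = float(np.abs(state.v - prev).max())
            if dv < 1e-12 + 1e-8 * float(np.abs(state.v).max()):
                break
        prev = state.v.copy()
    j = geom.ny // 2
    v_num = state.v[j, :]
    x = (np.arange(geom.nx) + 0.5) * h
    v_ref = props.rho_liquid * g / (2.0 * props.mu_liquid) * x * (W - x)
    err = float(np.linalg.norm(v_num - v_ref) / np.linalg.norm(v_ref))
    return {"error": err, "l2_relative": err, "t_end": t,
            "v_max": float(v_num.max()), "v_max_ref": float(v_ref.max())}


# ---------------------------------------------------------------------------
# Static droplet (Young-Laplace)
# ---------------------------------------------------------------------------

def _run_droplet(n: int) -> Dict[str, float]:
    L = 1.0e-3
    h = L / n
    R = 0.2e-3
    sigma = 0.01
    props = FluidProperties(rho_liquid=1000.0, mu_liquid=0.01,
                            rho_gas=100.0, mu_gas=0.01, sigma=sigma,
                            contact_angle_deg=90.0)
    geom = _box_geometry(L, L, h, {"left": "wall", "right": "wall",
                                   "bottom": "wall", "top": "outlet"})
    cfg = SolverConfig(end_time=1.0, cfl=0.3, inlet_speed=0.0,
                       checkpoint_times=(), vent_rate=0.0, dt_max=1e-4)
    solver = TwoPhaseSolver(geom, props, cfg)
    state = solver.initialize_state()
    xc = (np.arange(geom.nx) + 0.5) * h - L / 2
    yc = (np.arange(geom.ny) + 0.5) * h - L / 2
    X, Y = np.meshgrid(xc, yc)
    r = np.hypot(X, Y)
    # Smoothed initial circle (one-cell transition) to limit initial shock.
    state.alpha = np.clip((R - r) / h + 0.5, 0.0, 1.0)
    solver.apply_boundary_conditions(state)
    for _ in range(600):
        dt = solver.compute_dt(state)
        solver.step(state, dt)
    inner = state.alpha > 0.95
    outer = (state.alpha < 0.05) & solver.fluid
    dp = float(state.p[inner].mean() - state.p[outer].mean())
    dp_ref = sigma / R
    err = abs(dp - dp_ref) / dp_ref
    return {"error": err, "pressure_jump": dp, "pressure_jump_ref": dp_ref}


# ---------------------------------------------------------------------------
# Gaussian diffusion (species)
# ---------------------------------------------------------------------------

def _run_gaussian(n: int) -> Dict[str, float]:
    from .species import SpeciesField, step_species

    L = 1.0e-3
    h = L / n
    D = 1.0e-9
    geom = _box_geometry(L, L, h, {"left": "wall", "right": "wall",
                                   "bottom": "wall", "top": "wall"})
    state = FlowState(t=0.0, u=np.zeros((geom.ny, geom.nx + 1)),
                      v=np.zeros((geom.ny + 1, geom.nx)),
                      p=np.zeros((geom.ny, geom.nx)),
                      alpha=np.ones((geom.ny, geom.nx)))
    c0 = np.zeros((geom.ny, geom.nx))
    c0[geom.ny // 2, geom.nx // 2] = 1.0
    field_ = SpeciesField(c0, diffusivity=D)
    dt = 0.2 * h * h / D
    t_end = 40.0 * dt
    t = 0.0
    while t < t_end - 1e-12:
        field_ = step_species(field_, state, geom, dt)
        t += dt
    xc = (np.arange(geom.nx) + 0.5) * h
    yc = (np.arange(geom.ny) + 0.5) * h
    X, Y = np.meshgrid(xc, yc)
    m = field_.c
    total = m.sum()
    x0 = float((m * X).sum() / total)
    y0 = float((m * Y).sum() / total)
    r2 = float((m * ((X - x0) ** 2 + (Y - y0) ** 2)).sum() / total)
    r2_ref = 4.0 * D * t
    err = abs(r2 - r2_ref) / r2_ref
    return {"error": err, "second_moment": r2, "second_moment_ref": r2_ref,
            "t_end": t}


# ---------------------------------------------------------------------------
# Capillary channel (Lucas-Washburn)
# ---------------------------------------------------------------------------

def _run_capillary(n_across: int) -> Dict[str, float]:
    W = 1.0e-4
    h = W / n_across
    L = 15.0 * W
    sigma = 0.01
    theta = 45.0
    mu = 0.01
    props = FluidProperties(rho_liquid=1000.0, mu_liquid=mu,
                            rho_gas=10.0, mu_gas=1e-4, sigma=sigma,
                            contact_angle_deg=theta)
    # Horizontal channel: reservoir at the left (pressure outlet), gas vents
    # right; wetting walls top and bottom as explicit solid rows so the
    # contact-angle wall treatment is exercised exactly as at the implant.
    geom = _box_geometry(L, W + 2 * h, h, {"left": "outlet", "right": "outlet",
                                           "bottom": "wall", "top": "wall"})
    geom.bone_mask[0, :] = True
    geom.bone_mask[-1, :] = True
    cfg = SolverConfig(end_time=1.0, cfl=0.3, inlet_speed=0.0,
                       checkpoint_times=(), vent_rate=0.0, dt_max=1e-4)
    solver = TwoPhaseSolver(geom, props, cfg)
    state = solver.initialize_state()
    l0 = 2.0 * W
    ncols0 = int(round(l0 / h))
    state.alpha[:, :ncols0] = 1.0
    solver.apply_boundary_conditions(state)
    t_end = 0.015
    t = 0.0
    while t < t_end - 1e-12:
        dt = min(solver.compute_dt(state), t_end - t)
        solver.step(state, dt)
        t += dt
    area = float(state.alpha.sum()) * h * h
    l_num = area / W - l0
    l_ref = math.sqrt(sigma * W * math.cos(math.radians(theta)) * t / (3.0 * mu))
    err = abs(l_num - l_ref) / l_ref
    return {"error": err, "penetration": l_num, "penetration_ref": l_ref,
            "t_end": t}


# ---------------------------------------------------------------------------
# Mini implant experiment
# ---------------------------------------------------------------------------

def mini_implant_geometry(kind: str = "amorphous", h_um: float = 25.0,
                          gap_mm: float = 0.3,
                          interface_thickness_um: float = 100.0,
                          seed: int = 0) -> DomainGeometry:
    """Rasterized coarse implant domain for one surface topography.

    The nominal implant dimensions are used throughout: 11 mm length, 4 mm
    diameter, 3 threads, 0.3 mm implant-bone gap.  At the default 25 um
    grid the meso spikes are below the 4-cells-per-feature threshold and
    are represented by the effective wetting/drag layer rather than by
    geometric serration.
    """
    from .geometry import apply_texture_to_profile

    profile = build_implant_profile()
    spec = TextureSpec(kind=kind, seed=seed)
    if spec.has_meso and h_um <= spec.spike_width_um / 4.0:
        profile = apply_texture_to_profile(profile, spec)
    else:
        from dataclasses import replace
        profile = replace(profile, texture=spec)
    geom = rasterize(profile, gap_mm=gap_mm, h_um=h_um)
    assign_zones(geom, interface_thickness_um=interface_thickness_um)
    return geom


def run_topography(kind: str, end_time: float = 3.0, h_um: float = 25.0,
                   seed: int = 0,
                   props: Optional[FluidProperties] = None,
                   config: Optional[SolverConfig] = None):
    """Run the coarse implant experiment for one topography.

    Returns ``(geom, checkpoints, series, diagnostics)``.  Defaults follow
    the documented desk-scale study conditions (see docs/methods.md).
    """
    geom = mini_implant_geometry(kind=kind, h_um=h_um, seed=seed)
    if props is None:
        props = FluidProperties.desk_scale()
    if config is None:
        config = SolverConfig(end_time=end_time,
                              checkpoint_times=tuple(
                                  t for t in (1.0, 2.0, 3.0) if t <= end_time),
                              track_species=True)
    solver = TwoPhaseSolver(geom, props, config)
    checkpoints, series, diagnostics = solver.run()
    return geom, checkpoints, series, diagnostics


def _run_mini(n_unused: int) -> Dict[str, float]:
    _, _, series, diag = run_topography("amorphous", end_time=0.5)
    fin = series.final()
    return {"error": abs(diag["mass_balance_error"]),
            "mass_balance_error": diag["mass_balance_error"],
            "outer_liquid_fraction": fin["outer"]["liquid_fraction"],
            "steps": diag["steps"]}


# ---------------------------------------------------------------------------
# Case registry and harness
# ---------------------------------------------------------------------------

_CASES: Dict[str, BenchmarkCase] = {
    "poiseuille": BenchmarkCase(
        name="poiseuille",
        description="Body-force plane Poiseuille channel, steady profile",
        runner=_run_poiseuille,
        reference="v(x) = rho g x (W - x) / (2 mu)",
        default_resolution=32),
    "static_droplet": BenchmarkCase(
        name="static_droplet",
        description="Static 2D circular droplet, Young-Laplace jump",
        runner=_run_droplet,
        reference="dp = sigma / R",
        default_resolution=64),
    "gaussian_diffusion": BenchmarkCase(
        name="gaussian_diffusion",
        description="Point release diffusing in quiescent liquid",
        runner=_run_gaussian,
        reference="<r^2> = 4 D t",
        default_resolution=64),
    "capillary_channel": BenchmarkCase(
        name="capillary_channel",
        description="Capillary imbibition between parallel plates",
        runner=_run_capillary,
        reference="l(t) = sqrt(sigma W cos(theta) t / (3 mu))",
        default_resolution=12,
        convergence=False),
    "mini_implant": BenchmarkCase(
        name="mini_implant",
        description="Coarse 2D implant domain, short fill transient",
        runner=_run_mini,
        reference="liquid mass balance (inflow - outflow bookkeeping)",
        default_resolution=0,
        convergence=False),
}


def make_case(name: str) -> BenchmarkCase:
    """Look up a benchmark case by name."""
    try:
        return _CASES[name]
    except KeyError:
        raise BenchmarkError(
            f"unknown benchmark case {name!r}; valid names: "
            f"{', '.join(CASE_NAMES)}") from None


def run_benchmark(case: BenchmarkCase,
                  resolutions: Optional[Sequence[int]] = None) -> dict:
    """Run a case at one or more resolutions and report error norms.

    For convergence cases with >= 2 resolutions the observed order of
    accuracy is estimated from successive error ratios.
    """
    if resolutions is None:
        resolutions = [case.default_resolution]
    if case.convergence and len(resolutions) > 1 \
            and sorted(resolutions) != list(resolutions):
        raise BenchmarkError("resolutions must be increasing")
    results = []
    for n in resolutions:
        out = case.run(n)
        out["resolution"] = n
        results.append(out)
    report = {"case": case.name, "reference": case.reference,
              "results": results}
    if case.convergence and len(results) >= 2:
        orders = []
        for a, b in zip(results[:-1], results[1:]):
            if b["error"] > 0 and a["error"] > 0:
                ratio = b["resolution"] / a["resolution"]
                orders.append(math.log(a["error"] / b["error"])
                              / math.log(ratio))
        report["observed_order"] = orders
    return report


def default_experiment(seed: int = 0):
    """The three-topography experiment configurations.

    Returns a dict of fully resolved run configurations (amorphous, nano,
    hybrid) identical except for the texture block: the nominal implant
    geometry (11 mm x 4 mm, 3 threads, 0.3 mm gap), 3 s fill transient with
    checkpoints at 1/2/3 s, and the documented desk-scale defaults
    everywhere else.
    """
    from .io import RunConfig

    configs = {}
    for kind in ("amorphous", "nano", "hybrid"):
        cfg = RunConfig()
        cfg.geometry.texture.kind = kind
        cfg.seed = seed
        configs[kind] = cfg
    return configs
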