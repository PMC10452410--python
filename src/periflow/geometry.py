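"""Implant geometry, surface texture, rasterization, zones, and roughness.

The physical picture is a screw-shaped dental implant seated in a bone
socket with a thin blood-filled gap between implant and bone.  Everything
here is two-dimensional: an axial half cross-section through the implant
axis, lateral coordinate ``x`` from the implant axis outward, vertical
coordinate ``y`` positive upward (toward the outlet).

Length conventions
------------------
Macroscopic geometry (implant, gap, domain) is expressed in millimetres,
surface texture in micrometres (``*_um``) or nanometres (``*_nm``), and the
rasterized :class:`DomainGeometry` stores its grid spacing in metres for
direct use by the flow solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import ConfigError, GeometryError, ResolutionError, ZoneError

__all__ = [
    "HeightMap",
    "RoughnessMetrics",
    "TextureSpec",
    "ImplantProfile",
    "DomainGeometry",
    "build_implant_profile",
    "generate_texture_heightmap",
    "compute_roughness",
    "apply_texture_to_profile",
    "rasterize",
    "assign_zones",
    "thread_pocket_count",
    "ZONE_NONE",
    "ZONE_INTERFACE",
    "ZONE_THREAD",
    "ZONE_OUTER",
    "ZONE_NAMES",
]

# Zone labels for DomainGeometry.zone (0 = solid / unassigned).
ZONE_NONE = 0
ZONE_INTERFACE = 1
ZONE_THREAD = 2
ZONE_OUTER = 3
ZONE_NAMES = {ZONE_INTERFACE: "interface", ZONE_THREAD: "thread", ZONE_OUTER: "outer"}


# ---------------------------------------------------------------------------
# Height maps and areal roughness
# ---------------------------------------------------------------------------

@dataclass
class HeightMap:
    """Surface heights on a regular lateral grid.

    Parameters
    ----------
    heights
        2D array of heights in micrometres, indexed ``[row, col]``.
    spacing_um
        Lateral sample spacing in micrometres (same in both directions).
    """

    heights: np.ndarray
    spacing_um: float

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ConfigError("HeightMap.heights must be a 2D array")
        if not np.isfinite(self.heights).all():
            raise ConfigError("HeightMap.heights must be finite")
        if self.spacing_um <= 0:
            raise ConfigError("HeightMap.spacing_um must be positive")

    @property
    def extent_um(self) -> Tuple[float, float]:
        """Lateral size (x, y) in micrometres spanned by the samples."""
        ny, nx = self.heights.shape
        return ((nx - 1) * self.spacing_um, (ny - 1) * self.spacing_um)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.heights, delimiter=",",
                   header=f"periflow heightmap spacing_um={self.spacing_um}")

    @classmethod
    def from_csv(cls, path) -> "HeightMap":
        spacing = None
        with open(path) as fh:
            first = fh.readline()
        if "spacing_um=" in first:
            spacing = float(first.split("spacing_um=")[1].split()[0])
        if spacing is None:
            raise ConfigError(f"{path}: missing 'spacing_um=' header")
        return cls(np.loadtxt(path, delimiter=",", comments="#"), spacing)

    def to_png(self, path) -> None:
        """8-bit grayscale PNG with the height scale in tEXt metadata."""
        from PIL import Image
        from PIL.PngImagePlugin import PngInfo

        h = self.heights
        lo, hi = float(h.min()), float(h.max())
        scale = (hi - lo) if hi > lo else 1.0
        img = Image.fromarray(np.round(255 * (h - lo) / scale).astype(np.uint8))
        meta = PngInfo()
        meta.add_text("periflow_spacing_um", repr(self.spacing_um))
        meta.add_text("periflow_height_offset_um", repr(lo))
        meta.add_text("periflow_height_scale_um", repr(scale / 255.0))
        img.save(path, pnginfo=meta)

    @classmethod
    def from_png(cls, path) -> "HeightMap":
        from PIL import Image

        img = Image.open(path)
        meta = img.info
        try:
            spacing = float(meta["periflow_spacing_um"])
            offset = float(meta["periflow_height_offset_um"])
            scale = float(meta["periflow_height_scale_um"])
        except KeyError as exc:
            raise ConfigError(f"{path}: missing periflow scale metadata") from exc
        return cls(np.asarray(img, dtype=float) * scale + offset, spacing)


@dataclass(frozen=True)
class RoughnessMetrics:
    """ISO-25178-style areal roughness parameters.

    ``sa``/``sz`` in micrometres; ``sdr`` is the dimensionless developed
    interfacial area ratio (extra area / planar area).
    """

    sa: float
    sz: float
    sdr: float

    def __post_init__(self) -> None:
        if self.sa < 0 or self.sz < 0 or self.sdr < 0:
            raise ConfigError("roughness parameters must be non-negative")
        if self.sz + 1e-12 < self.sa:
            raise ConfigError("Sz cannot be smaller than Sa")

    @property
    def sdr_percent(self) -> float:
        return 100.0 * self.sdr


def compute_roughness(hmap: HeightMap) -> RoughnessMetrics:
    """Compute Sa, Sz and Sdr of a height map.

    Sa is the mean absolute deviation from the mean plane, Sz the largest
    peak height plus the largest pit depth (both relative to the mean
    plane), and Sdr the additional surface area contributed by the texture
    relative to the planar area, evaluated by splitting every grid cell
    into two triangular facets.
    """
    h = hmap.heights
    if h.shape[0] < 2 or h.shape[1] < 2:
        raise ConfigError("need at least 2x2 samples to compute roughness")
    hbar = h.mean()
    sa = float(np.abs(h - hbar).mean())
    sz = float((h.max() - hbar) + (hbar - h.min()))

    s = hmap.spacing_um
    # Triangulated facet area: cells split along the (00)-(11) diagonal.
    z00 = h[:-1, :-1]
    z01 = h[:-1, 1:]
    z10 = h[1:, :-1]
    z11 = h[1:, 1:]
    # Cross-product areas of triangles (00, 01, 11) and (00, 10, 11).
    a1 = 0.5 * np.sqrt((s * (z01 - z00)) ** 2 + (s * (z01 - z11)) ** 2 + s ** 4)
    a2 = 0.5 * np.sqrt((s * (z11 - z10)) ** 2 + (s * (z10 - z00)) ** 2 + s ** 4)
    true_area = float(a1.sum() + a2.sum())
    planar = s * s * (h.shape[0] - 1) * (h.shape[1] - 1)
    sdr = max(true_area / planar - 1.0, 0.0)
    return RoughnessMetrics(sa=sa, sz=sz, sdr=sdr)


# ---------------------------------------------------------------------------
# Texture specification and synthetic height maps
# ---------------------------------------------------------------------------

TEXTURE_KINDS = ("amorphous", "nano", "hybrid")
NANO_REPRESENTATIONS = ("effective_wetting", "drag_layer", "resolved")


@dataclass(frozen=True)
class TextureSpec:
    """Surface topography of the implant.

    ``amorphous`` has no texture scales; ``nano`` carries nodular bumps
    (default 300 nm high, 300 nm wide); ``hybrid`` superposes meso-scale
    crisscross spikes (default 40 um high, 50 um wide) with the same
    nano-nodules.  ``nano_representation`` selects how the sub-grid nano
    scale enters the flow solver.
    """

    kind: str = "amorphous"
    spike_height_um: float = 40.0
    spike_width_um: float = 50.0
    nodule_height_nm: float = 300.0
    nodule_width_nm: float = 300.0
    nano_representation: str = "effective_wetting"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in TEXTURE_KINDS:
            raise ConfigError(
                f"unknown texture kind {self.kind!r}; expected one of {TEXTURE_KINDS}")
        if self.nano_representation not in NANO_REPRESENTATIONS:
            raise ConfigError(
                f"unknown nano_representation {self.nano_representation!r}")
        if self.has_meso and (self.spike_height_um <= 0 or self.spike_width_um <= 0):
            raise ConfigError("active meso scale requires positive spike dimensions")
        if self.has_nano and (self.nodule_height_nm <= 0 or self.nodule_width_nm <= 0):
            raise ConfigError("active nano scale requires positive nodule dimensions")

    @property
    def has_meso(self) -> bool:
        return self.kind == "hybrid"

    @property
    def has_nano(self) -> bool:
        return self.kind in ("nano", "hybrid")


def _triangle_wave(u: np.ndarray) -> np.ndarray:
    """Unit-period, unit-amplitude triangle wave in [0, 1] with peak at 1/2."""
    frac = u - np.floor(u)
    return 1.0 - 2.0 * np.abs(frac - 0.5)


def _lattice_triangle(x: np.ndarray, period: float, spacing: float) -> np.ndarray:
    """Triangle wave in [0, 1] with the peak at x = 0, phase-aligned so both
    extremes fall on the sample lattice whenever the spacing divides the
    period (otherwise the symmetric wave is used).  This guarantees the
    nominal peak-to-valley amplitude is represented exactly on the grid."""
    ratio = period / spacing
    if abs(ratio - round(ratio)) < 1e-9 and round(ratio) >= 2:
        pit = spacing * math.floor(round(ratio) / 2.0)
        u = np.mod(x, period)
        return np.where(u <= pit, 1.0 - u / pit, (u - pit) / (period - pit))
    return _triangle_wave(x / period + 0.5)


def generate_texture_heightmap(
    spec: TextureSpec,
    extent_um: Tuple[float, float],
    spacing_um: float,
    scales: str = "auto",
) -> HeightMap:
    """Render a texture as a synthetic areal height map.

    ``scales`` picks which texture scales to render: ``"meso"``, ``"nano"``,
    ``"both"``, or ``"auto"`` (every scale active for ``spec.kind``).  The
    meso scale is a crisscross array of triangular spikes with peak-to-valley
    ``spike_height_um`` and period ``spike_width_um``; the nano scale an
    array of cosine-squared nodules with peak-to-valley ``nodule_height_nm``.
    """
    if scales not in ("auto", "meso", "nano", "both"):
        raise ConfigError(f"unknown scales selector {scales!r}")
    want_meso = spec.has_meso if scales == "auto" else scales in ("meso", "both")
    want_nano = spec.has_nano if scales == "auto" else scales in ("nano", "both")
    if want_meso and not spec.has_meso:
        raise ConfigError(f"texture kind {spec.kind!r} has no meso scale")
    if want_nano and not spec.has_nano:
        raise ConfigError(f"texture kind {spec.kind!r} has no nano scale")

    nx = int(round(extent_um[0] / spacing_um)) + 1
    ny = int(round(extent_um[1] / spacing_um)) + 1
    x = np.arange(nx) * spacing_um
    y = np.arange(ny) * spacing_um
    X, Y = np.meshgrid(x, y)
    h = np.zeros_like(X)

    if want_meso:
        if spacing_um > spec.spike_width_um / 4.0:
            raise ResolutionError(
                f"spacing {spacing_um} um too coarse for {spec.spike_width_um} um spikes "
                "(need >= 4 samples per feature width)")
        p = spec.spike_width_um
        # Crisscross laser passes: superposed orthogonal sawtooth carvings,
        # normalized so the combined peak-to-valley equals spike_height_um.
        h += 0.5 * spec.spike_height_um * (_lattice_triangle(X, p, spacing_um)
                                           + _lattice_triangle(Y, p, spacing_um))

    if want_nano:
        p = spec.nodule_width_nm / 1000.0  # um
        amp = spec.nodule_height_nm / 1000.0  # um
        if spacing_um > p / 4.0:
            raise ResolutionError(
                f"spacing {spacing_um} um too coarse for {spec.nodule_width_nm} nm nodules "
                "(need >= 4 samples per feature width)")
        # Dense nodular array: touching cos^2 bumps, period = nodule width.
        h += amp * (np.cos(np.pi * X / p) ** 2) * (np.cos(np.pi * Y / p) ** 2)

    return HeightMap(h, spacing_um)


# ---------------------------------------------------------------------------
# Implant profile
# ---------------------------------------------------------------------------

@dataclass
class ImplantProfile:
    """Closed half cross-section polyline of the implant in the (x, y) plane.

    ``vertices`` is an (N, 2) array in millimetres; the polygon is closed
    implicitly (last vertex connects back to the first).  ``x`` is the
    lateral distance from the implant axis, ``y`` the vertical position of
    the implant apex upward.
    """

    vertices: np.ndarray
    length_mm: float
    diameter_mm: float
    thread_count: int
    thread_depth_mm: float
    thread_pitch_mm: float
    core_half_width_mm: float
    thread_band_mm: Tuple[float, float]  # (first crest y, collar shoulder y)
    texture: Optional[TextureSpec] = None
    is_serrated: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError("profile vertices must be an (N, 2) array")

    @property
    def half_width_mm(self) -> float:
        return self.diameter_mm / 2.0

    def arc_length_mm(self) -> float:
        v = np.vstack([self.vertices, self.vertices[:1]])
        return float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())

    def bounding_box_mm(self) -> Tuple[float, float, float, float]:
        v = self.vertices
        return (float(v[:, 0].min()), float(v[:, 1].min()),
                float(v[:, 0].max()), float(v[:, 1].max()))

    def shapely_polygon(self):
        from shapely.geometry import Polygon

        return Polygon(self.vertices)

    def is_simple(self) -> bool:
        return bool(self.shapely_polygon().is_valid)

    def ridge_count(self) -> int:
        """Number of thread ridges: crest vertices at the full half-width
        below the collar shoulder (0 for a degenerate smooth profile)."""
        if self.thread_depth_mm == 0 or self.thread_count == 0:
            return 0
        v = self.vertices
        crest = np.isclose(v[:, 0], self.half_width_mm, atol=1e-9)
        collar_y = self.thread_band_mm[1]
        hits = v[crest & (v[:, 1] < collar_y - 1e-9)]
        return int(len(hits))


def build_implant_profile(
    length_mm: float = 11.0,
    diameter_mm: float = 4.0,
    thread_count: int = 3,
    thread_depth_mm: float = 0.35,
    thread_pitch_mm: float = 1.2,
    thread_start_mm: float = 0.6,
) -> ImplantProfile:
    """Build the screw-shaped implant half cross-section.

    The profile is, from the apex upward: a flat apex at the core
    half-width, ``thread_count`` triangular thread ridges of depth
    ``thread_depth_mm`` and pitch ``thread_pitch_mm`` reaching the full
    half-width, then a smooth collar at the full half-width up to the top.

    With ``thread_depth_mm = 0`` the profile degenerates to a smooth
    rectangle (no ridges).
    """
    if min(length_mm, diameter_mm, thread_pitch_mm) <= 0 or thread_depth_mm < 0:
        raise GeometryError("all implant dimensions must be positive")
    if thread_count < 0:
        raise GeometryError("thread_count must be non-negative")
    half = diameter_mm / 2.0
    core = half - thread_depth_mm
    if core <= 0:
        raise GeometryError("thread depth exceeds the implant half-width")
    thread_top = thread_start_mm + thread_count * thread_pitch_mm
    if thread_top >= length_mm:
        raise GeometryError(
            f"thread_count x thread_pitch ({thread_top:.3g} mm) exceeds the "
            f"implant length ({length_mm} mm)")

    if thread_depth_mm == 0 or thread_count == 0:
        verts = [(0.0, 0.0), (half, 0.0), (half, length_mm), (0.0, length_mm)]
        band = (thread_start_mm, thread_start_mm)
        return ImplantProfile(np.array(verts), length_mm, diameter_mm,
                              thread_count if thread_depth_mm > 0 else 0,
                              thread_depth_mm, thread_pitch_mm, half, band)

    verts = [(0.0, 0.0), (core, 0.0), (core, thread_start_mm)]
    y = thread_start_mm
    for _ in range(thread_count):
        verts.append((half, y + thread_pitch_mm / 2.0))  # crest
        verts.append((core, y + thread_pitch_mm))        # root
        y += thread_pitch_mm
    # Collar shoulder: horizontal ledge out to full half-width, then up.
    verts.append((half, y))
    verts.append((half, length_mm))
    verts.append((0.0, length_mm))
    first_crest_y = thread_start_mm + thread_pitch_mm / 2.0
    band = (first_crest_y, y)
    profile = ImplantProfile(np.array(verts), length_mm, diameter_mm,
                             thread_count, thread_depth_mm, thread_pitch_mm,
                             core, band)
    if not profile.is_simple():
        raise GeometryError("implant profile is self-intersecting")
    return profile


def apply_texture_to_profile(
    profile: ImplantProfile,
    spec: TextureSpec,
) -> ImplantProfile:
    """Attach a texture to the implant profile.

    Meso spikes are added as geometric serrations (a triangular sawtooth of
    period ``spike_width_um``, carved inward along the boundary normal) on
    the blood-facing boundary.  The nano scale is never geometrically
    resolved at profile scale; it stays as an annotation on the returned
    profile for the solver's effective wetting/drag models.  For amorphous
    textures the geometry is unchanged.
    """
    if not spec.has_meso:
        return replace(profile, texture=spec, is_serrated=False)

    period_mm = spec.spike_width_um / 1000.0
    amp_mm = spec.spike_height_um / 1000.0

    v = np.vstack([profile.vertices, profile.vertices[:1]])
    out_pts = []
    for a, b in zip(v[:-1], v[1:]):
        seg = b - a
        seg_len = float(np.linalg.norm(seg))
        if seg_len == 0:
            continue
        t_hat = seg / seg_len
        # The polygon is counter-clockwise in (x, y), so (ty, -tx) points
        # outward (into the blood).  Laser texturing removes material: the
        # sawtooth is carved inward, leaving the spike peaks flush with the
        # original surface so the overall half-width is unchanged.
        n_hat = np.array([t_hat[1], -t_hat[0]])
        on_axis = np.isclose(a[0], 0.0) and np.isclose(b[0], 0.0)
        on_top = np.isclose(a[1], profile.length_mm) and np.isclose(b[1], profile.length_mm)
        if on_axis or on_top:
            out_pts.append(a)
            continue
        # The sawtooth is piecewise linear, so emitting nodes exactly at its
        # extremes represents it without sampling error: peaks (depth 0) at
        # multiples of the period from the segment start, pits (full depth)
        # half a period later.
        nodes = [0.0]
        t = 0.0
        while t < seg_len - 1e-12:
            for off in (0.5 * period_mm, period_mm):
                tn = t + off
                if tn < seg_len - 1e-12:
                    nodes.append(tn)
            t += period_mm
        for t in nodes:
            frac = (t % period_mm) / period_mm
            depth = amp_mm * (1.0 - _triangle_wave(np.array([frac + 0.5]))[0])
            out_pts.append(a + t_hat * t - n_hat * depth)
    verts = np.array(out_pts)
    from shapely.geometry import MultiPolygon, Polygon

    poly = Polygon(verts)
    if not poly.is_valid:
        # Inward carving can momentarily fold the polyline at concave thread
        # roots; clean the polygon and keep the dominant component.
        fixed = poly.buffer(0)
        if isinstance(fixed, MultiPolygon):
            fixed = max(fixed.geoms, key=lambda g: g.area)
        if fixed.is_empty or not fixed.is_valid:
            raise GeometryError("textured profile is self-intersecting")
        verts = np.asarray(fixed.exterior.coords)[:-1]
    return replace(profile, vertices=verts, texture=spec, is_serrated=True)


# ---------------------------------------------------------------------------
# Rasterized domain
# ---------------------------------------------------------------------------

@dataclass
class DomainGeometry:
    """Structured-grid discretization of the peri-implant blood domain.

    Cell-centred boolean masks partition the grid into implant, bone and
    fluid.  ``zone`` labels every fluid cell as interface (1), thread (2)
    or outer (3) after :func:`assign_zones`.  ``boundary`` maps each domain
    edge (``left``/``right``/``bottom``/``top``) to one of ``wall``,
    ``slip``, ``inlet`` or ``outlet``; edge conditions apply only where the
    boundary cell is fluid.  ``side_inlet`` optionally prescribes inflow
    through an interior vertical solid face (the bone side-wall inlet) as
    ``(i_face, rows)``.  All stored lengths are metres unless suffixed
    ``_mm``/``_um``.
    """

    h_m: float
    nx: int
    ny: int
    implant_mask: np.ndarray
    bone_mask: np.ndarray
    gap_mm: float
    apex_clearance_mm: float
    boundary: dict = field(default_factory=lambda: {
        "left": "slip", "right": "wall", "bottom": "inlet", "top": "outlet"})
    side_inlet: Optional[Tuple[int, np.ndarray]] = None
    profile: Optional[ImplantProfile] = None
    zone: Optional[np.ndarray] = None
    interface_thickness_um: Optional[float] = None
    implant_distance_m: Optional[np.ndarray] = None
    texture_layer: Optional[np.ndarray] = None
    texture_layer_thickness_m: float = 0.0

    def __post_init__(self) -> None:
        for m in (self.implant_mask, self.bone_mask):
            if m.shape != (self.ny, self.nx):
                raise GeometryError("mask shape does not match grid dimensions")
        if (self.implant_mask & self.bone_mask).any():
            raise GeometryError("implant and bone masks overlap")
        valid = {"wall", "slip", "inlet", "outlet"}
        for edge, code in self.boundary.items():
            if edge not in ("left", "right", "bottom", "top") or code not in valid:
                raise ConfigError(f"invalid boundary entry {edge!r}: {code!r}")

    @property
    def solid_mask(self) -> np.ndarray:
        return self.implant_mask | self.bone_mask

    @property
    def fluid_mask(self) -> np.ndarray:
        return ~self.solid_mask

    @property
    def cell_area_m2(self) -> float:
        return self.h_m * self.h_m

    @property
    def x_centers_m(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.h_m

    @property
    def y_centers_m(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.h_m

    def zone_mask(self, label: int) -> np.ndarray:
        if self.zone is None:
            raise ZoneError("zones have not been assigned; call assign_zones first")
        return self.zone == label

    def min_clearance_m(self) -> float:
        """Minimum implant-bone distance measured on the grid."""
        if not self.implant_mask.any() or not self.bone_mask.any():
            return np.inf
        d = ndimage.distance_transform_edt(~self.implant_mask) * self.h_m
        return float(d[self.bone_mask].min())


def rasterize(
    profile: Optional[ImplantProfile],
    gap_mm: float = 0.3,
    h_um: float = 25.0,
    bone_thickness_mm: float = 0.15,
    apex_clearance_mm: float = 0.7,
    side_inlet_y_mm: Tuple[float, float] = (0.7, 1.7),
) -> DomainGeometry:
    """Rasterize the implant + bone domain onto a uniform structured grid.

    The implant sits ``apex_clearance_mm`` above the domain bottom; the bone
    socket wall is a vertical solid slab ``gap_mm`` outside the implant's
    widest radius.  Blood enters through the whole bottom boundary (implant
    apex inlet) and through a prescribed patch of the bone wall
    (``side_inlet_y_mm``, measured from the domain bottom); the only outlet
    is the gap opening at the domain top.

    With ``profile=None`` the grid contains no solid at all (every cell is
    fluid) — a plumbing convenience for solver benchmarks.
    """
    if h_um <= 0:
        raise ResolutionError("grid spacing must be positive")
    if gap_mm * 1000.0 / h_um < 8.0:
        raise ResolutionError(
            f"h = {h_um} um resolves the {gap_mm} mm gap with fewer than 8 cells")
    h_mm = h_um / 1000.0

    if profile is None:
        nx = ny = int(round(gap_mm / h_mm))
        implant = np.zeros((ny, nx), dtype=bool)
        bone = np.zeros((ny, nx), dtype=bool)
        return DomainGeometry(
            h_m=h_mm / 1000.0, nx=nx, ny=ny, implant_mask=implant,
            bone_mask=bone, gap_mm=gap_mm, apex_clearance_mm=0.0,
            boundary={"left": "wall", "right": "wall",
                      "bottom": "inlet", "top": "outlet"},
            profile=None)

    half = profile.half_width_mm
    wall_x = half + gap_mm
    width_mm = wall_x + bone_thickness_mm
    height_mm = apex_clearance_mm + profile.length_mm
    nx = int(round(width_mm / h_mm))
    ny = int(round(height_mm / h_mm))

    xc = (np.arange(nx) + 0.5) * h_mm
    yc = (np.arange(ny) + 0.5) * h_mm
    X, Y = np.meshgrid(xc, yc)

    from shapely import contains_xy

    poly = profile.shapely_polygon()
    pts_y = Y - apex_clearance_mm  # profile is in apex-relative coordinates
    implant = contains_xy(poly, X.ravel(), pts_y.ravel()).reshape(ny, nx)
    bone = (X >= wall_x)

    rows = np.arange(ny)
    side_rows = rows[(yc >= side_inlet_y_mm[0]) & (yc < side_inlet_y_mm[1])]
    i_wall = int(round(wall_x / h_mm))  # u-face index of the bone surface
    if not (~(implant[-1] | bone[-1])).any():
        raise GeometryError("no fluid opening at the domain top (outlet missing)")

    geom = DomainGeometry(
        h_m=h_mm / 1000.0, nx=nx, ny=ny, implant_mask=implant, bone_mask=bone,
        gap_mm=gap_mm, apex_clearance_mm=apex_clearance_mm,
        boundary={"left": "slip", "right": "wall",
                  "bottom": "inlet", "top": "outlet"},
        side_inlet=(i_wall, side_rows), profile=profile)
    geom.implant_distance_m = (
        ndimage.distance_transform_edt(~implant) * geom.h_m)
    _attach_texture_layer(geom)
    return geom


def _attach_texture_layer(geom: DomainGeometry) -> None:
    """Mark the near-surface layer occupied by unresolved texture.

    When the profile carries a meso texture that the grid cannot resolve
    geometrically (h > spike_width / 4), the spike layer is represented as a
    porous drag/wicking layer one spike-height thick along the implant
    surface.  Resolved serrations and nano-only textures leave no layer.
    """
    spec = geom.profile.texture if geom.profile is not None else None
    geom.texture_layer = np.zeros((geom.ny, geom.nx), dtype=bool)
    geom.texture_layer_thickness_m = 0.0
    if spec is None or not spec.has_meso or geom.profile.is_serrated:
        return
    h_um = geom.h_m * 1e6
    if h_um <= spec.spike_width_um / 4.0:
        # Fine enough to resolve the spikes geometrically; the caller should
        # have serrated the profile instead.
        return
    thickness_m = spec.spike_height_um * 1e-6
    ncells = max(int(np.ceil(thickness_m / geom.h_m)), 1)
    layer = (geom.implant_distance_m <= (ncells + 0.0) * geom.h_m) & geom.fluid_mask
    geom.texture_layer = layer
    geom.texture_layer_thickness_m = thickness_m


def assign_zones(geom: DomainGeometry, interface_thickness_um: float = 100.0) -> DomainGeometry:
    """Label every fluid cell as interface, thread, or outer (in place).

    Interface: fluid within ``interface_thickness_um`` of the implant
    surface.  Thread: fluid inside the thread envelope — between the core
    and the crest line, vertically between the first thread crest and the
    collar shoulder — that is not interface.  Outer: all remaining fluid.
    """
    if geom.profile is not None and interface_thickness_um >= geom.gap_mm * 1000.0:
        raise ConfigError(
            f"interface thickness {interface_thickness_um} um >= gap "
            f"{geom.gap_mm * 1000:.0f} um: zones degenerate")
    if geom.implant_distance_m is None:
        geom.implant_distance_m = (
            ndimage.distance_transform_edt(~geom.implant_mask) * geom.h_m)

    fluid = geom.fluid_mask
    zone = np.zeros((geom.ny, geom.nx), dtype=np.int8)
    interface = fluid & (geom.implant_distance_m <= interface_thickness_um * 1e-6)

    thread = np.zeros_like(interface)
    if geom.profile is not None and geom.profile.thread_count > 0 \
            and geom.profile.thread_depth_mm > 0:
        p = geom.profile
        xc = geom.x_centers_m * 1000.0
        yc = geom.y_centers_m * 1000.0 - geom.apex_clearance_mm
        X, Y = np.meshgrid(xc, yc)
        band_lo, band_hi = p.thread_band_mm
        thread = (fluid & ~interface
                  & (X > p.core_half_width_mm) & (X < p.half_width_mm)
                  & (Y >= band_lo) & (Y <= band_hi))

    outer = fluid & ~interface & ~thread
    zone[interface] = ZONE_INTERFACE
    zone[thread] = ZONE_THREAD
    zone[outer] = ZONE_OUTER
    geom.zone = zone
    geom.interface_thickness_um = interface_thickness_um
    return geom


def thread_pocket_count(geom: DomainGeometry) -> int:
    """Number of disjoint thread-zone pockets (4-connected components)."""
    mask = geom.zone_mask(ZONE_THREAD)
    _, n = ndimage.label(mask)
    return int(n)
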