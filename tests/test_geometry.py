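"""Implant profile, texture height maps, roughness, rasterization, zones."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periflow.errors import ConfigError, GeometryError, ResolutionError
from periflow.geometry import (ZONE_INTERFACE, ZONE_NONE, ZONE_OUTER,
                               ZONE_THREAD, HeightMap, TextureSpec,
                               apply_texture_to_profile, assign_zones,
                               build_implant_profile, compute_roughness,
                               generate_texture_heightmap, rasterize,
                               thread_pocket_count)


def segments_intersect(p1, p2, p3, p4):
    """Brute-force proper-intersection test (strict straddling, so shared
    endpoints of consecutive polyline segments do not count)."""
    d = lambda a, b, c: (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    d1, d2 = d(p3, p4, p1), d(p3, p4, p2)
    d3, d4 = d(p1, p2, p3), d(p1, p2, p4)
    return (d1 * d2 < 0) and (d3 * d4 < 0)


class TestImplantProfile:
    def test_printed_dimensions(self):
        p = build_implant_profile(11.0, 4.0, 3)
        x0, y0, x1, y1 = p.bounding_box_mm()
        assert (x1 - x0) == pytest.approx(2.0)  # half-width = diameter / 2
        assert (y1 - y0) == pytest.approx(11.0)
        assert p.ridge_count() == 3
        assert p.is_simple()

    def test_zero_thread_depth_degenerates_to_rectangle(self):
        p = build_implant_profile(thread_depth_mm=0.0)
        assert p.ridge_count() == 0
        assert len(p.vertices) == 4

    def test_thread_overrun_rejected(self):
        with pytest.raises(GeometryError):
            build_implant_profile(length_mm=11.0, thread_count=9,
                                  thread_pitch_mm=1.2)

    @pytest.mark.parametrize("kwargs", [
        dict(thread_count=1), dict(thread_count=5),
        dict(thread_depth_mm=0.1), dict(thread_pitch_mm=0.8),
        dict(length_mm=8.0, diameter_mm=3.5),
    ])
    def test_no_segment_pair_intersects(self, kwargs):
        # All-pairs segment oracle: the profile polyline must be simple.
        p = build_implant_profile(**kwargs)
        v = np.vstack([p.vertices, p.vertices[:1]])
        segs = list(zip(v[:-1], v[1:]))
        for (a1, a2), (b1, b2) in itertools.combinations(segs, 2):
            assert not segments_intersect(a1, a2, b1, b2)


class TestTextureHeightmaps:
    def test_amorphous_is_flat(self):
        hm = generate_texture_heightmap(TextureSpec("amorphous"), (100, 100), 1.0)
        m = compute_roughness(hm)
        assert np.all(hm.heights == 0.0)
        assert (m.sa, m.sz, m.sdr) == (0.0, 0.0, 0.0)

    def test_meso_peak_to_valley_is_spike_height(self):
        spec = TextureSpec("hybrid")
        hm = generate_texture_heightmap(spec, (500, 500), 2.0, scales="meso")
        assert compute_roughness(hm).sz == pytest.approx(40.0, abs=1e-9)

    def test_nano_peak_to_valley_is_nodule_height(self):
        spec = TextureSpec("nano")
        hm = generate_texture_heightmap(spec, (10, 10), 0.03, scales="nano")
        assert compute_roughness(hm).sz == pytest.approx(0.3, abs=1e-12)

    def test_too_coarse_spacing_rejected(self):
        with pytest.raises(ResolutionError):
            generate_texture_heightmap(TextureSpec("nano"), (10, 10), 0.2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            TextureSpec(kind="fractal")


class TestRoughness:
    def test_flat_plane_any_offset(self):
        hm = HeightMap(np.full((16, 16), 7.3), 1.0)
        m = compute_roughness(hm)
        assert m.sa == pytest.approx(0.0, abs=1e-12)
        assert m.sz == pytest.approx(0.0, abs=1e-12)
        assert m.sdr == pytest.approx(0.0, abs=1e-12)

    def test_triangular_wave_closed_form(self):
        # Symmetric triangular wave of peak-to-valley H: Sa = H/4, Sz = H
        # (closed-form integral of |h - mean| over one period).
        H, period, n = 8.0, 64, 256
        x = np.arange(n, dtype=float)
        wave = H * np.abs((x / period) % 1.0 - 0.5) * 2.0
        hm = HeightMap(np.tile(wave, (8, 1)), 1.0)
        m = compute_roughness(hm)
        assert m.sz == pytest.approx(H, rel=1e-12)
        assert m.sa == pytest.approx(H / 4.0, rel=1e-12)

    @pytest.mark.parametrize("slope", [0.25, 1.0, 3.0])
    def test_tilted_plane_sdr(self, slope):
        x = np.arange(33, dtype=float)
        X, _ = np.meshgrid(x, x)
        m = compute_roughness(HeightMap(slope * X, 1.0))
        assert m.sdr == pytest.approx(np.sqrt(1 + slope ** 2) - 1, rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        h = rng.normal(size=(48, 64))
        m = compute_roughness(HeightMap(h, 0.7))
        # Direct per-sample summation oracle.
        sa = np.mean(np.abs(h - h.mean()))
        sz = h.max() - h.min()
        s = 0.7
        area = 0.0
        for j in range(47):
            for i in range(63):
                z00, z01 = h[j, i], h[j, i + 1]
                z10, z11 = h[j + 1, i], h[j + 1, i + 1]
                u1 = np.array([s, 0, z01 - z00])
                v1 = np.array([s, s, z11 - z00])
                u2 = np.array([0, s, z10 - z00])
                area += 0.5 * np.linalg.norm(np.cross(u1, v1))
                area += 0.5 * np.linalg.norm(np.cross(u2, v1))
        sdr = area / (s * s * 47 * 63) - 1
        assert m.sa == pytest.approx(sa, rel=1e-12)
        assert m.sz == pytest.approx(sz, rel=1e-12)
        assert m.sdr == pytest.approx(sdr, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(-5.0, 5.0))
    def test_invariances(self, seed, offset):
        h = np.random.default_rng(seed).normal(size=(12, 12))
        m0 = compute_roughness(HeightMap(h, 1.0))
        # Sdr invariant under constant height shifts.
        m_off = compute_roughness(HeightMap(h + offset, 1.0))
        assert m_off.sdr == pytest.approx(m0.sdr, rel=1e-9, abs=1e-12)
        # Sa and Sz invariant under height-sign flip.
        m_flip = compute_roughness(HeightMap(-h, 1.0))
        assert m_flip.sa == pytest.approx(m0.sa, rel=1e-12)
        assert m_flip.sz == pytest.approx(m0.sz, rel=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigError):
            compute_roughness(HeightMap(np.zeros((1, 5)), 1.0))


class TestTexturedProfile:
    def test_amorphous_leaves_geometry_unchanged(self):
        p = build_implant_profile()
        t = apply_texture_to_profile(p, TextureSpec("amorphous"))
        assert np.array_equal(t.vertices, p.vertices)
        assert not t.is_serrated

    def test_serration_adds_arc_length(self):
        p = build_implant_profile()
        t = apply_texture_to_profile(p, TextureSpec("hybrid"))
        assert t.is_serrated
        assert t.arc_length_mm() > p.arc_length_mm()
        assert t.is_simple()

    def test_serration_preserves_half_width(self):
        p = build_implant_profile()
        t = apply_texture_to_profile(p, TextureSpec("hybrid"))
        assert t.vertices[:, 0].max() <= p.half_width_mm + 1e-9

    def test_serration_depth_matches_spike_height(self):
        # Local peak-to-valley along the collar flank equals 40 um.
        p = build_implant_profile()
        t = apply_texture_to_profile(p, TextureSpec("hybrid"))
        collar = t.vertices[(t.vertices[:, 1] > 5.0) & (t.vertices[:, 1] < 10.0)]
        depth = collar[:, 0].max() - collar[:, 0].min()
        assert depth == pytest.approx(0.040, rel=0.05)


class TestRasterize:
    def test_gap_clearance(self):
        geom = rasterize(build_implant_profile(), gap_mm=0.3, h_um=25.0)
        h_mm = 0.025
        assert abs(geom.min_clearance_m() * 1e3 - 0.3) <= 2 * h_mm

    def test_no_profile_all_fluid(self):
        geom = rasterize(None, gap_mm=0.3, h_um=25.0)
        assert geom.fluid_mask.all()

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(ResolutionError):
            rasterize(build_implant_profile(), gap_mm=0.3, h_um=50.0)

    @pytest.mark.parametrize("h_um", [37.5, 25.0, 12.5])
    def test_solid_area_matches_shoelace(self, h_um):
        # Shoelace-polygon-area oracle with O(h) perimeter correction.
        p = build_implant_profile()
        v = p.vertices
        shoelace = 0.5 * abs(np.sum(v[:, 0] * np.roll(v[:, 1], -1)
                                    - np.roll(v[:, 0], -1) * v[:, 1]))
        geom = rasterize(p, gap_mm=0.3, h_um=h_um)
        area = geom.implant_mask.sum() * (h_um / 1000.0) ** 2
        tol = p.arc_length_mm() * (h_um / 1000.0)
        assert abs(area - shoelace) < tol

    def test_rasterization_convergence_order(self):
        # Off-lattice profile so the area error does not vanish by symmetry.
        p = build_implant_profile(length_mm=10.37, diameter_mm=3.91,
                                  thread_depth_mm=0.333, thread_pitch_mm=1.13,
                                  thread_start_mm=0.57)
        v = p.vertices
        shoelace = 0.5 * abs(np.sum(v[:, 0] * np.roll(v[:, 1], -1)
                                    - np.roll(v[:, 0], -1) * v[:, 1]))
        errs = []
        for h_um in (100.0, 50.0, 25.0, 12.5):
            geom = rasterize(p, gap_mm=0.9, h_um=h_um)
            area = geom.implant_mask.sum() * (h_um / 1000.0) ** 2
            errs.append(abs(area - shoelace))
        # Error must vanish under refinement with observed order >= 1
        # (measured across the 8x spacing range to average staircase noise).
        assert errs[-1] < errs[0]
        order = np.log2(errs[0] / errs[-1]) / 3.0
        assert order >= 0.9


class TestZones:
    @pytest.fixture(scope="class")
    def geom(self):
        g = rasterize(build_implant_profile(), gap_mm=0.3, h_um=25.0)
        return assign_zones(g, interface_thickness_um=100.0)

    def test_three_thread_pockets(self, geom):
        assert thread_pocket_count(geom) == 3

    def test_labels_partition_fluid(self, geom):
        z = geom.zone
        fluid = geom.fluid_mask
        assert np.all(z[fluid] != ZONE_NONE)
        assert np.all(z[~fluid] == ZONE_NONE)
        n = ((z == ZONE_INTERFACE).sum() + (z == ZONE_THREAD).sum()
             + (z == ZONE_OUTER).sum())
        assert n == fluid.sum()

    def test_interface_band_area_smooth_cylinder(self):
        # Smooth (threadless) implant: interface area ~ wetted perimeter x t.
        p = build_implant_profile(thread_depth_mm=0.0)
        g = assign_zones(rasterize(p, gap_mm=0.5, h_um=25.0), 150.0)
        h_mm = 0.025
        t_mm = 0.150
        area = g.zone_mask(ZONE_INTERFACE).sum() * h_mm ** 2
        # Blood-wetted perimeter: flank + apex underside (axis side excluded).
        perim = p.length_mm + p.half_width_mm
        assert abs(area - perim * t_mm) <= 2 * h_mm * perim + t_mm * t_mm

    def test_interface_thickness_must_be_below_gap(self, geom):
        with pytest.raises(ConfigError):
            assign_zones(geom, interface_thickness_um=300.0)
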