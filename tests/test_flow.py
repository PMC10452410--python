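"""Two-phase flow solver: wetting model, time stepping, invariants."""

import math

import numpy as np
import pytest

from periflow.benchmarks import _box_geometry
from periflow.errors import ConfigError
from periflow.flow import (FluidProperties, SolverConfig, TwoPhaseSolver,
                           effective_contact_angle, texture_roughness_ratio)
from periflow.geometry import TextureSpec


class TestEffectiveContactAngle:
    def test_amorphous_identity(self):
        spec = TextureSpec("amorphous")
        assert effective_contact_angle(70.0, spec) == pytest.approx(70.0)
        assert effective_contact_angle(70.0, None) == pytest.approx(70.0)

    def test_ninety_degrees_is_fixed_point(self):
        spec = TextureSpec("nano")
        assert effective_contact_angle(90.0, spec) == pytest.approx(90.0)

    @pytest.mark.parametrize("base,r", [(70.0, 1.5), (60.0, 1.2), (120.0, 1.8)])
    def test_wenzel_formula_roundtrip(self, base, r):
        spec = TextureSpec("nano")
        theta = effective_contact_angle(base, spec, roughness_ratio=r)
        # Invert the Wenzel relation (unclamped for these r values).
        expected = math.degrees(math.acos(
            max(-1.0, min(1.0, r * math.cos(math.radians(base))))))
        assert theta == pytest.approx(expected, abs=1e-9)

    def test_roughness_ratio_below_one_rejected(self):
        with pytest.raises(ConfigError):
            effective_contact_angle(70.0, TextureSpec("nano"),
                                    roughness_ratio=0.9)

    def test_hierarchical_texture_wets_more(self):
        base = 70.0
        th_nano = effective_contact_angle(base, TextureSpec("nano"))
        th_hyb = effective_contact_angle(base, TextureSpec("hybrid"))
        assert th_hyb <= th_nano < base

    def test_roughness_ratio_exceeds_one_for_textures(self):
        assert texture_roughness_ratio(TextureSpec("nano")) > 1.0
        assert texture_roughness_ratio(TextureSpec("hybrid")) > \
            texture_roughness_ratio(TextureSpec("nano"))


def _quiet_solver(n=16, **cfg_kwargs):
    geom = _box_geometry(1e-3, 1e-3, 1e-3 / n,
                         {"left": "wall", "right": "wall",
                          "bottom": "wall", "top": "outlet"})
    cfg = SolverConfig(end_time=1.0, inlet_speed=0.0, checkpoint_times=(),
                       vent_rate=0.0, **cfg_kwargs)
    props = FluidProperties(rho_liquid=1000.0, mu_liquid=1e-3,
                            rho_gas=10.0, mu_gas=1e-5, sigma=0.01,
                            contact_angle_deg=70.0)
    return TwoPhaseSolver(geom, props, cfg)


class TestComputeDt:
    def test_zero_velocity_gives_capillary_or_dt_max(self):
        s = _quiet_solver()
        st = s.initialize_state()
        dt = s.compute_dt(st)
        p = s.props
        cap = math.sqrt(0.5 * (p.rho_liquid + p.rho_gas) * s.h ** 3
                        / (2 * math.pi * p.sigma))
        visc = 0.2 * s.h ** 2 / max(p.mu_liquid / p.rho_liquid,
                                    p.mu_gas / p.rho_gas)
        assert dt == pytest.approx(min(cap, visc, s.config.dt_max))

    def test_advective_bound_matches_face_scan(self, rng):
        s = _quiet_solver()
        st = s.initialize_state()
        st.u = rng.normal(scale=0.05, size=st.u.shape)
        st.v = rng.normal(scale=0.05, size=st.v.shape)
        umax = max(np.abs(st.u).max(), np.abs(st.v).max())  # face-scan oracle
        dt = s.compute_dt(st)
        assert dt <= s.config.cfl * s.h / umax + 1e-15

    def test_advective_bound_scales_linearly_with_h(self, rng):
        u = rng.normal(scale=0.05, size=(16, 17))
        v = rng.normal(scale=0.05, size=(17, 16))
        dts = []
        for n in (16, 32):
            s = _quiet_solver(n=16)
            s.h = 1e-3 / n  # same velocities, halved spacing
            st = s.initialize_state()
            st.u[:], st.v[:] = u, v
            p = s.props
            umax = max(np.abs(u).max(), np.abs(v).max())
            dts.append(s.config.cfl * s.h / umax)
        assert dts[1] == pytest.approx(dts[0] / 2)


class TestQuiescentStates:
    def test_uniform_liquid_is_equilibrium(self):
        # alpha = 1 everywhere, no inlet, no gravity: nothing may move.
        s = _quiet_solver()
        st = s.initialize_state()
        st.alpha[:] = 1.0
        for _ in range(5):
            st = s.step(st, s.compute_dt(st))
        assert np.abs(st.u).max() < 1e-10
        assert np.abs(st.v).max() < 1e-10
        assert np.abs(st.alpha - 1.0).max() < 1e-10

    def test_initialize_state_invariants(self, short_mini_run):
        geom, _, _, _ = short_mini_run
        solver = TwoPhaseSolver(geom, FluidProperties.desk_scale(),
                                SolverConfig(end_time=0.1, checkpoint_times=()))
        st = solver.initialize_state()
        assert np.isfinite(st.alpha).all()
        assert st.alpha.min() >= 0.0 and st.alpha.max() <= 1.0
        # Initial liquid is only the inlet seed.
        seed_area = solver.inlet_cells.sum() * solver.h ** 2
        assert solver.liquid_volume_m2(st) <= seed_area + 1e-15
        # Interface and thread zones start empty.
        from periflow.metrics import zone_liquid_fraction
        lf = zone_liquid_fraction(st, geom)
        assert lf["interface"] == 0.0
        assert lf["thread"] == 0.0


class TestBoundaryConditions:
    def test_zero_inlet_speed_zero_fluxes(self):
        geom = _box_geometry(1e-3, 1e-3, 1e-3 / 16,
                             {"left": "wall", "right": "wall",
                              "bottom": "inlet", "top": "outlet"})
        cfg = SolverConfig(end_time=1.0, inlet_speed=0.0, checkpoint_times=())
        s = TwoPhaseSolver(geom, FluidProperties(), cfg)
        st = s.initialize_state()
        assert np.abs(st.u).max() == 0.0
        assert np.abs(st.v).max() == 0.0

    def test_steady_single_phase_flux_balance(self):
        # Liquid-filled channel, inflow at bottom, outlet at top: once
        # steady, discrete inflow equals outflow to high accuracy.
        n = 16
        geom = _box_geometry(1e-3, 2e-3, 1e-3 / n,
                             {"left": "wall", "right": "wall",
                              "bottom": "inlet", "top": "outlet"})
        cfg = SolverConfig(end_time=1.0, inlet_speed=1e-3, checkpoint_times=(),
                           vent_rate=0.0)
        props = FluidProperties(rho_liquid=1000.0, mu_liquid=5e-3,
                                rho_gas=1000.0, mu_gas=5e-3, sigma=0.0,
                                contact_angle_deg=90.0)
        s = TwoPhaseSolver(geom, props, cfg)
        st = s.initialize_state()
        st.alpha[:] = 1.0
        for _ in range(600):
            st = s.step(st, s.compute_dt(st))
        inflow = st.v[0, :].sum() * s.h
        outflow = st.v[-1, :].sum() * s.h
        assert outflow == pytest.approx(inflow, rel=1e-8)

    def test_inlet_cells_fully_wetted_after_step(self):
        geom = _box_geometry(1e-3, 1e-3, 1e-3 / 16,
                             {"left": "wall", "right": "wall",
                              "bottom": "inlet", "top": "outlet"})
        cfg = SolverConfig(end_time=1.0, inlet_speed=1e-3, checkpoint_times=())
        s = TwoPhaseSolver(geom, FluidProperties.desk_scale(), cfg)
        st = s.initialize_state()
        st = s.step(st, s.compute_dt(st))
        assert np.all(st.alpha[s.inlet_cells] == 1.0)


class TestStepInvariants:
    def test_alpha_bounded_and_divergence_free(self, short_mini_run):
        geom, checkpoints, _, _ = short_mini_run
        st = checkpoints[-1]
        assert st.alpha.min() >= -1e-8
        assert st.alpha.max() <= 1.0 + 1e-8
        # Liquid cells are divergence-free to the solve tolerance; vented
        # (trapped gas) cells carry the prescribed sink instead.
        solver = TwoPhaseSolver(geom, FluidProperties.desk_scale(),
                                SolverConfig(end_time=0.2, checkpoint_times=(),
                                             track_species=True))
        st2 = solver.initialize_state()
        for _ in range(30):
            st2 = solver.step(st2, solver.compute_dt(st2))
        div = solver.divergence(st2)
        liquid = solver.fluid & (st2.alpha > 0.5)
        scale = max(np.abs(st2.u).max(), np.abs(st2.v).max()) / solver.h
        assert np.abs(div[liquid]).max() <= 1e-6 * scale + 1e-12

    def test_monotone_filling_before_breakthrough(self, short_mini_run):
        # Inflow-only regime: total liquid volume never decreases while the
        # outlet carries no liquid.
        _, _, series, diag = short_mini_run
        outer = series.data["outer"]["liquid_fraction"]
        assert np.all(np.diff(outer) >= -1e-12)

    def test_short_run_mass_balance(self, short_mini_run):
        _, _, _, diag = short_mini_run
        assert abs(diag["mass_balance_error"]) < 0.01


class TestRunLoop:
    def test_end_time_zero_returns_initial_state(self):
        from periflow.benchmarks import mini_implant_geometry

        geom = mini_implant_geometry("amorphous")
        cfg = SolverConfig(end_time=0.0, checkpoint_times=())
        solver = TwoPhaseSolver(geom, FluidProperties.desk_scale(), cfg)
        cps, series, diag = solver.run()
        assert len(cps) == 1
        assert cps[0].t == 0.0
        assert diag["steps"] == 0
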