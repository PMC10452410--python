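"""Zone reductions, recruitment statistics, and the comparison summary."""

import numpy as np
import pytest

from periflow.errors import ZoneError
from periflow.flow import FlowState
from periflow.geometry import (ZONE_INTERFACE, ZONE_OUTER, ZONE_THREAD,
                               DomainGeometry)
from periflow.metrics import (DEFAULT_LABEL_THRESHOLDS, ZoneTimeSeries,
                              compare_topographies, recruitment_efficiency,
                              recruitment_totals, render_summary_table,
                              zone_liquid_fraction, zone_mean_vectors)


def tiny_geometry(n=4):
    """All-fluid n x n grid with a hand-laid zone chessboard."""
    geom = DomainGeometry(
        h_m=1e-3 / n, nx=n, ny=n,
        implant_mask=np.zeros((n, n), dtype=bool),
        bone_mask=np.zeros((n, n), dtype=bool),
        gap_mm=1.0, apex_clearance_mm=0.0,
        boundary={"left": "wall", "right": "wall",
                  "bottom": "wall", "top": "outlet"})
    zone = np.full((n, n), ZONE_OUTER, dtype=np.int8)
    zone[:, 0] = ZONE_INTERFACE
    zone[:, 1] = ZONE_THREAD
    geom.zone = zone
    return geom


def state_on(geom, alpha=1.0, u=0.0, v=0.0):
    ny, nx = geom.ny, geom.nx
    return FlowState(t=0.0, u=np.full((ny, nx + 1), float(u)),
                     v=np.full((ny + 1, nx), float(v)),
                     p=np.zeros((ny, nx)),
                     alpha=np.full((ny, nx), float(alpha)))


class TestZoneLiquidFraction:
    def test_saturated_and_empty(self):
        geom = tiny_geometry()
        assert all(v == 1.0 for v in
                   zone_liquid_fraction(state_on(geom, 1.0), geom).values())
        assert all(v == 0.0 for v in
                   zone_liquid_fraction(state_on(geom, 0.0), geom).values())

    def test_checkerboard_matches_hand_sum(self):
        geom = tiny_geometry(4)
        st = state_on(geom)
        st.alpha = np.indices((4, 4)).sum(axis=0) % 2 * 1.0  # checkerboard
        lf = zone_liquid_fraction(st, geom)
        for code, name in ((ZONE_INTERFACE, "interface"),
                           (ZONE_THREAD, "thread"), (ZONE_OUTER, "outer")):
            mask = geom.zone == code
            assert lf[name] == pytest.approx(st.alpha[mask].mean(), rel=1e-12)

    def test_grid_mismatch_rejected(self):
        geom = tiny_geometry(4)
        st = state_on(tiny_geometry(5))
        with pytest.raises(ZoneError):
            zone_liquid_fraction(st, geom)


class TestZoneMeanVectors:
    def test_uniform_upward_field(self):
        geom = tiny_geometry()
        mv = zone_mean_vectors(state_on(geom, 1.0, u=0.0, v=0.25), geom)
        for vert, horiz, speed in mv.values():
            assert vert == pytest.approx(0.25)
            assert horiz == pytest.approx(0.0, abs=1e-15)
            assert speed == pytest.approx(0.25)

    def test_inbound_sign_convention(self):
        # Flow from the bone wall toward the implant axis is -x, and must
        # report as positive ("inbound") horizontal component.
        geom = tiny_geometry()
        mv = zone_mean_vectors(state_on(geom, 1.0, u=-0.1, v=0.0), geom)
        for vert, horiz, speed in mv.values():
            assert vert == pytest.approx(0.0, abs=1e-15)
            assert horiz == pytest.approx(0.1)
            assert speed == pytest.approx(0.1)

    def test_matches_liquid_weighted_oracle(self, rng):
        geom = tiny_geometry(8)
        st = state_on(geom)
        st.u = rng.normal(size=st.u.shape)
        st.v = rng.normal(size=st.v.shape)
        st.alpha = rng.uniform(0, 1, size=st.alpha.shape)
        mv = zone_mean_vectors(st, geom)
        uc = 0.5 * (st.u[:, :-1] + st.u[:, 1:])
        vc = 0.5 * (st.v[:-1, :] + st.v[1:, :])
        for code, name in ((ZONE_INTERFACE, "interface"),
                           (ZONE_THREAD, "thread"), (ZONE_OUTER, "outer")):
            mask = geom.zone == code
            w = st.alpha[mask]
            vert = (vc[mask] * w).sum() / w.sum()
            horiz = -(uc[mask] * w).sum() / w.sum()
            assert mv[name][0] == pytest.approx(vert, rel=1e-12)
            assert mv[name][1] == pytest.approx(horiz, rel=1e-12)
            assert mv[name][2] == pytest.approx(np.hypot(vert, horiz), rel=1e-12)

    def test_dry_zone_undefined_not_zero(self):
        geom = tiny_geometry()
        st = state_on(geom, alpha=0.0, v=0.5)
        mv = zone_mean_vectors(st, geom)
        assert all(np.isnan(val) for triple in mv.values() for val in triple)


def series_from(interface, thread, outer=None, species=None, speeds=None):
    times = np.arange(len(interface), dtype=float) + 1.0
    zones = {"interface": interface, "thread": thread,
             "outer": outer if outer is not None else np.zeros_like(times)}
    data = {}
    for z, lf in zones.items():
        n = len(times)
        data[z] = {
            "liquid_fraction": np.asarray(lf, float),
            "species_mass": (np.asarray(species[z], float)
                             if species else np.zeros(n)),
            "v_vertical": np.zeros(n),
            "v_horizontal": np.zeros(n),
            "speed": (np.full(n, speeds[z]) if speeds else np.zeros(n)),
            "speed_mean_mag": np.zeros(n),
        }
    return ZoneTimeSeries(times, data)


class TestRecruitment:
    def test_all_zero_series(self):
        s = series_from([0, 0], [0, 0])
        assert recruitment_totals(s) == (0.0, 0.0)

    def test_volume_weighted_hand_calculation(self):
        s = series_from([0.1, 0.3], [0.2, 0.5])
        vols = {"interface": 2.0, "thread": 4.0}
        blood, species = recruitment_totals(s, vols)
        assert blood == pytest.approx(0.3 * 2.0 + 0.5 * 4.0)
        assert species == 0.0

    def test_totals_ignore_outer_zone(self):
        a = series_from([0.1, 0.3], [0.2, 0.5], outer=[0.0, 0.0])
        b = series_from([0.1, 0.3], [0.2, 0.5], outer=[0.9, 1.0])
        assert recruitment_totals(a) == recruitment_totals(b)

    def test_efficiency_arithmetic(self):
        s = series_from([0.2, 0.2], [0.8, 0.8],
                        species={"interface": [0.2, 0.2],
                                 "thread": [0.8, 0.8], "outer": [0, 0]})
        eff_b, eff_s = recruitment_efficiency(s)
        assert eff_b == pytest.approx(25.0)
        assert eff_s == pytest.approx(25.0)

    def test_equal_quantities_give_100_percent(self):
        s = series_from([0.4, 0.4], [0.4, 0.4],
                        species={"interface": [1, 1], "thread": [1, 1],
                                 "outer": [0, 0]})
        assert recruitment_efficiency(s) == (pytest.approx(100.0),
                                             pytest.approx(100.0))

    def test_zero_thread_quantity_undefined(self):
        s = series_from([0.2, 0.2], [0.0, 0.0])
        with pytest.raises(ZoneError):
            recruitment_efficiency(s)


class TestCompareTopographies:
    def _mk(self, speed_i, lf_i=0.5, sp_i=0.5):
        return series_from([lf_i], [0.5],
                           species={"interface": [sp_i], "thread": [0.5],
                                    "outer": [0]},
                           speeds={"interface": speed_i, "thread": 0.01,
                                   "outer": 0.01})

    def test_identical_series_all_baseline_labels(self):
        s = self._mk(0.01)
        summary = compare_topographies({"amorphous": s, "nano": s, "hybrid": s})
        for metric, pairs in summary.fold_ratios.items():
            assert all(r == pytest.approx(1.0) for r in pairs.values())
        for t in ("nano", "hybrid"):
            assert summary.labels[t]["interface"]["density"] == "+/-"
            assert summary.labels[t]["interface"]["speed"] == "+/-"

    def test_four_fold_speed_ratio(self):
        res = {"amorphous": self._mk(0.04), "hybrid": self._mk(0.01)}
        summary = compare_topographies(res)
        assert summary.fold_ratios["interface_speed"]["amorphous:hybrid"] \
            == pytest.approx(4.0)
        assert summary.labels["hybrid"]["interface"]["speed"] == "Very slow"

    @pytest.mark.parametrize("ratio,label", [
        (1.6, "++"), (1.5, "++"), (1.3, "+"), (1.15, "+"),
        (1.0, "+/-"), (0.86, "+/-"), (0.85, "-"), (0.5, "-")])
    def test_density_label_thresholds(self, ratio, label):
        res = {"amorphous": self._mk(0.01, lf_i=0.5),
               "hybrid": self._mk(0.01, lf_i=0.5 * ratio)}
        summary = compare_topographies(res)
        assert summary.labels["hybrid"]["interface"]["density"] == label

    def test_direction_words(self):
        s = self._mk(0.01)
        s.data["interface"]["v_vertical"][:] = 0.01
        s.data["interface"]["v_horizontal"][:] = -0.002
        summary = compare_topographies({"amorphous": s})
        assert summary.labels["amorphous"]["interface"]["vector"] == "Up and Out"

    def test_missing_baseline_rejected(self):
        with pytest.raises(ZoneError):
            compare_topographies({"nano": self._mk(0.01)})

    def test_rendered_table_contains_topographies(self):
        s = self._mk(0.01)
        summary = compare_topographies({"amorphous": s, "hybrid": s})
        table = render_summary_table(summary)
        assert "amorphous" in table and "hybrid" in table


class TestZoneTimeSeries:
    def test_times_must_increase(self):
        with pytest.raises(ZoneError):
            ZoneTimeSeries(np.array([1.0, 1.0]), {})

    def test_dataframe_round_trip(self):
        s = series_from([0.1, 0.2, 0.3], [0.0, 0.1, 0.2])
        df = s.to_dataframe("amorphous")
        back = ZoneTimeSeries.from_dataframe(df)
        for z in s.data:
            for m in s.METRICS:
                np.testing.assert_allclose(back.data[z][m], s.data[z][m])

    def test_speed_consistency_of_stored_means(self, short_mini_run):
        _, _, series, _ = short_mini_run
        for z in series.data:
            vert = series.data[z]["v_vertical"]
            horiz = series.data[z]["v_horizontal"]
            speed = series.data[z]["speed"]
            ok = ~np.isnan(speed)
            np.testing.assert_allclose(speed[ok],
                                       np.hypot(vert[ok], horiz[ok]),
                                       rtol=1e-12)
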