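"""Zone-resolved outputs: plasma density, velocity vectors, recruitment.

All reductions are over the three peri-implant analysis zones (interface,
thread, outer).  Sign conventions for zone-mean velocity components:
*vertical* is the axial component, positive up toward the outlet
("upbound"); *horizontal* is the lateral component, positive toward the
implant surface ("inbound"; the implant axis lies at x = 0, so inbound is
-x).  Zone means are liquid-weighted by default, mirroring that the blood
phase carries the quantities of interest; unweighted means are available
via ``liquid_weighted=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ZoneError
from .geometry import (ZONE_INTERFACE, ZONE_NAMES, ZONE_OUTER, ZONE_THREAD,
                       DomainGeometry)

__all__ = [
    "ZoneTimeSeries",
    "ComparisonSummary",
    "zone_liquid_fraction",
    "zone_species_mass",
    "zone_mean_vectors",
    "sample_zone_metrics",
    "recruitment_totals",
    "recruitment_efficiency",
    "compare_topographies",
    "render_summary_table",
    "DEFAULT_LABEL_THRESHOLDS",
]

_MIN_LIQUID = 1e-12  # below this a zone's velocity average is undefined


def _zone_masks(geom: DomainGeometry) -> Dict[str, np.ndarray]:
    if geom.zone is None:
        raise ZoneError("geometry has no zone labels; call assign_zones first")
    return {name: geom.zone == code for code, name in ZONE_NAMES.items()}


def _check_grids(arr: np.ndarray, geom: DomainGeometry) -> None:
    if arr.shape != (geom.ny, geom.nx):
        raise ZoneError(
            f"field shape {arr.shape} does not match zone grid "
            f"({geom.ny}, {geom.nx})")


def zone_liquid_fraction(state, geom: DomainGeometry) -> Dict[str, float]:
    """Per-zone liquid (plasma) content: sum(alpha) / zone cell count."""
    _check_grids(state.alpha, geom)
    out = {}
    for name, mask in _zone_masks(geom).items():
        n = int(mask.sum())
        if n == 0:
            raise ZoneError(f"zone {name!r} contains no cells")
        out[name] = float(state.alpha[mask].sum() / n)
    return out


def zone_species_mass(state, geom: DomainGeometry,
                      c: Optional[np.ndarray] = None) -> Dict[str, float]:
    """Per-zone fibrinogen quantity: sum(c * alpha * cell area).

    Reported in mm^2-equivalents of inlet-normalized concentration (2D
    volume per unit depth) so numbers stay O(1) at implant scale.
    """
    conc = state.c if c is None else c
    if conc is None:
        return {name: 0.0 for name in _zone_masks(geom)}
    _check_grids(conc, geom)
    cell_mm2 = (geom.h_m * 1000.0) ** 2
    out = {}
    for name, mask in _zone_masks(geom).items():
        out[name] = float((conc[mask] * state.alpha[mask]).sum() * cell_mm2)
    return out


def zone_mean_vectors(state, geom: DomainGeometry,
                      liquid_weighted: bool = True
                      ) -> Dict[str, Tuple[float, float, float]]:
    """Per-zone mean velocity as (vertical, horizontal, speed), in m/s.

    The mean is liquid-weighted (weights alpha) by default.  ``speed`` is
    the magnitude of the mean vector.  Zones holding essentially no liquid
    get ``(nan, nan, nan)`` — the average is undefined there, not zero.
    """
    _check_grids(state.alpha, geom)
    uc, vc = state.cell_velocity()
    out = {}
    for name, mask in _zone_masks(geom).items():
        w = state.alpha[mask] if liquid_weighted else np.ones(int(mask.sum()))
        wsum = float(w.sum())
        if wsum < _MIN_LIQUID:
            out[name] = (float("nan"), float("nan"), float("nan"))
            continue
        vert = float((vc[mask] * w).sum() / wsum)
        horiz = float(-(uc[mask] * w).sum() / wsum)  # +x is away from implant
        out[name] = (vert, horiz, float(np.hypot(vert, horiz)))
    return out


def zone_mean_speed(state, geom: DomainGeometry,
                    liquid_weighted: bool = True) -> Dict[str, float]:
    """Secondary statistic: per-zone mean of cell speed magnitudes."""
    uc, vc = state.cell_velocity()
    sp = np.hypot(uc, vc)
    out = {}
    for name, mask in _zone_masks(geom).items():
        w = state.alpha[mask] if liquid_weighted else np.ones(int(mask.sum()))
        wsum = float(w.sum())
        out[name] = float((sp[mask] * w).sum() / wsum) if wsum >= _MIN_LIQUID \
            else float("nan")
    return out


def sample_zone_metrics(state, geom: DomainGeometry) -> dict:
    """One time sample of every per-zone metric (used by the run loop)."""
    lf = zone_liquid_fraction(state, geom)
    sm = zone_species_mass(state, geom)
    mv = zone_mean_vectors(state, geom)
    ms = zone_mean_speed(state, geom)
    row = {}
    for z in lf:
        row[z] = {
            "liquid_fraction": lf[z],
            "species_mass": sm[z],
            "v_vertical": mv[z][0],
            "v_horizontal": mv[z][1],
            "speed": mv[z][2],
            "speed_mean_mag": ms[z],
        }
    return row


@dataclass
class ZoneTimeSeries:
    """Per-zone, per-time metrics of a single run.

    ``data[zone][metric]`` is an array aligned with ``times``.  Metrics:
    liquid_fraction, species_mass, v_vertical, v_horizontal, speed,
    speed_mean_mag.
    """

    times: np.ndarray
    data: Dict[str, Dict[str, np.ndarray]]
    zone_cell_counts: Optional[Dict[str, int]] = None
    cell_area_mm2: Optional[float] = None

    METRICS = ("liquid_fraction", "species_mass", "v_vertical",
               "v_horizontal", "speed", "speed_mean_mag")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not (np.diff(self.times) > 0).all():
            raise ZoneError("series times must be strictly increasing")

    @classmethod
    def from_samples(cls, times: List[float], rows: List[dict],
                     zone_cell_counts: Optional[Dict[str, int]] = None,
                     cell_area_mm2: Optional[float] = None) -> "ZoneTimeSeries":
        zones = rows[0].keys() if rows else []
        data = {z: {m: np.array([r[z][m] for r in rows]) for m in cls.METRICS}
                for z in zones}
        return cls(np.asarray(times, float), data, zone_cell_counts,
                   cell_area_mm2)

    @property
    def zones(self) -> List[str]:
        return list(self.data.keys())

    def at_time(self, t: float, atol: float = 1e-9) -> Dict[str, Dict[str, float]]:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > max(atol, 1e-6 * max(abs(t), 1.0)):
            raise ZoneError(f"series holds no sample at t = {t}")
        return {z: {m: float(self.data[z][m][i]) for m in self.METRICS}
                for z in self.data}

    def final(self) -> Dict[str, Dict[str, float]]:
        return {z: {m: float(self.data[z][m][-1]) for m in self.METRICS}
                for z in self.data}

    def to_dataframe(self, topography: Optional[str] = None) -> pd.DataFrame:
        recs = []
        for z in self.data:
            for k, t in enumerate(self.times):
                rec = {"time": float(t), "zone": z}
                if topography is not None:
                    rec["topography"] = topography
                for m in self.METRICS:
                    rec[m] = float(self.data[z][m][k])
                recs.append(rec)
        return pd.DataFrame.from_records(recs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ZoneTimeSeries":
        times = np.sort(df["time"].unique())
        data = {}
        for z, sub in df.groupby("zone"):
            sub = sub.sort_values("time")
            data[str(z)] = {m: sub[m].to_numpy(float) for m in cls.METRICS}
        return cls(times, data)


def recruitment_totals(series: ZoneTimeSeries,
                       zone_volumes_mm2: Optional[Dict[str, float]] = None
                       ) -> Tuple[float, float]:
    """Total (interface + thread) blood and fibrinogen at the end time.

    Blood is reported as liquid area (mm^2 per unit depth) when zone
    volumes are known, otherwise as the sum of zone liquid fractions.
    The outer zone never contributes.
    """
    fin = series.final()
    for z in ("interface", "thread"):
        if z not in fin:
            raise ZoneError(f"series lacks zone {z!r}")
    if zone_volumes_mm2 is not None:
        blood = sum(fin[z]["liquid_fraction"] * zone_volumes_mm2[z]
                    for z in ("interface", "thread"))
    else:
        blood = sum(fin[z]["liquid_fraction"] for z in ("interface", "thread"))
    species = sum(fin[z]["species_mass"] for z in ("interface", "thread"))
    return float(blood), float(species)


def recruitment_efficiency(series: ZoneTimeSeries,
                           zone_volumes_mm2: Optional[Dict[str, float]] = None
                           ) -> Tuple[float, float]:
    """Interface infiltration as a percentage of thread infiltration.

    Returns ``(blood_percent, species_percent)`` at the series end time.
    Undefined (raises) when the thread zone holds nothing.
    """
    fin = series.final()
    vols = zone_volumes_mm2 or {"interface": 1.0, "thread": 1.0}
    b_int = fin["interface"]["liquid_fraction"] * vols["interface"]
    b_thr = fin["thread"]["liquid_fraction"] * vols["thread"]
    s_int = fin["interface"]["species_mass"]
    s_thr = fin["thread"]["species_mass"]
    if b_thr <= 0 or s_thr <= 0:
        raise ZoneError("thread-zone quantity is zero; efficiency undefined")
    return 100.0 * b_int / b_thr, 100.0 * s_int / s_thr


# ---------------------------------------------------------------------------
# Cross-topography comparison (qualitative summary table)
# ---------------------------------------------------------------------------

# Ratio-to-amorphous thresholds for the qualitative labels.
DEFAULT_LABEL_THRESHOLDS = {"very_high": 1.5, "high": 1.15, "low": 0.85}


def _quantity_label(ratio: float, thr: Dict[str, float]) -> str:
    if ratio >= thr["very_high"]:
        return "++"
    if ratio >= thr["high"]:
        return "+"
    if ratio <= thr["low"]:
        return "-"
    return "+/-"


def _speed_label(ratio: float, thr: Dict[str, float]) -> str:
    # Inverted sense: slower than the amorphous baseline is the notable case.
    if ratio <= 1.0 / thr["very_high"]:
        return "Very slow"
    if ratio <= 1.0 / thr["high"]:
        return "Slow"
    if ratio >= thr["high"]:
        return "Fast"
    return "+/-"


def _direction_label(vert: float, horiz: float) -> str:
    ud = "Up" if vert >= 0 else "Down"
    io = "In" if horiz >= 0 else "Out"
    return f"{ud} and {io}"


@dataclass
class ComparisonSummary:
    """Cross-topography summary mirroring a qualitative outcomes table."""

    topographies: List[str]
    density_3s: Dict[str, Dict[str, float]]       # topo -> zone -> value
    speed: Dict[str, Dict[str, float]]
    vectors: Dict[str, Dict[str, Tuple[float, float]]]
    species_3s: Dict[str, Dict[str, float]]
    totals: Dict[str, Tuple[float, float]]        # topo -> (blood, species)
    efficiency: Dict[str, Tuple[float, float]]    # topo -> (blood %, species %)
    fold_ratios: Dict[str, Dict[str, float]]      # metric -> "a:b" -> ratio
    labels: Dict[str, Dict[str, Dict[str, str]]]  # topo -> zone -> metric -> label
    baseline: str = "amorphous"
    thresholds: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_THRESHOLDS))

    def to_dict(self) -> dict:
        return {
            "topographies": self.topographies,
            "baseline": self.baseline,
            "thresholds": self.thresholds,
            "density_3s": self.density_3s,
            "speed": self.speed,
            "vectors": {t: {z: list(v) for z, v in zz.items()}
                        for t, zz in self.vectors.items()},
            "species_3s": self.species_3s,
            "totals": {t: list(v) for t, v in self.totals.items()},
            "efficiency": {t: list(v) for t, v in self.efficiency.items()},
            "fold_ratios": self.fold_ratios,
            "labels": self.labels,
        }


def compare_topographies(results: Dict[str, ZoneTimeSeries],
                         zone_volumes_mm2: Optional[Dict[str, float]] = None,
                         baseline: str = "amorphous",
                         thresholds: Optional[Dict[str, float]] = None
                         ) -> ComparisonSummary:
    """Build the cross-topography summary from per-topography zone series.

    Fold ratios are pairwise between topographies for interface/thread
    density, speed and species mass; qualitative labels compare each
    topography to the ``baseline`` via the documented ratio thresholds.
    """
    if baseline not in results:
        raise ZoneError(f"missing baseline topography {baseline!r}")
    thr = dict(DEFAULT_LABEL_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    topos = list(results.keys())
    zones = ("interface", "thread")

    density, speed, vectors, species = {}, {}, {}, {}
    totals, efficiency = {}, {}
    for t, series in results.items():
        fin = series.final()
        density[t] = {z: fin[z]["liquid_fraction"] for z in zones}
        speed[t] = {z: fin[z]["speed"] for z in zones}
        vectors[t] = {z: (fin[z]["v_vertical"], fin[z]["v_horizontal"])
                      for z in zones}
        species[t] = {z: fin[z]["species_mass"] for z in zones}
        totals[t] = recruitment_totals(series, zone_volumes_mm2)
        efficiency[t] = recruitment_efficiency(series, zone_volumes_mm2)

    def safe_ratio(a: float, b: float) -> float:
        return float(a / b) if b != 0 else float("inf")

    fold: Dict[str, Dict[str, float]] = {}
    for metric, table in (("interface_density", {t: density[t]["interface"] for t in topos}),
                          ("thread_density", {t: density[t]["thread"] for t in topos}),
                          ("interface_speed", {t: speed[t]["interface"] for t in topos}),
                          ("thread_speed", {t: speed[t]["thread"] for t in topos}),
                          ("interface_species", {t: species[t]["interface"] for t in topos}),
                          ("thread_species", {t: species[t]["thread"] for t in topos})):
        fold[metric] = {}
        for a in topos:
            for b in topos:
                if a != b:
                    fold[metric][f"{a}:{b}"] = safe_ratio(table[a], table[b])

    labels: Dict[str, Dict[str, Dict[str, str]]] = {}
    for t in topos:
        labels[t] = {}
        for z in zones:
            rho_r = safe_ratio(density[t][z], density[baseline][z])
            sp_r = safe_ratio(speed[t][z], speed[baseline][z])
            spec_r = safe_ratio(species[t][z], species[baseline][z])
            labels[t][z] = {
                "density": _quantity_label(rho_r, thr),
                "speed": _speed_label(sp_r, thr),
                "vector": _direction_label(*vectors[t][z]),
                "species": _quantity_label(spec_r, thr),
            }
        eff_b_r = safe_ratio(efficiency[t][0], efficiency[baseline][0])
        eff_s_r = safe_ratio(efficiency[t][1], efficiency[baseline][1])
        labels[t]["efficiency"] = {
            "blood": _quantity_label(eff_b_r, thr),
            "species": _quantity_label(eff_s_r, thr),
        }

    return ComparisonSummary(
        topographies=topos, density_3s=density, speed=speed, vectors=vectors,
        species_3s=species, totals=totals, efficiency=efficiency,
        fold_ratios=fold, labels=labels, baseline=baseline, thresholds=thr)


def render_summary_table(summary: ComparisonSummary) -> str:
    """Plain-text qualitative summary table (one row per topography)."""
    head = (f"{'Topography':<14} | {'Density I/T':<11} | {'Speed I/T':<20} | "
            f"{'Vector I':<14} | {'Vector T':<14} | {'Fibrino. I/T':<12} | "
            f"{'Eff. B/F':<9}")
    lines = [head, "-" * len(head)]
    for t in summary.topographies:
        lab = summary.labels[t]
        row = (f"{t:<14} | "
               f"{lab['interface']['density'] + '/' + lab['thread']['density']:<11} | "
               f"{lab['interface']['speed'] + '/' + lab['thread']['speed']:<20} | "
               f"{lab['interface']['vector']:<14} | {lab['thread']['vector']:<14} | "
               f"{lab['interface']['species'] + '/' + lab['thread']['species']:<12} | "
               f"{lab['efficiency']['blood'] + '/' + lab['efficiency']['species']:<9}")
        lines.append(row)
    return "\n".join(lines)
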