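"""Traditional wing morphometrics: measures, ratios and length residuals.

Builds the three classical variable sets used for bat species comparison:

* method 1 — "size-independent" wing ratios: tip length ratio T_l, tip area
  ratio T_s, wingtip shape index I = T_s/(T_l - T_s), aspect ratio
  A = span^2/area, and wing loading WL = M g0 / S (N m^-2);
* method 2 — method 1 with wing loading replaced by relative wing loading
  RWL = WL / M^(1/3) (the isometric normalization) and the tail-to-wing
  area ratio appended;
* method 3 — residuals of four digit/phalanx lengths regressed (pooled
  ordinary least squares) on forearm length.

Lengths and areas are derived from landmark coordinates: lengths as
distances between declared landmark role pairs, areas as shoelace areas of
declared landmark loops, in physical units via the digitizing scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

G0 = 9.81  # gravitational acceleration, m s^-2

__all__ = [
    "WingMeasures",
    "TraditionalVariables",
    "polygon_area",
    "derive_wing_measures",
    "landmark_distances",
    "method1_variables",
    "method2_variables",
    "method3_residuals",
]


@dataclass
class WingMeasures:
    """Physical wing measures for one specimen (mm, mm², g)."""

    hand_wing_length: float
    arm_wing_length: float
    wing_span: float
    arm_wing_area: float
    hand_wing_area: float
    tail_area: float
    wing_area: float
    body_mass: float
    forearm_length: float

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, "
                                 f"got {value}")


@dataclass
class TraditionalVariables:
    """A named per-specimen variable matrix for one traditional method."""

    method: int
    names: list[str]
    values: np.ndarray
    specimen_ids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "individual_id", self.specimen_ids)
        df.insert(1, "method", self.method)
        return df


def polygon_area(points: np.ndarray, name: str = "polygon") -> float:
    """Shoelace area of a simple polygon; rejects self-intersecting loops."""
    poly = Polygon(points)
    if not poly.is_valid:
        raise ValueError(f"self-intersecting loop: {name}")
    return float(poly.area)


def _midline_axis_distance(coords: np.ndarray, midline_idx) -> float:
    """Perpendicular distance of the wingtip from the body midline axis.

    The axis is the total-least-squares line through the declared midline
    landmarks; the distance is measured from the first landmark (wingtip).
    """
    pts = coords[np.asarray(midline_idx)]
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid)
    direction = vt[0]
    rel = coords[0] - centroid
    return float(abs(rel[0] * direction[1] - rel[1] * direction[0]))


def derive_wing_measures(config, mass_g: float, forearm_mm: float,
                         scale: float | None = None,
                         geometry=None) -> WingMeasures:
    """Compute lengths and areas from one landmark configuration.

    ``geometry`` is a template geometry descriptor (landmark role pairs and
    area loops); by default the 17-landmark half-wing template's geometry is
    used. ``scale`` (units per coordinate) overrides the configuration's own
    scale; coordinates default to being already in mm.
    """
    if geometry is None:
        from .synthetic import TEMPLATE_GEOMETRY
        geometry = TEMPLATE_GEOMETRY
    coords = np.asarray(config.coords if hasattr(config, "coords")
                        else config, dtype=float)
    if scale is None:
        scale = getattr(config, "scale", None) or 1.0
    xy = coords * scale

    def dist(pair):
        i, j = pair
        return float(np.linalg.norm(xy[i - 1] - xy[j - 1]))

    def area(loop, name):
        return polygon_area(xy[np.asarray(loop) - 1], name=name)

    span = 2.0 * _midline_axis_distance(
        xy, np.asarray(geometry["midline"]) - 1)
    return WingMeasures(
        hand_wing_length=dist(geometry["hand_wing_length"]),
        arm_wing_length=dist(geometry["arm_wing_length"]),
        wing_span=span,
        arm_wing_area=area(geometry["armwing_loop"], "armwing"),
        hand_wing_area=area(geometry["handwing_loop"], "handwing"),
        tail_area=area(geometry["tail_loop"], "tail"),
        wing_area=area(geometry["wing_loop"], "wing"),
        body_mass=mass_g,
        forearm_length=forearm_mm,
    )


def landmark_distances(config, scale: float | None = None,
                       geometry=None) -> dict[str, float]:
    """The four digit/phalanx distances used by method 3 (d13, d57, ph1, ph2).

    d13 spans the 3rd digit (landmarks 1-7), d57 the 5th digit (7-9), ph1
    and ph2 the first (5-6) and second (4-5) phalanges of the 4th digit.
    """
    if geometry is None:
        from .synthetic import TEMPLATE_GEOMETRY
        geometry = TEMPLATE_GEOMETRY
    coords = np.asarray(config.coords if hasattr(config, "coords")
                        else config, dtype=float)
    if scale is None:
        scale = getattr(config, "scale", None) or 1.0
    xy = coords * scale
    out = {}
    for name, (i, j) in geometry["method3_pairs"].items():
        out[name] = float(np.linalg.norm(xy[i - 1] - xy[j - 1]))
    return out


def _wing_ratios(m: WingMeasures) -> dict[str, float]:
    t_l = m.hand_wing_length / m.arm_wing_length
    t_s = m.hand_wing_area / m.arm_wing_area
    if abs(t_l - t_s) < 1e-12:
        raise ValueError(
            "wingtip shape index undefined: tip length ratio equals tip "
            "area ratio")
    index = t_s / (t_l - t_s)
    aspect = m.wing_span**2 / m.wing_area
    mass_kg = m.body_mass / 1000.0
    area_m2 = m.wing_area / 1e6
    wl = mass_kg * G0 / area_m2
    return {"tip_length_ratio": t_l, "tip_area_ratio": t_s,
            "wingtip_shape_index": index, "aspect_ratio": aspect,
            "wing_loading": wl, "mass_kg": mass_kg}


METHOD1_NAMES = ["tip_length_ratio", "tip_area_ratio", "wingtip_shape_index",
                 "aspect_ratio", "wing_loading"]
METHOD2_NAMES = ["tip_length_ratio", "tip_area_ratio", "wingtip_shape_index",
                 "aspect_ratio", "relative_wing_loading",
                 "tail_wing_area_ratio"]
METHOD3_NAMES = ["d13_residual", "d57_residual", "ph1_residual",
                 "ph2_residual"]


def method1_variables(measures, specimen_ids=None) -> TraditionalVariables:
    """Method 1: the five classical 'size-independent' wing variables."""
    measures, specimen_ids = _as_list(measures, specimen_ids)
    rows = []
    for m in measures:
        r = _wing_ratios(m)
        rows.append([r[n] for n in METHOD1_NAMES])
    return TraditionalVariables(method=1, names=list(METHOD1_NAMES),
                                values=np.array(rows),
                                specimen_ids=specimen_ids)


def method2_variables(measures, specimen_ids=None) -> TraditionalVariables:
    """Method 2: wing loading replaced by relative wing loading
    (WL / mass^(1/3), mass in kg) and the tail-to-wing area ratio added."""
    measures, specimen_ids = _as_list(measures, specimen_ids)
    rows = []
    for m in measures:
        r = _wing_ratios(m)
        rwl = r["wing_loading"] / r["mass_kg"] ** (1.0 / 3.0)
        twr = m.tail_area / m.wing_area
        rows.append([r["tip_length_ratio"], r["tip_area_ratio"],
                     r["wingtip_shape_index"], r["aspect_ratio"], rwl, twr])
    return TraditionalVariables(method=2, names=list(METHOD2_NAMES),
                                values=np.array(rows),
                                specimen_ids=specimen_ids)


def method3_residuals(distances: pd.DataFrame, forearm: np.ndarray,
                      specimen_ids=None) -> TraditionalVariables:
    """Method 3: residuals of digit lengths on forearm length (pooled OLS).

    Each of the four distances (columns d13, d57, ph1, ph2, in mm) is
    regressed on forearm length across all specimens pooled; the residual
    vectors are the discriminating variables. Residuals are exactly
    orthogonal to forearm length and sum to zero (OLS identities).
    """
    forearm = np.asarray(forearm, dtype=float)
    if len(forearm) < 3:
        raise ValueError("need at least 3 specimens")
    if np.ptp(forearm) == 0:
        raise ValueError("forearm length is constant; residuals undefined")
    if specimen_ids is None:
        specimen_ids = np.arange(len(forearm))
    x = np.column_stack([np.ones_like(forearm), forearm])
    resids = []
    for col in ["d13", "d57", "ph1", "ph2"]:
        y = distances[col].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resids.append(y - x @ beta)
    return TraditionalVariables(method=3, names=list(METHOD3_NAMES),
                                values=np.column_stack(resids),
                                specimen_ids=np.asarray(specimen_ids))


def _as_list(measures, specimen_ids):
    if isinstance(measures, WingMeasures):
        measures = [measures]
    measures = list(measures)
    if specimen_ids is None:
        specimen_ids = np.arange(len(measures))
    return measures, np.asarray(specimen_ids)
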