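"""Synthetic replicated bat-wing landmark datasets with known truth.

Emulates a photograph-based study design for five European horseshoe bat
species: each individual is fixed twice on a copy stand and photographed,
and three photos per individual (two from the better fixation, one from the
other) are digitized with 17 landmarks on the right wing half. The
generator produces raw digitizing coordinates with the statistical
structure the downstream analysis assumes:

* a template half-wing shape with named anatomical landmark roles;
* species mean-shape offsets, decomposed into a size-correlated component
  along a common allometric direction (evolutionary allometry) plus small
  idiosyncratic, mostly tail/shoulder-region, contrasts;
* static (within-species) allometry: individual shape covaries with log
  centroid size along the same allometric vector, calibrated so that a
  pooled within-group regression of shape on size explains a target
  fraction (default 16%) of within-species shape variance;
* hierarchical isotropic Gaussian landmark noise at the individual,
  fixation and photo levels (photo/digitizing error smallest);
* nuisance similarity transforms (rotation, translation, slight scale
  jitter) applied to each emitted photo configuration;
* body mass scaling isometrically with centroid size (mass ∝ CS³ with
  lognormal noise) and forearm length proportional to centroid size.

Everything is reproducible from the configuration's seed, and the
generating truth (mean shapes, allometric vector, noise levels) is recorded
for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tps import LandmarkConfiguration
from . import procrustes

logger = logging.getLogger(__name__)

__all__ = [
    "LANDMARK_ROLES",
    "TEMPLATE_GEOMETRY",
    "SpeciesSpec",
    "GeneratorConfig",
    "SimulatedDataset",
    "build_template_wing",
    "allometric_direction",
    "default_config",
    "simulate_dataset",
    "traditional_table_from_dataset",
]


# ----------------------------------------------------------------------------
# template half-wing
# ----------------------------------------------------------------------------

#: 1-based anatomical roles of the 17 landmarks.
LANDMARK_ROLES = {
    1: "digit3_tip",            # wingtip, most distal point
    2: "digit3_distal_joint",
    3: "digit3_proximal_joint",
    4: "digit4_tip",
    5: "digit4_interphalangeal_joint",
    6: "digit4_metacarpal_joint",
    7: "wrist",
    8: "elbow",
    9: "digit5_tip",
    10: "shoulder",
    11: "body_midline_cranial",
    12: "body_midline_caudal",
    13: "armwing_trailing_edge",
    14: "tail_tip",
    15: "propatagium_edge",
    16: "handwing_trailing_edge",
    17: "handwing_membrane_notch",
}

# raw template coordinates (x spanwise, y cranial-positive, y-up Cartesian),
# drawn so every declared area loop is a simple polygon
_TEMPLATE_RAW = np.array([
    (5.00, 1.00),    # 1  digit3_tip
    (4.00, 1.08),    # 2  digit3_distal_joint
    (3.00, 1.05),    # 3  digit3_proximal_joint
    (4.10, -0.15),   # 4  digit4_tip
    (3.30, 0.25),    # 5  digit4_interphalangeal_joint
    (2.50, 0.55),    # 6  digit4_metacarpal_joint
    (2.00, 0.80),    # 7  wrist
    (1.10, 0.15),    # 8  elbow
    (2.60, -1.00),   # 9  digit5_tip
    (0.55, 0.90),    # 10 shoulder
    (0.00, 1.25),    # 11 body_midline_cranial
    (0.00, -0.95),   # 12 body_midline_caudal
    (1.30, -1.35),   # 13 armwing_trailing_edge
    (0.00, -2.10),   # 14 tail_tip
    (1.30, 1.00),    # 15 propatagium_edge
    (3.30, -0.75),   # 16 handwing_trailing_edge
    (4.62, 0.35),    # 17 handwing_membrane_notch
])

#: landmark role pairs, area loops and midline roles (all 1-based)
TEMPLATE_GEOMETRY = {
    "hand_wing_length": (7, 1),          # wrist to wingtip
    "arm_wing_length": (10, 7),          # shoulder to wrist
    "handwing_loop": [7, 3, 2, 1, 17, 4, 16, 9],
    "armwing_loop": [7, 15, 10, 11, 12, 13, 9],
    "tail_loop": [12, 13, 14],
    "wing_loop": [11, 10, 15, 7, 3, 2, 1, 17, 4, 16, 9, 13, 14, 12],
    "midline": [11, 12, 14],
    "method3_pairs": {"d13": (1, 7), "d57": (7, 9),
                      "ph1": (5, 6), "ph2": (4, 5)},
    "wireframe_links": [(1, 2), (2, 3), (3, 7), (7, 6), (6, 5), (5, 4),
                        (7, 9), (7, 8), (8, 10), (1, 17), (17, 4), (4, 16),
                        (16, 9), (9, 13), (13, 14), (13, 12), (12, 14),
                        (10, 11), (10, 15), (15, 7), (11, 12)],
}


def build_template_wing(n_landmarks: int = 17) -> np.ndarray:
    """The centered, unit-centroid-size template half wing (17 x 2).

    Only the 17-landmark scheme is supported; other counts are rejected.
    """
    if n_landmarks != 17:
        raise ValueError(
            f"unsupported landmark count {n_landmarks}; the template "
            "defines 17 anatomical roles")
    coords = procrustes.center_configuration(_TEMPLATE_RAW)
    return coords / procrustes.centroid_size(coords)


def _tangent_field(template: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Center a displacement field and remove similarity nuisance components.

    Projects a raw (k, 2) displacement field onto the tangent space at the
    template (orthogonal to translations, rotation and scaling), so adding
    it to the template changes shape only.
    """
    q = procrustes.nuisance_basis(template)
    v = np.asarray(raw, dtype=float).ravel()
    v = v - (v @ q) @ q.T
    return v.reshape(template.shape)


def _unit_field(template: np.ndarray, raw: np.ndarray) -> np.ndarray:
    v = _tangent_field(template, raw)
    return v / np.linalg.norm(v)


# direction of shape change per unit increase in log centroid size: larger
# bats have the wing reaching less far cranially (digit-3 region pulled
# caudally/inward), a relatively shorter hand wing and arm wing trailing
# edge, mirroring the dominant interspecific contrast
_ALLOMETRY_RAW = np.zeros((17, 2))
_ALLOMETRY_RAW[0] = (-0.12, -0.30)   # digit3 tip pulled back and in
_ALLOMETRY_RAW[1] = (-0.08, -0.25)
_ALLOMETRY_RAW[2] = (-0.05, -0.18)
_ALLOMETRY_RAW[3] = (-0.10, -0.12)   # digit4 tip: handwing 4-1 shortens
_ALLOMETRY_RAW[4] = (-0.05, -0.05)
_ALLOMETRY_RAW[6] = (0.02, -0.05)    # wrist
_ALLOMETRY_RAW[7] = (0.03, 0.05)     # elbow
_ALLOMETRY_RAW[8] = (0.05, 0.02)     # digit5 tip
_ALLOMETRY_RAW[9] = (-0.02, -0.05)   # shoulder
_ALLOMETRY_RAW[10] = (0.00, -0.10)   # cranial midline: body front recedes
_ALLOMETRY_RAW[11] = (0.00, 0.02)
_ALLOMETRY_RAW[12] = (0.08, 0.08)    # armwing trailing edge toward digit5
_ALLOMETRY_RAW[14] = (0.00, -0.03)
_ALLOMETRY_RAW[15] = (-0.05, -0.08)
_ALLOMETRY_RAW[16] = (-0.08, -0.15)


def _scale_free_ratios(coords: np.ndarray) -> np.ndarray:
    """The scale-free classical ratios of a configuration.

    Tip length ratio, tip area ratio, wingtip shape index, aspect ratio and
    tail-to-wing area ratio — the shape-visible parts of the method-1/2
    variable sets (wing loading depends on size and mass, not shape).
    """
    from .traditional import polygon_area

    g = TEMPLATE_GEOMETRY

    def dist(pair):
        i, j = pair
        return float(np.linalg.norm(coords[i - 1] - coords[j - 1]))

    def area(loop):
        return polygon_area(coords[np.asarray(loop) - 1])

    t_l = dist(g["hand_wing_length"]) / dist(g["arm_wing_length"])
    t_s = area(g["handwing_loop"]) / area(g["armwing_loop"])
    wing = area(g["wing_loop"])
    pts = coords[np.asarray(g["midline"]) - 1]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    d = vt[0]
    rel = coords[0] - centroid
    span = 2.0 * abs(rel[0] * d[1] - rel[1] * d[0])
    return np.array([t_l, t_s, t_s / (t_l - t_s), span**2 / wing,
                     area(g["tail_loop"]) / wing])


def _ratio_gradients(template: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Finite-difference Jacobian (2k, 5) of the scale-free ratios."""
    base = _scale_free_ratios(template)
    grads = np.zeros((template.size, len(base)))
    flat = template.ravel()
    for i in range(template.size):
        plus = flat.copy(); plus[i] += eps
        minus = flat.copy(); minus[i] -= eps
        grads[i] = (_scale_free_ratios(plus.reshape(template.shape))
                    - _scale_free_ratios(minus.reshape(template.shape))
                    ) / (2 * eps)
    return grads


def allometric_direction() -> np.ndarray:
    """Unit tangent field of the default allometric shape change.

    The drafted displacement field is projected onto the orthogonal
    complement of the similarity nuisance directions AND of the gradients
    of the classical scale-free ratios at the template: to first order the
    dominant interspecific shape trend is invisible to the ratio-based
    variable sets while remaining fully visible to the landmark
    configuration — the localized, relational kind of shape change that
    motivates landmark-based morphometrics.
    """
    template = build_template_wing()
    q_nuis = procrustes.nuisance_basis(template)
    grads = _ratio_gradients(template)
    basis = np.column_stack([q_nuis, grads])
    q, _ = np.linalg.qr(basis)
    v = _tangent_field(template, _ALLOMETRY_RAW).ravel()
    v = v - (v @ q) @ q.T
    return (v / np.linalg.norm(v)).reshape(template.shape)


# idiosyncratic (size-independent) species contrasts: tail/trailing-edge
# components (visible to the tail-to-wing area ratio), phalanx-proportion
# components on the digit-4 joints and digit-5 tip (visible to the digit
# length residuals, largely invisible to area/span ratios) and elbow
# components (visible only to the full landmark configuration);
# (raw field, tangent norm)
_SPECIES_CONTRAST_RAW = {
    "R_hipposideros": (
        {14: (0.0, -1.0), 13: (0.25, -0.25), 6: (-0.9, 0.34),
         5: (0.6, -0.2), 8: (0.25, -0.3)}, 0.030),
    "R_blasii": (
        {14: (0.0, 1.0), 13: (0.35, 0.0), 11: (0.0, 0.3),
         5: (-0.9, 0.44), 8: (-0.2, 0.2)}, 0.032),
    "R_euryale": (
        {6: (0.4, -0.15), 5: (0.35, -0.17), 13: (-0.1, 0.1),
         8: (0.15, 0.25)}, 0.009),
    "R_mehelyi": (
        {6: (-0.4, 0.15), 5: (-0.35, 0.17), 13: (-0.05, 0.15),
         8: (0.1, -0.25)}, 0.009),
    "R_ferrumequinum": (
        {14: (0.0, -0.8), 10: (-0.3, 0.0), 5: (0.6, 0.3),
         6: (0.35, -0.5), 8: (0.25, 0.2)}, 0.024),
}


def _species_contrast(template: np.ndarray, name: str,
                      allometry_unit: np.ndarray) -> np.ndarray:
    """Build a species' idiosyncratic offset, orthogonal to the allometric
    direction, with the configured tangent norm."""
    sparse, norm = _SPECIES_CONTRAST_RAW[name]
    raw = np.zeros((17, 2))
    for lm, vec in sparse.items():
        raw[lm - 1] = vec
    v = _tangent_field(template, raw).ravel()
    a = allometry_unit.ravel()
    v = v - (v @ a) * a
    v = v / np.linalg.norm(v) * norm
    return v.reshape(17, 2)


# ----------------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------------

@dataclass
class SpeciesSpec:
    """Generating parameters for one species."""

    name: str
    n_individuals: int
    mean_log_centroid_size: float     # log mm
    sd_log_centroid_size: float
    species_shape_offset: np.ndarray  # (17, 2) tangent field, centered

    def __post_init__(self):
        self.species_shape_offset = np.asarray(self.species_shape_offset,
                                               dtype=float)
        if self.n_individuals < 2:
            raise ValueError(f"{self.name}: need at least 2 individuals")
        if self.sd_log_centroid_size < 0:
            raise ValueError(f"{self.name}: negative size sd")
        colsum = np.abs(self.species_shape_offset.sum(axis=0)).max()
        if colsum > 1e-8:
            raise ValueError(
                f"{self.name}: species_shape_offset is not centered "
                f"(column sums {self.species_shape_offset.sum(axis=0)})")


@dataclass
class GeneratorConfig:
    """Full generating model for a replicated landmark dataset."""

    species: list
    n_landmarks: int = 17
    allometric_vector: np.ndarray | None = None  # (17, 2) per unit log CS
    target_static_allometry_fraction: float = 0.16
    evolutionary_allometry_gain: float = 3.2
    individual_noise_sd: float = 0.006
    fixation_noise_sd: float = 0.0015
    photo_noise_sd: float = 0.002
    n_fixations: int = 2
    photos_kept: int = 3
    mass_coefficient: float = 1.6e-6  # g per mm^3 of CS^exponent
    mass_exponent: float = 3.0
    mass_noise_sd: float = 0.20       # lognormal sd
    forearm_coefficient: float = 0.25  # forearm mm per mm of CS
    forearm_noise_sd: float = 0.01
    rotation_range_deg: float = 15.0
    translation_range: float = 50.0
    scale_jitter_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.allometric_vector is not None:
            self.allometric_vector = np.asarray(self.allometric_vector,
                                                dtype=float)
        for name in ("individual_noise_sd", "fixation_noise_sd",
                     "photo_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.target_static_allometry_fraction < 1:
            raise ValueError(
                "target_static_allometry_fraction must be in [0, 1)")
        if self.photos_kept < 1 or self.n_fixations < 1:
            raise ValueError("need at least one fixation and one photo")

    @property
    def n_individuals_total(self) -> int:
        return sum(s.n_individuals for s in self.species)


def _photo_split(n_fixations: int, photos_kept: int) -> list[int]:
    """Photos per fixation: best fixation gets the extras (e.g. 3 -> 2+1)."""
    base, extra = divmod(photos_kept, n_fixations)
    return [base + (1 if i < extra else 0) for i in range(n_fixations)]


def calibrated_allometry_norm(config_like) -> float:
    """Allometric-vector magnitude hitting the target variance fraction.

    After 3-photo replicate averaging the residual (non-allometric)
    within-species tangent variance is about d_eff * (sd_ind^2 +
    w_fix * sd_fix^2 + sd_photo^2 / n_photos) with d_eff = 2k - 4 and w_fix
    the squared-weight factor of the fixation split. Solving
    f = allo / (allo + resid) for the allometric variance and dividing by
    the within-species log-size sd gives the vector magnitude.
    """
    c = config_like
    d_eff = 2 * c.n_landmarks - 4
    split = np.array(_photo_split(c.n_fixations, c.photos_kept), dtype=float)
    w_fix = float(np.sum((split / split.sum()) ** 2))
    resid = d_eff * (c.individual_noise_sd**2
                     + w_fix * c.fixation_noise_sd**2
                     + c.photo_noise_sd**2 / split.sum())
    f = c.target_static_allometry_fraction
    allo_var = f / (1.0 - f) * resid
    sd_sizes = np.array([s.sd_log_centroid_size for s in c.species])
    n = np.array([s.n_individuals for s in c.species], dtype=float)
    pooled_sd2 = float(np.sum((n - 1) * sd_sizes**2) / np.sum(n - 1))
    if pooled_sd2 <= 0:
        raise ValueError(
            "inconsistent config: zero within-species size variance with a "
            "nonzero static allometry fraction requested")
    return float(np.sqrt(allo_var / pooled_sd2))


#: default species: sample sizes and a size ordering with R. hipposideros
#: smallest and R. ferrumequinum largest (centroid sizes in mm)
_DEFAULT_SPECIES = [
    ("R_hipposideros", 6, 150.0),
    ("R_blasii", 7, 192.0),
    ("R_euryale", 22, 200.0),
    ("R_mehelyi", 20, 210.0),
    ("R_ferrumequinum", 21, 240.0),
]


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The calibrated five-species default configuration.

    Species shape offsets are built from the allometric direction (scaled by
    the evolutionary gain and each species' size deviation at simulation
    time) plus fixed idiosyncratic contrasts; the allometric vector's
    magnitude is calibrated analytically so the pooled within-group
    regression explains the target fraction of within-species variance.
    """
    template = build_template_wing()
    a_unit = allometric_direction()
    species = []
    for name, n, cs in _DEFAULT_SPECIES:
        offset = _species_contrast(template, name, a_unit)
        species.append(SpeciesSpec(
            name=name, n_individuals=n,
            mean_log_centroid_size=float(np.log(cs)),
            sd_log_centroid_size=0.06,
            species_shape_offset=offset))
    config = GeneratorConfig(species=species, seed=seed, **overrides)
    if config.allometric_vector is None:
        config.allometric_vector = a_unit * calibrated_allometry_norm(config)
    return config


# ----------------------------------------------------------------------------
# simulation
# ----------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """A simulated study: photo configurations, specimen table and truth."""

    configurations: list
    specimen_table: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def n_photos(self) -> int:
        return len(self.configurations)


def simulate_dataset(config: GeneratorConfig) -> SimulatedDataset:
    """Generate one replicated landmark dataset from a generating model.

    Each photo configuration is template + species offset + evolutionary
    allometric component + static allometric component + individual +
    fixation + photo deviations, then scaled to the individual's centroid
    size, rotated, translated and scale-jittered into raw digitizing
    coordinates (mm).
    """
    rng = np.random.default_rng(config.seed)
    template = build_template_wing(config.n_landmarks)
    a = config.allometric_vector
    if a is None:
        raise ValueError("config has no allometric_vector; use "
                         "default_config() or set one explicitly")
    sd_sizes = [s.sd_log_centroid_size for s in config.species]
    if (max(sd_sizes) == 0
            and config.target_static_allometry_fraction > 0
            and np.linalg.norm(a) > 0):
        raise ValueError(
            "inconsistent config: zero size variance but nonzero "
            "allometry requested")

    grand_mls = float(np.mean([s.mean_log_centroid_size
                               for s in config.species]))
    split = _photo_split(config.n_fixations, config.photos_kept)

    configs: list[LandmarkConfiguration] = []
    rows = []
    truth_means = {}
    for spec in config.species:
        mean_shape = (template + spec.species_shape_offset
                      + config.evolutionary_allometry_gain * a
                      * (spec.mean_log_centroid_size - grand_mls))
        truth_means[spec.name] = mean_shape
        for i in range(spec.n_individuals):
            ind_id = f"{spec.name}_{i + 1:02d}"
            log_cs = rng.normal(spec.mean_log_centroid_size,
                                spec.sd_log_centroid_size)
            cs = float(np.exp(log_cs))
            ind_shape = (mean_shape
                         + a * (log_cs - spec.mean_log_centroid_size)
                         + rng.normal(0.0, config.individual_noise_sd,
                                      template.shape))
            mass = (config.mass_coefficient * cs**config.mass_exponent
                    * float(np.exp(rng.normal(0.0, config.mass_noise_sd))))
            forearm = (config.forearm_coefficient * cs
                       * float(np.exp(rng.normal(0.0,
                                                 config.forearm_noise_sd))))
            for fix in range(config.n_fixations):
                fix_dev = rng.normal(0.0, config.fixation_noise_sd,
                                     template.shape)
                for photo in range(split[fix]):
                    photo_dev = rng.normal(0.0, config.photo_noise_sd,
                                           template.shape)
                    shape = ind_shape + fix_dev + photo_dev
                    raw = _nuisance_transform(shape, cs, rng, config)
                    image_id = f"{ind_id}_f{fix + 1}p{photo + 1}"
                    configs.append(LandmarkConfiguration(
                        coords=raw, image_id=image_id,
                        individual_id=ind_id, fixation=fix + 1, scale=1.0))
                    rows.append({
                        "individual_id": ind_id, "species": spec.name,
                        "fixation": fix + 1, "photo": photo + 1,
                        "true_centroid_size": cs, "mass_g": mass,
                        "forearm_mm": forearm})

    table = pd.DataFrame(rows)
    truth = {
        "species_mean_shapes": truth_means,
        "allometric_vector": a.copy(),
        "evolutionary_allometry_gain": config.evolutionary_allometry_gain,
        "noise_sds": {"individual": config.individual_noise_sd,
                      "fixation": config.fixation_noise_sd,
                      "photo": config.photo_noise_sd},
        "seed": config.seed,
    }
    return SimulatedDataset(configurations=configs, specimen_table=table,
                            truth=truth)


def _nuisance_transform(shape, cs, rng, config):
    """Scale to size, rotate, translate and jitter into raw coordinates."""
    theta = np.deg2rad(rng.uniform(-config.rotation_range_deg,
                                   config.rotation_range_deg))
    rot = np.array([[np.cos(theta), np.sin(theta)],
                    [-np.sin(theta), np.cos(theta)]])
    jitter = float(np.exp(rng.normal(0.0, config.scale_jitter_sd)))
    offset = rng.uniform(0.0, config.translation_range, size=2)
    return shape * cs * jitter @ rot + offset


# ----------------------------------------------------------------------------
# bridge to traditional morphometrics
# ----------------------------------------------------------------------------

def traditional_table_from_dataset(dataset: SimulatedDataset
                                   ) -> pd.DataFrame:
    """Per-specimen measurement table from the first best-fixation photo.

    For each individual, the first photo of fixation 1 is measured with
    :func:`wingmorph.traditional.derive_wing_measures` (lengths, areas) and
    :func:`wingmorph.traditional.landmark_distances` (method-3 distances).
    Specimens whose noisy configuration yields a self-intersecting area
    loop are excluded with a logged warning.
    """
    from .traditional import derive_wing_measures, landmark_distances

    chosen: dict[str, LandmarkConfiguration] = {}
    for cfg in dataset.configurations:
        if cfg.fixation == 1 and cfg.individual_id not in chosen:
            chosen[cfg.individual_id] = cfg

    meta = (dataset.specimen_table
            .drop_duplicates("individual_id").set_index("individual_id"))
    rows = []
    for ind_id, cfg in chosen.items():
        info = meta.loc[ind_id]
        try:
            m = derive_wing_measures(cfg, mass_g=float(info["mass_g"]),
                                     forearm_mm=float(info["forearm_mm"]))
        except ValueError as exc:
            logger.warning("excluding %s: %s", ind_id, exc)
            continue
        d = landmark_distances(cfg)
        rows.append({
            "individual_id": ind_id, "species": info["species"],
            "hand_wing_length": m.hand_wing_length,
            "arm_wing_length": m.arm_wing_length,
            "wing_span": m.wing_span,
            "arm_wing_area": m.arm_wing_area,
            "hand_wing_area": m.hand_wing_area,
            "tail_area": m.tail_area, "wing_area": m.wing_area,
            "mass_g": m.body_mass, "forearm_mm": m.forearm_length,
            **d})
    return pd.DataFrame(rows)


def write_dataset(dataset: SimulatedDataset, tps_path, table_path) -> None:
    """Write a simulated dataset as a TPS file plus a specimen CSV."""
    from .tps import write_tps
    write_tps(dataset.configurations, tps_path)
    cols = ["individual_id", "species", "fixation", "photo", "mass_g",
            "forearm_mm"]
    dataset.specimen_table[cols].to_csv(table_path, index=False)
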