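"""Procrustes superimposition and measurement-error decomposition.

Implements the standard geometric-morphometrics tool chain for 2D landmark
configurations: centroid size, ordinary (pairwise) Procrustes alignment,
generalized Procrustes analysis (GPA) with full Procrustes scaling, orthogonal
projection into the tangent space at the consensus, per-individual replicate
averaging, and a nested Procrustes ANOVA that partitions shape variation into
group (species), individual, fixation and photo (digitizing) components.

Conventions follow common morphometrics software: every aligned shape is
centered and scaled to unit centroid size, the consensus is re-centered and
re-scaled at each GPA iteration, and the reported distance is the partial
Procrustes distance (root summed squared differences between unit-size
aligned shapes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedShapeSet",
    "ShapeDataset",
    "ProcrustesAnovaTable",
    "centroid_size",
    "center_configuration",
    "align_pair",
    "gpa",
    "nuisance_basis",
    "project_tangent",
    "average_replicates",
    "procrustes_anova",
]


# ----------------------------------------------------------------------------
# basic geometry
# ----------------------------------------------------------------------------

def centroid_size(coords: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances from centroid.

    Parameters
    ----------
    coords : (k, 2) array of landmark coordinates.

    Raises
    ------
    ValueError if the landmarks are all coincident (size would be zero).
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs <= 0.0:
        raise ValueError("degenerate configuration: all landmarks coincident")
    return cs


def center_configuration(coords: np.ndarray) -> np.ndarray:
    """Translate a configuration so its centroid is at the origin."""
    coords = np.asarray(coords, dtype=float)
    return coords - coords.mean(axis=0)


def _unitize(coords: np.ndarray) -> np.ndarray:
    """Center and scale to unit centroid size (pre-shape)."""
    c = center_configuration(coords)
    return c / centroid_size(c)


def _optimal_rotation(moving: np.ndarray, target: np.ndarray,
                      allow_reflection: bool = False) -> np.ndarray:
    """2x2 rotation (optionally improper) minimizing ||moving @ R - target||.

    Kabsch solution via SVD of the cross-covariance. When reflections are
    disallowed the smallest singular value's sign is flipped to force
    det(R) = +1.
    """
    h = moving.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    if allow_reflection or d > 0:
        return u @ vt
    flip = np.diag([1.0, -1.0])
    return u @ flip @ vt


def align_pair(moving: np.ndarray, target: np.ndarray,
               allow_reflection: bool = False) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes superimposition of ``moving`` onto ``target``.

    Both configurations are centered and scaled to unit centroid size; the
    moving one is then rotated (optionally reflected) to minimize the summed
    squared distance to the target.

    Returns
    -------
    (aligned, distance) : the superimposed moving configuration and the
    partial Procrustes distance (root of the minimized sum of squares).
    """
    m = np.asarray(moving, dtype=float)
    t = np.asarray(target, dtype=float)
    if m.shape != t.shape:
        raise ValueError(
            f"landmark count mismatch: {m.shape} vs {t.shape}")
    mu = _unitize(m)
    tu = _unitize(t)
    rot = _optimal_rotation(mu, tu, allow_reflection=allow_reflection)
    aligned = mu @ rot
    dist = float(np.linalg.norm(aligned - tu))
    return aligned, dist


# ----------------------------------------------------------------------------
# generalized Procrustes analysis
# ----------------------------------------------------------------------------

@dataclass
class AlignedShapeSet:
    """Superimposed landmark configurations with size and provenance.

    Attributes
    ----------
    shapes : (n, k, 2) aligned coordinates, each centered with unit centroid
        size.
    centroid_sizes : (n,) centroid sizes of the raw configurations.
    consensus : (k, 2) mean shape (centered, unit centroid size).
    provenance : DataFrame with one row per shape; whatever identifier
        columns the caller supplied (individual, species, fixation, photo).
    """

    shapes: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_shapes(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.shapes.shape[1]


def gpa(configs, allow_reflection: bool = False, tol: float = 1e-10,
        max_iter: int = 100, provenance: pd.DataFrame | None = None
        ) -> AlignedShapeSet:
    """Generalized Procrustes analysis with full Procrustes scaling.

    All configurations are centered and scaled to unit centroid size, then
    iteratively rotated to the evolving consensus. The consensus is the
    arithmetic mean of the aligned shapes, re-centered and re-scaled to unit
    centroid size at every iteration; iteration stops when its
    root-mean-square change falls below ``tol``.

    The result is invariant (up to a joint rotation, which does not affect
    inter-shape distances) to the input order and to arbitrary similarity
    transformations of the inputs.
    """
    arrs = [np.asarray(c, dtype=float) for c in configs]
    if len(arrs) < 2:
        raise ValueError("GPA needs at least two configurations")
    k = arrs[0].shape[0]
    if any(a.shape != (k, 2) for a in arrs):
        raise ValueError("configurations must share the same landmark count")

    sizes = np.array([centroid_size(a) for a in arrs])
    shapes = np.stack([_unitize(a) for a in arrs])

    consensus = shapes[0].copy()
    for _ in range(max_iter):
        for i in range(shapes.shape[0]):
            rot = _optimal_rotation(shapes[i], consensus,
                                    allow_reflection=allow_reflection)
            shapes[i] = shapes[i] @ rot
        new_consensus = _unitize(shapes.mean(axis=0))
        change = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus RMS change {change:.3e})")

    if provenance is None:
        provenance = pd.DataFrame(index=range(len(arrs)))
    else:
        provenance = provenance.reset_index(drop=True)
    return AlignedShapeSet(shapes=shapes, centroid_sizes=sizes,
                           consensus=consensus, provenance=provenance)


# ----------------------------------------------------------------------------
# tangent-space projection
# ----------------------------------------------------------------------------

def nuisance_basis(consensus: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2k, 4) of the similarity nuisance directions.

    At a centered, unit-size consensus the four directions are: uniform x
    translation, uniform y translation, infinitesimal rotation of the
    consensus, and scaling (the consensus itself). For a centered consensus
    these four are mutually orthogonal already; they are normalized and
    re-orthonormalized for safety.
    """
    c = np.asarray(consensus, dtype=float)
    k = c.shape[0]
    tx = np.zeros((k, 2)); tx[:, 0] = 1.0
    ty = np.zeros((k, 2)); ty[:, 1] = 1.0
    rot = np.column_stack([-c[:, 1], c[:, 0]])
    basis = np.stack([tx.ravel(), ty.ravel(), rot.ravel(), c.ravel()], axis=1)
    q, _ = np.linalg.qr(basis)
    return q


def project_tangent(aligned: AlignedShapeSet) -> np.ndarray:
    """Project aligned shapes into the tangent space at the consensus.

    Each shape's deviation from the consensus is orthogonally projected onto
    the complement of the four similarity nuisance directions, giving
    vectors of length 2k with rank at most 2k - 4.
    """
    q = nuisance_basis(aligned.consensus)
    flat = aligned.shapes.reshape(aligned.n_shapes, -1)
    dev = flat - aligned.consensus.ravel()
    return dev - (dev @ q) @ q.T


# ----------------------------------------------------------------------------
# replicate averaging
# ----------------------------------------------------------------------------

@dataclass
class ShapeDataset:
    """Per-individual averaged tangent shapes with size and species labels.

    Attributes
    ----------
    shapes : (n_individuals, 2k) averaged tangent-space shape vectors.
    centroid_sizes : (n_individuals,) mean of the photo centroid sizes.
    species : array of species labels, one per individual.
    individual_ids : array of individual identifiers.
    consensus : (k, 2) consensus shape the tangent space is anchored at.
    """

    shapes: np.ndarray
    centroid_sizes: np.ndarray
    species: np.ndarray
    individual_ids: np.ndarray
    consensus: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.shapes.shape[0]

    def with_shapes(self, shapes: np.ndarray) -> "ShapeDataset":
        """Copy of the dataset with the shape matrix replaced."""
        return ShapeDataset(shapes=np.asarray(shapes, dtype=float),
                            centroid_sizes=self.centroid_sizes.copy(),
                            species=self.species.copy(),
                            individual_ids=self.individual_ids.copy(),
                            consensus=self.consensus.copy())


def average_replicates(tangent: np.ndarray, aligned: AlignedShapeSet,
                       individual_col: str = "individual_id",
                       species_col: str = "species") -> ShapeDataset:
    """Average each individual's photo tangent vectors and centroid sizes.

    Replicate photos (and fixations) of the same individual are reduced to a
    single row: the arithmetic mean of the tangent shape vectors and of the
    photo centroid sizes, further reducing digitizing error.
    """
    prov = aligned.provenance
    if individual_col not in prov.columns:
        raise ValueError(f"provenance lacks column {individual_col!r}")
    ids = prov[individual_col].to_numpy()
    order = pd.unique(ids)
    rows, sizes, species, out_ids = [], [], [], []
    for ind in order:
        mask = ids == ind
        if not mask.any():  # pragma: no cover - unique() guarantees presence
            raise ValueError(f"individual {ind!r} has no photos")
        rows.append(tangent[mask].mean(axis=0))
        sizes.append(float(aligned.centroid_sizes[mask].mean()))
        if species_col in prov.columns:
            species.append(prov.loc[mask, species_col].iloc[0])
        else:
            species.append("all")
        out_ids.append(ind)
    return ShapeDataset(shapes=np.array(rows),
                        centroid_sizes=np.array(sizes),
                        species=np.array(species, dtype=object),
                        individual_ids=np.array(out_ids, dtype=object),
                        consensus=aligned.consensus.copy())


# ----------------------------------------------------------------------------
# Procrustes ANOVA
# ----------------------------------------------------------------------------

@dataclass
class ProcrustesAnovaTable:
    """Nested decomposition of shape variation (sums over all coordinates).

    ``table`` has one row per effect (species, individual, fixation,
    residual) with columns SS, df, MS, F, p. F compares each effect's MS to
    the next level down; p-values are permutation based. SS are additive:
    they sum to the total SS of the tangent coordinates.
    """

    table: pd.DataFrame
    total_ss: float
    n_permutations: int

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "Effect"
        out.to_csv(path)


def _group_ss(x: np.ndarray, codes: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-group means and the between-group SS about the grand mean."""
    n_groups = codes.max() + 1
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    sums = np.zeros((n_groups, x.shape[1]))
    np.add.at(sums, codes, x)
    means = sums / counts[:, None]
    grand = x.mean(axis=0)
    ss = float(np.sum(counts[:, None] * (means - grand) ** 2))
    return means, ss


def _nested_ss(x: np.ndarray, levels: list[np.ndarray]) -> list[float]:
    """Sequential nested sums of squares for a hierarchy of groupings.

    ``levels`` are integer codes from coarsest (e.g. species) to finest
    (e.g. fixation); the residual is the within-finest-cell scatter. The
    returned list has one SS per level plus the residual, summing exactly to
    the total SS.
    """
    grand = x.mean(axis=0)
    fitted = np.broadcast_to(grand, x.shape).copy()
    ss_list = []
    for codes in levels:
        n_groups = codes.max() + 1
        counts = np.bincount(codes, minlength=n_groups).astype(float)
        sums = np.zeros((n_groups, x.shape[1]))
        np.add.at(sums, codes, x)
        means = sums / counts[:, None]
        level_fit = means[codes]
        ss_list.append(float(np.sum((level_fit - fitted) ** 2)))
        fitted = level_fit
    ss_list.append(float(np.sum((x - fitted) ** 2)))
    return ss_list


def procrustes_anova(tangent: np.ndarray, provenance: pd.DataFrame,
                     species_col: str = "species",
                     individual_col: str = "individual_id",
                     fixation_col: str = "fixation",
                     include_fixation: bool = True,
                     n_permutations: int = 999,
                     n_landmarks: int | None = None,
                     rng: np.random.Generator | None = None
                     ) -> ProcrustesAnovaTable:
    """Nested Procrustes ANOVA on tangent coordinates.

    Partitions the total coordinate-wise sum of squares into species,
    individual-within-species, fixation-within-individual (optional) and
    photo residual components. Degrees of freedom are the conventional
    nested df multiplied by the shape-space dimension 2k - 4. F ratios test
    each effect against the next level down; p-values come from permuting
    units one level below the tested effect ((count+1)/(N+1) estimator).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.asarray(tangent, dtype=float)
    n = x.shape[0]
    if n_landmarks is None:
        n_landmarks = x.shape[1] // 2
    dim = 2 * n_landmarks - 4

    sp = pd.factorize(provenance[species_col])[0]
    # nest individuals within species, fixations within individuals
    ind_key = pd.factorize(
        provenance[species_col].astype(str) + "|"
        + provenance[individual_col].astype(str))[0]
    levels = [sp, ind_key]
    names = ["species", "individual"]
    if include_fixation and fixation_col in provenance.columns:
        fix_key = pd.factorize(
            provenance[individual_col].astype(str) + "|"
            + provenance[fixation_col].astype(str))[0]
        # fixation level is only meaningful if it refines individuals and
        # leaves photo replication below it
        if fix_key.max() > ind_key.max() and fix_key.max() + 1 < n:
            levels.append(fix_key)
            names.append("fixation")
        else:
            logger.info("no photo replication below fixations; "
                        "fixation level merged into residual")

    ss = _nested_ss(x, levels)
    names = names + ["residual"]
    n_units = [codes.max() + 1 for codes in levels] + [n]
    df = []
    prev = 1
    for units in n_units:
        df.append((units - prev) * dim)
        prev = units
    df = np.array(df, dtype=float)
    ss = np.array(ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        ms = np.where(df > 0, ss / df, np.nan)
    f = np.full(len(ss), np.nan)
    for i in range(len(ss) - 1):
        if np.isfinite(ms[i + 1]) and ms[i + 1] > 0:
            f[i] = ms[i] / ms[i + 1]

    # permutation p-values: permute the units one level below the effect
    pvals = np.full(len(ss), np.nan)
    for i in range(len(levels)):
        if not np.isfinite(f[i]):
            continue
        pvals[i] = _permute_f(x, levels, i, f[i], dim,
                              n_permutations, rng)

    table = pd.DataFrame({"SS": ss, "df": df.astype(int), "MS": ms,
                          "F": f, "p": pvals}, index=names)
    return ProcrustesAnovaTable(table=table, total_ss=float(ss.sum()),
                                n_permutations=n_permutations)


def _permute_f(x, levels, effect_idx, f_obs, dim, n_perm, rng) -> float:
    """Permutation p-value for one nested effect.

    Units one level below the tested effect are shuffled across the effect's
    groups (restricted within the enclosing stratum, if any), the nested
    decomposition is recomputed, and the F ratio compared with the observed.
    """
    codes = levels[effect_idx]
    if effect_idx + 1 < len(levels):
        sub = levels[effect_idx + 1]
    else:
        sub = np.arange(x.shape[0])  # photos
    strata = levels[effect_idx - 1] if effect_idx > 0 else np.zeros(
        x.shape[0], dtype=int)

    # map each sub-unit to its effect-group and stratum
    n_sub = sub.max() + 1
    sub_to_effect = np.zeros(n_sub, dtype=int)
    sub_to_stratum = np.zeros(n_sub, dtype=int)
    sub_to_effect[sub] = codes
    sub_to_stratum[sub] = strata

    count = 0
    for _ in range(n_perm):
        perm_effect = sub_to_effect.copy()
        for s in np.unique(sub_to_stratum):
            mask = sub_to_stratum == s
            perm_effect[mask] = rng.permutation(perm_effect[mask])
        new_codes = perm_effect[sub]
        new_levels = list(levels)
        new_levels[effect_idx] = pd.factorize(
            new_codes.astype(str) + "|" + strata.astype(str))[0] \
            if effect_idx > 0 else new_codes
        ss = _nested_ss(x, new_levels)
        n_units = [c.max() + 1 for c in new_levels] + [x.shape[0]]
        prev = 1
        df = []
        for units in n_units:
            df.append((units - prev) * dim)
            prev = units
        with np.errstate(divide="ignore", invalid="ignore"):
            ms = [s / d if d > 0 else np.nan for s, d in zip(ss, df)]
        denom = ms[effect_idx + 1]
        if denom and np.isfinite(denom) and denom > 0:
            f_perm = ms[effect_idx] / denom
            if f_perm >= f_obs:
                count += 1
    return (count + 1) / (n_perm + 1)
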