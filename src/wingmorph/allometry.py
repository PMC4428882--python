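"""Allometric correction and size-shape regressions.

Static (within-species) allometry is removed by a pooled within-group
regression of shape on centroid size: shape and size are centered within
species, a single common slope vector is fitted by least squares on the
pooled centered data, and the residuals — which retain the species mean
differences — replace the raw shapes in downstream analyses. A
permutation-based homogeneity-of-slopes test stands in for the parametric
MANCOVA interaction test (which is ill-posed when a species has fewer
individuals than shape dimensions), and a simple scores-on-size regression
quantifies evolutionary allometry along an ordination axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .procrustes import ShapeDataset

__all__ = [
    "AllometryModel",
    "ScoreSizeRegression",
    "pooled_within_group_regression",
    "test_common_slopes",
    "regress_scores_on_size",
]


@dataclass
class AllometryModel:
    """Fitted pooled within-group allometry.

    ``pooled_slope_vector`` is shape change per unit of the size variable
    (centroid size, or log centroid size when ``use_log_size``);
    ``residual_shapes`` are the allometry-corrected shapes, with species
    mean differences retained (observed minus slope times within-species
    centered size).
    """

    pooled_slope_vector: np.ndarray
    species_intercepts: dict
    percent_variance_explained: float
    residual_shapes: np.ndarray
    use_log_size: bool
    size_variable: np.ndarray

    def corrected_dataset(self, dataset: ShapeDataset) -> ShapeDataset:
        """The input dataset with shapes replaced by corrected residuals."""
        return dataset.with_shapes(self.residual_shapes)

    def to_csv(self, path) -> None:
        """Flat CSV: one row for the slope vector, one per species
        intercept, plus a summary row with the percent variance."""
        import pandas as pd

        rows = [{"term": "pooled_slope",
                 **{f"c{i}": v for i, v in
                    enumerate(self.pooled_slope_vector)}}]
        for species, intercept in self.species_intercepts.items():
            rows.append({"term": f"intercept_{species}",
                         **{f"c{i}": v for i, v in enumerate(intercept)}})
        rows.append({"term": "percent_variance_explained",
                     "c0": self.percent_variance_explained})
        pd.DataFrame(rows).to_csv(path, index=False)


def _within_center(values: np.ndarray, species: np.ndarray):
    centered = values.astype(float).copy()
    means = {}
    for s in np.unique(species):
        mask = species == s
        mu = centered[mask].mean(axis=0)
        centered[mask] = centered[mask] - mu
        means[s] = mu
    return centered, means


def pooled_within_group_regression(dataset: ShapeDataset,
                                   use_log_size: bool = False
                                   ) -> AllometryModel:
    """Fit a common within-species slope of shape on centroid size.

    Shape vectors and sizes are centered within species; the common slope is
    the least-squares solution on the pooled centered data. The percent of
    variance explained is 100 x predicted SS / total SS of the pooled
    centered shapes (predicted and residual SS add up to the total exactly).
    """
    species = dataset.species
    uniq, counts = np.unique(species, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two species")
    if counts.min() < 3:
        small = uniq[counts.argmin()]
        raise ValueError(f"species {small!r} has fewer than 3 individuals")
    size = np.log(dataset.centroid_sizes) if use_log_size \
        else dataset.centroid_sizes
    x_c, x_means = _within_center(size[:, None], species)
    x_c = x_c[:, 0]
    for s, mu in x_means.items():
        if np.allclose(size[species == s], mu):
            raise ValueError(f"species {s!r} has zero size variance")
    y_c, y_means = _within_center(dataset.shapes, species)

    sxx = float(x_c @ x_c)
    slope = (x_c @ y_c) / sxx
    predicted = np.outer(x_c, slope)
    ss_pred = float(np.sum(predicted**2))
    ss_total = float(np.sum(y_c**2))
    residual = dataset.shapes - predicted
    return AllometryModel(
        pooled_slope_vector=slope,
        species_intercepts=y_means,
        percent_variance_explained=100.0 * ss_pred / ss_total,
        residual_shapes=residual,
        use_log_size=use_log_size,
        size_variable=size.copy(),
    )


def test_common_slopes(dataset: ShapeDataset, n_perm: int = 999,
                       use_log_size: bool = False,
                       rng: np.random.Generator | None = None) -> float:
    """Permutation test of slope homogeneity across species.

    The statistic is the reduction in residual shape SS when each species
    gets its own slope instead of the common pooled slope, scaled by the
    common-slope residual SS (Goodall-style F numerator). Under the null of
    a common slope the common-slope residuals are exchangeable across
    species: residuals are permuted across all specimens, data rebuilt from
    the common fit plus permuted residuals, and the statistic recomputed.
    Returns the (count+1)/(n_perm+1) p-value.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if rng is None:
        rng = np.random.default_rng(0)
    species = dataset.species
    size = np.log(dataset.centroid_sizes) if use_log_size \
        else dataset.centroid_sizes
    x_c, _ = _within_center(size[:, None], species)
    x_c = x_c[:, 0]
    y_c, _ = _within_center(dataset.shapes, species)

    def statistic(y):
        sxx = float(x_c @ x_c)
        common = np.outer(x_c, (x_c @ y) / sxx)
        ss_common = float(np.sum((y - common) ** 2))
        ss_sep = 0.0
        for s in np.unique(species):
            m = species == s
            sxx_s = float(x_c[m] @ x_c[m])
            fit = np.outer(x_c[m], (x_c[m] @ y[m]) / sxx_s)
            ss_sep += float(np.sum((y[m] - fit) ** 2))
        return (ss_common - ss_sep) / ss_common

    obs = statistic(y_c)
    sxx = float(x_c @ x_c)
    common_fit = np.outer(x_c, (x_c @ y_c) / sxx)
    resid = y_c - common_fit
    count = 0
    for _ in range(n_perm):
        y_perm = common_fit + resid[rng.permutation(len(resid))]
        # recenter within species: permuted residuals need not balance
        y_perm, _ = _within_center(y_perm, species)
        if statistic(y_perm) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


@dataclass
class ScoreSizeRegression:
    """OLS of ordination scores on size with a permutation p-value."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float


def regress_scores_on_size(scores: np.ndarray, sizes: np.ndarray,
                           n_perm: int = 999,
                           rng: np.random.Generator | None = None
                           ) -> ScoreSizeRegression:
    """Ordinary least squares of per-individual scores on centroid size.

    ``r_squared`` is the squared Pearson correlation; the p-value permutes
    the score-size pairing ((count+1)/(n_perm+1) estimator). Constant
    scores give slope 0, r² 0 and p 1.
    """
    scores = np.asarray(scores, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if len(scores) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(sizes) == 0:
        raise ValueError("size variance is zero")
    if np.ptp(scores) == 0:
        return ScoreSizeRegression(slope=0.0, intercept=float(scores[0]),
                                   r_squared=0.0, p_value=1.0)
    if rng is None:
        rng = np.random.default_rng(0)
    x_c = sizes - sizes.mean()
    y_c = scores - scores.mean()
    slope = float(x_c @ y_c / (x_c @ x_c))
    intercept = float(scores.mean() - slope * sizes.mean())
    r = float(x_c @ y_c / np.sqrt((x_c @ x_c) * (y_c @ y_c)))
    r2_obs = r * r
    count = 0
    for _ in range(n_perm):
        yp = y_c[rng.permutation(len(y_c))]
        rp = float(x_c @ yp / np.sqrt((x_c @ x_c) * (yp @ yp)))
        if rp * rp >= r2_obs:
            count += 1
    return ScoreSizeRegression(slope=slope, intercept=intercept,
                               r_squared=r2_obs,
                               p_value=(count + 1) / (n_perm + 1))
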