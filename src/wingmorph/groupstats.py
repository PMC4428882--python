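"""Between-group ordination, mean-shape tests and shape visualization.

Between-group PCA (bwgPCA) computes principal axes from the covariance of
the k unweighted species mean shapes and projects every specimen onto them;
unlike canonical variate analysis the ordination does not exaggerate group
separation, and per-axis variance is reported as a share of the TOTAL
specimen variance. Pairwise mean-shape differences are tested by permuting
specimen group labels, with the tangent-space Euclidean distance between
group means (equal to the Procrustes distance in the small-variation
regime) as the statistic. Shape results can be mirrored about the body
midline into symmetric "bat-like" displays and exported as SVG wireframes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .procrustes import ShapeDataset

__all__ = [
    "BwgPcaResult",
    "PairwiseShapeTest",
    "between_group_pca",
    "pairwise_permutation_test",
    "all_pairwise_tests",
    "species_mean_contrasts",
    "reflect_for_display",
    "export_wireframe",
    "export_scatter",
]


@dataclass
class BwgPcaResult:
    """Between-group PCA axes, specimen scores and variance shares."""

    axes: np.ndarray                 # (2k, n_axes) orthonormal columns
    specimen_scores: np.ndarray      # (n, n_axes)
    percent_total_variance: np.ndarray
    species_means: dict              # label -> (k, 2) mean shape
    grand_mean: np.ndarray           # (k, 2), unweighted mean of means
    species: np.ndarray
    consensus: np.ndarray

    def mean_shape(self, label) -> np.ndarray:
        return self.species_means[label]


def between_group_pca(dataset: ShapeDataset,
                      weighted: bool = False) -> BwgPcaResult:
    """PCA of the species mean shapes with all specimens projected.

    Group means are unweighted by default (each species counts once,
    despite unequal sample sizes); the variance share of each axis is the
    variance of all specimen scores on it divided by the total specimen
    variance, so the k-1 between-group axes need not sum to 100%.
    """
    species = dataset.species
    uniq = list(pd.unique(species))
    if len(uniq) < 2:
        raise ValueError("between-group PCA needs at least two groups")
    k2 = dataset.shapes.shape[1]
    means = np.array([dataset.shapes[species == s].mean(axis=0)
                      for s in uniq])
    counts = np.array([(species == s).sum() for s in uniq], dtype=float)
    weights = counts / counts.sum() if weighted \
        else np.full(len(uniq), 1.0 / len(uniq))
    grand = weights @ means
    dm = (means - grand) * np.sqrt(weights[:, None])
    cov = dm.T @ dm
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][: len(uniq) - 1]
    axes = evecs[:, order]
    sign = np.sign(axes[np.abs(axes).argmax(axis=0),
                        np.arange(axes.shape[1])])
    sign[sign == 0] = 1.0
    axes = axes * sign

    centered = dataset.shapes - grand
    scores = centered @ axes
    total_var = float(np.sum(
        (dataset.shapes - dataset.shapes.mean(axis=0)) ** 2))
    score_var = np.sum((scores - scores.mean(axis=0)) ** 2, axis=0)
    percent = 100.0 * score_var / total_var

    k = k2 // 2
    mean_shapes = {s: (dataset.consensus.ravel() + means[i]).reshape(k, 2)
                   for i, s in enumerate(uniq)}
    grand_shape = (dataset.consensus.ravel() + grand).reshape(k, 2)
    return BwgPcaResult(axes=axes, specimen_scores=scores,
                        percent_total_variance=percent,
                        species_means=mean_shapes, grand_mean=grand_shape,
                        species=species.copy(),
                        consensus=dataset.consensus.copy())


# ----------------------------------------------------------------------------
# permutation tests on mean-shape differences
# ----------------------------------------------------------------------------

@dataclass
class PairwiseShapeTest:
    """Pairwise mean-shape distances and permutation p-values."""

    distance_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    n_perm: int

    def to_csv(self, path) -> None:
        """Write a combined table: distances above the diagonal, p-values
        below."""
        labels = list(self.distance_matrix.index)
        out = pd.DataFrame("", index=labels, columns=labels, dtype=object)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    out.loc[a, b] = f"{self.distance_matrix.loc[a, b]:.6g}"
                elif i > j:
                    out.loc[a, b] = f"{self.p_matrix.loc[a, b]:.6g}"
                else:
                    out.loc[a, b] = "-"
        out.to_csv(path)


def pairwise_permutation_test(dataset: ShapeDataset, group_a, group_b,
                              n_perm: int = 999,
                              rng: np.random.Generator | None = None,
                              full_procrustes: bool = False
                              ) -> tuple[float, float]:
    """Permutation test of equal mean shapes for two species.

    The statistic is the Euclidean tangent-space distance between the two
    group mean shapes (equal to the Procrustes distance for small shape
    variation); the null distribution reshuffles the specimens of the two
    groups across the group labels ``n_perm`` times. With
    ``full_procrustes`` the group mean configurations are rebuilt from the
    tangent vectors and re-superimposed for every permutation, so the
    statistic is the actual partial Procrustes distance — a sensitivity
    check for the linear approximation. Returns (distance, p) with the
    (count+1)/(n_perm+1) estimator.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if rng is None:
        rng = np.random.default_rng(0)
    mask_a = dataset.species == group_a
    mask_b = dataset.species == group_b
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need at least 2 specimens")
    x = np.vstack([dataset.shapes[mask_a], dataset.shapes[mask_b]])

    if full_procrustes:
        from .procrustes import align_pair
        k = dataset.consensus.shape[0]
        base = dataset.consensus.ravel()

        def statistic(a_rows, b_rows):
            mean_a = (base + a_rows.mean(axis=0)).reshape(k, 2)
            mean_b = (base + b_rows.mean(axis=0)).reshape(k, 2)
            return align_pair(mean_a, mean_b)[1]
    else:
        def statistic(a_rows, b_rows):
            return float(np.linalg.norm(a_rows.mean(axis=0)
                                        - b_rows.mean(axis=0)))

    obs = statistic(x[:n_a], x[n_a:])
    if obs == 0.0:
        return 0.0, 1.0
    count = 0
    n = n_a + n_b
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if statistic(x[perm[:n_a]], x[perm[n_a:]]) >= obs:
            count += 1
    return obs, (count + 1) / (n_perm + 1)


def all_pairwise_tests(dataset: ShapeDataset, n_perm: int = 999,
                       rng: np.random.Generator | None = None
                       ) -> PairwiseShapeTest:
    """Distance and p-value matrices for every species pair."""
    if rng is None:
        rng = np.random.default_rng(0)
    labels = list(pd.unique(dataset.species))
    dist = pd.DataFrame(0.0, index=labels, columns=labels)
    pval = pd.DataFrame(1.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d, p = pairwise_permutation_test(dataset, a, b, n_perm=n_perm,
                                             rng=rng)
            dist.loc[a, b] = dist.loc[b, a] = d
            pval.loc[a, b] = pval.loc[b, a] = p
    return PairwiseShapeTest(distance_matrix=dist, p_matrix=pval,
                             n_perm=n_perm)


# ----------------------------------------------------------------------------
# mean-shape contrasts and display
# ----------------------------------------------------------------------------

def species_mean_contrasts(dataset: ShapeDataset) -> dict:
    """Each species' mean shape minus the unweighted grand mean.

    Returns label -> (k, 2) landmark displacement field; the unweighted sum
    of the fields over species is zero at every landmark.
    """
    labels = list(pd.unique(dataset.species))
    k = dataset.shapes.shape[1] // 2
    means = {s: dataset.shapes[dataset.species == s].mean(axis=0)
             for s in labels}
    grand = np.mean([means[s] for s in labels], axis=0)
    return {s: (means[s] - grand).reshape(k, 2) for s in labels}


def reflect_for_display(shape: np.ndarray,
                        midline_idx=None) -> np.ndarray:
    """Mirror a half-configuration about the body midline axis.

    Midline landmarks (1-based indices; default: the template's declared
    midline roles) stay single; every other landmark gains a mirrored
    partner, appended after the originals in landmark order. The output has
    2k - m landmarks for m midline roles.
    """
    if midline_idx is None:
        from .synthetic import TEMPLATE_GEOMETRY
        midline_idx = TEMPLATE_GEOMETRY["midline"]
    midline_idx = np.asarray(midline_idx, dtype=int)
    if midline_idx.size == 0:
        raise ValueError("no midline landmarks declared")
    coords = np.asarray(shape, dtype=float)
    pts = coords[midline_idx - 1]
    centroid = pts.mean(axis=0)
    if len(pts) > 1:
        _, _, vt = np.linalg.svd(pts - centroid)
        d = vt[0]
    else:
        d = np.array([0.0, 1.0])
    d = d / np.linalg.norm(d)
    rel = coords - centroid
    along = rel @ d
    perp = rel - np.outer(along, d)
    mirrored = centroid + np.outer(along, d) - perp
    others = np.setdiff1d(np.arange(coords.shape[0]),
                          midline_idx - 1)
    return np.vstack([coords, mirrored[others]])


def export_wireframe(shape: np.ndarray, reference_shape: np.ndarray,
                     links, path, width: int = 640) -> None:
    """Write an SVG overlaying target (colored) and reference (grey)
    wireframes, plus a CSV of both coordinate sets next to it.

    ``links`` are 1-based landmark index pairs; the SVG contains exactly
    two line elements per link (one per shape).
    """
    shape = np.asarray(shape, dtype=float)
    ref = np.asarray(reference_shape, dtype=float)
    k = shape.shape[0]
    for i, j in links:
        if not (1 <= i <= k and 1 <= j <= k):
            raise ValueError(f"link ({i}, {j}) references an invalid "
                             f"landmark (1..{k})")
    both = np.vstack([shape, ref])
    lo = both.min(axis=0)
    hi = both.max(axis=0)
    span = max(hi[0] - lo[0], hi[1] - lo[1], 1e-12)
    pad = 0.05 * span
    scale = width / (span + 2 * pad)

    def to_px(p):
        # y-up data to y-down SVG
        return ((p[0] - lo[0] + pad) * scale,
                (hi[1] - p[1] + pad) * scale)

    height = int((hi[1] - lo[1] + 2 * pad) * scale) or width
    lines = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
             f'height="{height}">']
    for coords, color, sw in ((ref, "#999999", 1.5), (shape, "#c03028", 2)):
        for i, j in links:
            x1, y1 = to_px(coords[i - 1])
            x2, y2 = to_px(coords[j - 1])
            lines.append(
                f'<line x1="{x1:.2f}" y1="{y1:.2f}" x2="{x2:.2f}" '
                f'y2="{y2:.2f}" stroke="{color}" stroke-width="{sw}"/>')
    lines.append("</svg>")
    path = Path(path)
    path.write_text("\n".join(lines), encoding="utf-8")

    csv_path = path.with_suffix(".csv")
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["landmark", "shape_x", "shape_y",
                         "reference_x", "reference_y"])
        for idx in range(k):
            writer.writerow([idx + 1, repr(float(shape[idx, 0])),
                             repr(float(shape[idx, 1])),
                             repr(float(ref[idx, 0])),
                             repr(float(ref[idx, 1]))])


def export_scatter(result: BwgPcaResult, path) -> None:
    """Scatterplot of the first two between-group PC scores by species."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    labels = list(pd.unique(result.species))
    for s in labels:
        mask = result.species == s
        xs = result.specimen_scores[mask, 0]
        ys = (result.specimen_scores[mask, 1]
              if result.specimen_scores.shape[1] > 1
              else np.zeros(mask.sum()))
        ax.scatter(xs, ys, label=str(s), s=22, alpha=0.8)
    ax.set_xlabel(f"bwgPC1 ({result.percent_total_variance[0]:.1f}% of "
                  "total variance)")
    if len(result.percent_total_variance) > 1:
        ax.set_ylabel(f"bwgPC2 ({result.percent_total_variance[1]:.1f}%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
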