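"""Cross-validated discriminant classification of per-specimen variables.

Leave-one-out cross-validation (LOOCV) with linear discriminant analysis:
for each held-out specimen the discriminant is refitted on the remainder
(pooled within-group covariance, Moore-Penrose pseudo-inverse at relative
tolerance 1e-10 so p >= n folds are handled; equal priors) and the specimen
is assigned to the nearest group mean in the Mahalanobis metric. The
multi-group variant (canonical variate analysis) classifies to the nearest
group centroid in canonical space. PCA reduction and Anderson's
equality-of-trailing-eigenvalues test support the dimensionality-reduction
path that counters the artefactual inflation of LDA rates at high
dimension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PINV_RTOL = 1e-10

__all__ = [
    "ClassificationReport",
    "PcReduction",
    "loocv_pairwise",
    "loocv_multigroup",
    "resubstitution_rate",
    "pca_reduce",
    "anderson_retain",
]


@dataclass
class ClassificationReport:
    """Cross-validated correct classification rates for one variable set."""

    method: str
    overall_rate: float
    per_species_rates: dict
    confusion: pd.DataFrame
    pairwise_rates: dict | None = None

    @property
    def pairwise_average(self) -> float | None:
        if not self.pairwise_rates:
            return None
        return float(np.mean(list(self.pairwise_rates.values())))

    @property
    def pairwise_range(self) -> tuple | None:
        if not self.pairwise_rates:
            return None
        vals = list(self.pairwise_rates.values())
        return (float(min(vals)), float(max(vals)))


def _drop_constant_columns(x_train: np.ndarray) -> np.ndarray:
    """Indices of variables with nonzero variance in the training fold."""
    var = x_train.var(axis=0)
    keep = np.flatnonzero(var > 0)
    if len(keep) < x_train.shape[1]:
        logger.info("dropping %d zero-variance variable(s) for this fold",
                    x_train.shape[1] - len(keep))
    return keep


def _pooled_within(x: np.ndarray, codes: np.ndarray, n_groups: int):
    """Group means and pooled within-group covariance (df = n - k)."""
    n, p = x.shape
    means = np.zeros((n_groups, p))
    scatter = np.zeros((p, p))
    for g in range(n_groups):
        xg = x[codes == g]
        means[g] = xg.mean(axis=0)
        d = xg - means[g]
        scatter += d.T @ d
    return means, scatter / max(n - n_groups, 1)


def loocv_pairwise(data: np.ndarray, labels) -> tuple[float, pd.DataFrame]:
    """LOOCV linear discriminant rate for exactly two groups.

    Returns (percent correct, confusion matrix). Ties in the Mahalanobis
    comparison are broken in group label order (logged).
    """
    x = np.asarray(data, dtype=float)
    codes, uniq = pd.factorize(np.asarray(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected two groups, got {len(uniq)}")
    return _loocv_mahalanobis(x, codes, uniq)


def _loocv_mahalanobis(x, codes, uniq):
    n_groups = len(uniq)
    counts = np.bincount(codes, minlength=n_groups)
    if counts.min() < 3:
        raise ValueError(
            f"every group needs at least 3 specimens, got {counts.min()}")
    n = x.shape[0]
    confusion = np.zeros((n_groups, n_groups), dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        keep = _drop_constant_columns(x[mask])
        xt = x[mask][:, keep]
        means, w = _pooled_within(xt, codes[mask], n_groups)
        w_inv = np.linalg.pinv(w, rcond=PINV_RTOL)
        d = means - x[i, keep]
        d2 = np.einsum("gi,ij,gj->g", d, w_inv, d)
        assigned = int(np.argmin(d2))  # argmin takes first on ties
        if np.sum(d2 == d2.min()) > 1:
            logger.info("tie in Mahalanobis assignment broken by label "
                        "order for specimen %d", i)
        confusion[codes[i], assigned] += 1
    rate = 100.0 * np.trace(confusion) / n
    conf = pd.DataFrame(confusion, index=list(uniq), columns=list(uniq))
    return rate, conf


def loocv_multigroup(data: np.ndarray, labels,
                     method: str = "") -> ClassificationReport:
    """LOOCV canonical variate analysis across all groups at once.

    Per fold, canonical axes are computed from the training data (whitening
    by the pseudo-inverse square root of the pooled within-group covariance,
    then eigendecomposition of the between-group scatter of training group
    means); the held-out specimen goes to the nearest group centroid in
    canonical space. Equal priors; ties broken by group label order.
    """
    x = np.asarray(data, dtype=float)
    codes, uniq = pd.factorize(np.asarray(labels))
    n_groups = len(uniq)
    if n_groups < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes, minlength=n_groups)
    if counts.min() < 3:
        raise ValueError(
            f"every group needs at least 3 specimens, got {counts.min()}")
    n = x.shape[0]
    confusion = np.zeros((n_groups, n_groups), dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        keep = _drop_constant_columns(x[mask])
        xt = x[mask][:, keep]
        ct = codes[mask]
        means, w = _pooled_within(xt, ct, n_groups)
        axes = _canonical_axes(xt, ct, means, w, n_groups)
        z_means = means @ axes
        z_i = x[i, keep] @ axes
        d2 = np.sum((z_means - z_i) ** 2, axis=1)
        assigned = int(np.argmin(d2))
        confusion[codes[i], assigned] += 1
    overall = 100.0 * np.trace(confusion) / n
    per_species = {lab: 100.0 * confusion[g, g] / counts[g]
                   for g, lab in enumerate(uniq)}
    conf = pd.DataFrame(confusion, index=list(uniq), columns=list(uniq))
    return ClassificationReport(method=method, overall_rate=overall,
                                per_species_rates=per_species,
                                confusion=conf)


def _canonical_axes(xt, ct, means, w, n_groups):
    """Canonical variate axes: whiten by pinv(W)^(1/2), rotate to the
    between-group eigenvectors."""
    evals, evecs = np.linalg.eigh(w)
    tol = max(evals.max(), 0) * PINV_RTOL
    nz = evals > tol
    whiten = evecs[:, nz] / np.sqrt(evals[nz])
    n_g = np.bincount(ct, minlength=n_groups).astype(float)
    grand = xt.mean(axis=0)
    mz = (means - grand) @ whiten
    b = (mz * n_g[:, None]).T @ mz / max(n_groups - 1, 1)
    bev, bvec = np.linalg.eigh(b)
    order = np.argsort(bev)[::-1][: n_groups - 1]
    return whiten @ bvec[:, order]


def pairwise_report(data: np.ndarray, labels,
                    method: str = "") -> ClassificationReport:
    """Multi-group CVA report augmented with all pairwise LOOCV rates."""
    report = loocv_multigroup(data, labels, method=method)
    x = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    uniq = list(pd.unique(labels))
    pairwise = {}
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            mask = (labels == a) | (labels == b)
            rate, _ = loocv_pairwise(x[mask], labels[mask])
            pairwise[(a, b)] = rate
    report.pairwise_rates = pairwise
    return report


def resubstitution_rate(data: np.ndarray, labels) -> float:
    """Apparent (training-set) correct classification rate.

    The discriminant is fitted once on all specimens and every specimen is
    classified with it. At high dimension relative to sample size this
    apparent rate inflates far above chance even for pure noise — the
    artefact that motivates cross-validation and dimensionality reduction
    before discriminant analysis.
    """
    x = np.asarray(data, dtype=float)
    codes, uniq = pd.factorize(np.asarray(labels))
    n_groups = len(uniq)
    means, w = _pooled_within(x, codes, n_groups)
    w_inv = np.linalg.pinv(w, rcond=PINV_RTOL)
    correct = 0
    for i in range(x.shape[0]):
        d = means - x[i]
        d2 = np.einsum("gi,ij,gj->g", d, w_inv, d)
        correct += int(np.argmin(d2) == codes[i])
    return 100.0 * correct / x.shape[0]


# ----------------------------------------------------------------------------
# PCA reduction and Anderson's test
# ----------------------------------------------------------------------------

@dataclass
class PcReduction:
    """Principal components of the centered covariance, sorted by eigenvalue."""

    loadings: np.ndarray      # (p, n_retained), orthonormal columns
    scores: np.ndarray        # (n, n_retained)
    eigenvalues: np.ndarray   # all eigenvalues, nonincreasing
    n_retained: int
    mean: np.ndarray


def pca_reduce(data: np.ndarray, n_components: int) -> PcReduction:
    """Covariance PCA retaining the first ``n_components`` axes.

    Signs are fixed so each axis's largest-magnitude loading is positive.
    Raises if more components are requested than the data's rank.
    """
    x = np.asarray(data, dtype=float)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    rank = int(np.sum(evals > evals[0] * 1e-12)) if evals[0] > 0 else 0
    if n_components > rank:
        raise ValueError(
            f"requested {n_components} components but the data rank is "
            f"{rank}")
    sign = np.sign(evecs[np.abs(evecs).argmax(axis=0),
                         np.arange(evecs.shape[1])])
    sign[sign == 0] = 1.0
    evecs = evecs * sign
    loadings = evecs[:, :n_components]
    return PcReduction(loadings=loadings, scores=xc @ loadings,
                       eigenvalues=evals, n_retained=n_components,
                       mean=mean)


def anderson_retain(eigenvalues: np.ndarray, n: int,
                    alpha: float = 0.05) -> int:
    """Smallest k for which the trailing eigenvalues are plausibly equal.

    Anderson's chi-square test of sphericity of the trailing p - k
    eigenvalues: the statistic -(n-1) [sum(log l_i) - (p-k) log(mean l)]
    over the trailing set is referred to a chi-square with
    (p-k+2)(p-k-1)/2 degrees of freedom. Returns the smallest k whose
    trailing test is non-significant at ``alpha``.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    p = len(lam)
    if n <= p:
        raise ValueError("sample size must exceed the number of eigenvalues")
    if np.any(lam <= 0):
        raise ValueError("all eigenvalues must be strictly positive")
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigenvalues must be nonincreasing")
    for k in range(p - 1):
        trail = lam[k:]
        q = len(trail)
        statistic = -(n - 1) * (np.sum(np.log(trail))
                                - q * np.log(trail.mean()))
        df = (q + 2) * (q - 1) / 2.0
        p_value = stats.chi2.sf(statistic, df)
        if p_value > alpha:
            return k
    return p - 1
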