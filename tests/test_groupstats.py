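"""Between-group PCA, mean-shape permutation tests, contrasts and
display exports."""

import numpy as np
import pytest

import wingmorph.groupstats as gs
import wingmorph.synthetic as syn
from wingmorph.procrustes import ShapeDataset


def make_dataset(rng, group_means, n_per_group, noise=0.05, k=5):
    shapes, species = [], []
    for g, (mean, n) in enumerate(zip(group_means, n_per_group)):
        for _ in range(n):
            shapes.append(np.asarray(mean, float)
                          + rng.normal(scale=noise, size=2 * k))
            species.append(f"sp{g}")
    n_tot = len(shapes)
    return ShapeDataset(shapes=np.array(shapes),
                        centroid_sizes=np.linspace(90, 110, n_tot),
                        species=np.array(species, dtype=object),
                        individual_ids=np.array(
                            [f"i{j}" for j in range(n_tot)], dtype=object),
                        consensus=np.zeros((k, 2)))


def bwgpca_oracle(dataset):
    """Independent between-group PCA: explicit unweighted means covariance
    eigendecomposition via SVD, then projection of centered specimens."""
    labels = list(dict.fromkeys(dataset.species))
    means = np.array([dataset.shapes[dataset.species == s].mean(axis=0)
                      for s in labels])
    grand = means.mean(axis=0)
    u, sv, vt = np.linalg.svd(means - grand, full_matrices=False)
    axes = vt[: len(labels) - 1].T
    scores = (dataset.shapes - grand) @ axes
    total = np.sum((dataset.shapes - dataset.shapes.mean(axis=0)) ** 2)
    percent = 100.0 * np.sum(
        (scores - scores.mean(axis=0)) ** 2, axis=0) / total
    return axes, scores, percent


def test_two_groups_single_axis_collinear_with_mean_difference(rng):
    ds = make_dataset(rng, [np.zeros(10), np.ones(10)], [8, 9])
    res = gs.between_group_pca(ds)
    labels = list(dict.fromkeys(ds.species))
    means = [ds.shapes[ds.species == s].mean(axis=0) for s in labels]
    diff = means[0] - means[1]
    nonzero = res.percent_total_variance > 1e-10
    assert nonzero.sum() == 1
    cosine = np.abs(res.axes[:, 0] @ diff) / np.linalg.norm(diff)
    assert cosine > 1.0 - 1e-10


def test_projected_group_means_equal_mean_of_projections(rng):
    ds = make_dataset(rng, [rng.normal(size=10) for _ in range(4)],
                      [5, 7, 9, 11])
    res = gs.between_group_pca(ds)
    labels = list(dict.fromkeys(ds.species))
    grand = np.mean([ds.shapes[ds.species == s].mean(axis=0)
                     for s in labels], axis=0)
    for s in labels:
        mean_proj = res.specimen_scores[ds.species == s].mean(axis=0)
        proj_mean = (ds.shapes[ds.species == s].mean(axis=0)
                     - grand) @ res.axes
        np.testing.assert_allclose(mean_proj, proj_mean, atol=1e-9)


def test_bwgpca_matches_independent_oracle(shape_dataset):
    res = gs.between_group_pca(shape_dataset)
    axes_o, scores_o, percent_o = bwgpca_oracle(shape_dataset)
    np.testing.assert_allclose(res.percent_total_variance, percent_o,
                               atol=1e-8)
    # axes agree up to sign
    for j in range(axes_o.shape[1]):
        cosine = abs(res.axes[:, j] @ axes_o[:, j])
        assert cosine == pytest.approx(1.0, abs=1e-8)
        sign = np.sign(res.axes[:, j] @ axes_o[:, j])
        np.testing.assert_allclose(res.specimen_scores[:, j],
                                   sign * scores_o[:, j], atol=1e-8)


def test_scores_invariant_under_joint_rotation(shape_dataset):
    """Rotating the whole aligned dataset leaves bwgPCA scores unchanged."""
    res = gs.between_group_pca(shape_dataset)
    theta = 0.31
    k = shape_dataset.shapes.shape[1] // 2
    rot = np.array([[np.cos(theta), np.sin(theta)],
                    [-np.sin(theta), np.cos(theta)]])
    rotated = (shape_dataset.shapes.reshape(-1, k, 2) @ rot).reshape(
        shape_dataset.shapes.shape)
    ds2 = shape_dataset.with_shapes(rotated)
    res2 = gs.between_group_pca(ds2)
    for j in range(res.specimen_scores.shape[1]):
        sign = np.sign(res.axes[:, j] @ ((res2.axes[:, j].reshape(k, 2)
                                          @ rot.T).ravel()))
        np.testing.assert_allclose(res2.specimen_scores[:, j],
                                   sign * res.specimen_scores[:, j],
                                   atol=1e-9)


def test_percent_total_variance_bounded(shape_dataset):
    res = gs.between_group_pca(shape_dataset)
    assert np.all(res.percent_total_variance >= 0.0)
    assert res.percent_total_variance.sum() <= 100.0 + 1e-9


def test_single_group_rejected(rng):
    ds = make_dataset(rng, [np.zeros(10)], [8])
    with pytest.raises(ValueError, match="two groups"):
        gs.between_group_pca(ds)


# ------------------------------------------------------------- permutation test

def test_identical_composition_gives_zero_distance(rng):
    shapes = rng.normal(size=(12, 10))
    ds = ShapeDataset(
        shapes=np.vstack([shapes, shapes]),
        centroid_sizes=np.ones(24),
        species=np.array(["a"] * 12 + ["b"] * 12, dtype=object),
        individual_ids=np.array([f"i{j}" for j in range(24)], dtype=object),
        consensus=np.zeros((5, 2)))
    d, p = gs.pairwise_permutation_test(ds, "a", "b", n_perm=99)
    assert d == 0.0 and p == 1.0


def test_permutation_p_reproducible_and_stable(rng):
    ds = make_dataset(rng, [np.zeros(10), np.ones(10) * 0.05], [10, 10])
    d1, p1 = gs.pairwise_permutation_test(
        ds, "sp0", "sp1", n_perm=499, rng=np.random.default_rng(7))
    d2, p2 = gs.pairwise_permutation_test(
        ds, "sp0", "sp1", n_perm=499, rng=np.random.default_rng(7))
    assert (d1, p1) == (d2, p2)
    _, p4 = gs.pairwise_permutation_test(
        ds, "sp0", "sp1", n_perm=998, rng=np.random.default_rng(8))
    assert abs(p4 - p1) < 2.0 / 499.0 + 1e-12


def test_full_procrustes_statistic_agrees_in_small_variation_regime(
        shape_dataset):
    """Re-superimposing the group means (true partial Procrustes
    distance) agrees with the tangent-space statistic to high relative
    accuracy on study-scale data."""
    d_tan, _ = gs.pairwise_permutation_test(
        shape_dataset, "R_euryale", "R_mehelyi", n_perm=99,
        rng=np.random.default_rng(1))
    d_full, _ = gs.pairwise_permutation_test(
        shape_dataset, "R_euryale", "R_mehelyi", n_perm=99,
        rng=np.random.default_rng(1), full_procrustes=True)
    assert d_tan < 0.06  # the closest species pair
    assert d_full == pytest.approx(d_tan, rel=0.02)


def test_all_pairwise_matrices_symmetric(shape_dataset):
    res = gs.all_pairwise_tests(shape_dataset, n_perm=99,
                                rng=np.random.default_rng(0))
    d = res.distance_matrix
    assert np.allclose(d.to_numpy(), d.to_numpy().T)
    assert np.allclose(np.diag(d.to_numpy()), 0.0)
    p = res.p_matrix.to_numpy()
    assert ((p > 0) & (p <= 1)).all()


# ------------------------------------------------------------- contrasts/display

def test_contrasts_sum_to_zero(shape_dataset):
    contrasts = gs.species_mean_contrasts(shape_dataset)
    total = sum(contrasts.values())
    np.testing.assert_allclose(total, 0.0, atol=1e-10)


def test_single_species_zero_contrast(rng):
    ds = make_dataset(rng, [np.zeros(10)], [8])
    contrasts = gs.species_mean_contrasts(ds)
    np.testing.assert_allclose(contrasts["sp0"], 0.0, atol=1e-12)


def test_known_localized_offset_recovered(rng):
    """A species built with an offset at one landmark shows its contrast
    concentrated there at low noise."""
    k = 6
    base = np.zeros(2 * k)
    offset = np.zeros(2 * k)
    offset[0] = 0.3  # x of landmark 1 only
    ds = make_dataset(rng, [base - offset / 2, base + offset / 2],
                      [20, 20], noise=0.001, k=k)
    contrasts = gs.species_mean_contrasts(ds)
    c = contrasts["sp1"].ravel()
    assert np.abs(c[0]) / np.linalg.norm(c) > 0.9


def _reflect_about(points, axis_points):
    centroid = axis_points.mean(axis=0)
    _, _, vt = np.linalg.svd(axis_points - centroid)
    d = vt[0] / np.linalg.norm(vt[0])
    rel = points - centroid
    along = rel @ d
    perp = rel - np.outer(along, d)
    return centroid + np.outer(along, d) - perp


def test_reflection_symmetric_and_involutive():
    t = syn.build_template_wing()
    sym = gs.reflect_for_display(t)
    midline = np.asarray(syn.TEMPLATE_GEOMETRY["midline"]) - 1
    assert sym.shape[0] == 2 * 17 - len(midline)
    np.testing.assert_allclose(sym[:17], t, atol=1e-15)  # originals kept
    others = np.setdiff1d(np.arange(17), midline)
    mirrored = sym[17:]
    # exact mirror symmetry about the midline axis, and reflecting the
    # mirror again (involution) reproduces the right-side originals
    np.testing.assert_allclose(_reflect_about(t[others], t[midline]),
                               mirrored, atol=1e-12)
    np.testing.assert_allclose(_reflect_about(mirrored, t[midline]),
                               t[others], atol=1e-12)


def test_reflection_requires_midline():
    t = syn.build_template_wing()
    with pytest.raises(ValueError, match="midline"):
        gs.reflect_for_display(t, midline_idx=np.array([], dtype=int))


def test_wireframe_export(tmp_path):
    t = syn.build_template_wing()
    links = syn.TEMPLATE_GEOMETRY["wireframe_links"]
    path = tmp_path / "wire.svg"
    gs.export_wireframe(t, t, links, path)
    text = path.read_text()
    assert text.count("<line") == 2 * len(links)
    import csv
    with open(tmp_path / "wire.csv") as fh:
        rows = list(csv.DictReader(fh))
    assert len(rows) == 17
    for i, row in enumerate(rows):
        assert float(row["shape_x"]) == pytest.approx(t[i, 0], abs=1e-9)
        assert float(row["shape_x"]) == float(row["reference_x"])


def test_wireframe_invalid_link_rejected(tmp_path):
    t = syn.build_template_wing()
    with pytest.raises(ValueError, match="invalid"):
        gs.export_wireframe(t, t, [(1, 99)], tmp_path / "bad.svg")
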