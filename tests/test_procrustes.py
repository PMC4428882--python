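"""Superimposition: centroid size, pairwise/generalized Procrustes,
tangent projection, replicate averaging and the nested ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import wingmorph.procrustes as pro


def rotate(coords, deg):
    t = np.deg2rad(deg)
    r = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
    return coords @ r


# ---------------------------------------------------------------- centroid size

def test_centroid_size_closed_form():
    square = np.array([[0.5, 0.5], [0.5, -0.5], [-0.5, 0.5], [-0.5, -0.5]])
    assert pro.centroid_size(square) == pytest.approx(np.sqrt(2.0))


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 2**32 - 1), st.floats(0.01, 100.0))
def test_centroid_size_homogeneous(seed, c):
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(7, 2))
    assert pro.centroid_size(coords * c) == pytest.approx(
        c * pro.centroid_size(coords), rel=1e-9)


def test_coincident_landmarks_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        pro.centroid_size(np.ones((4, 2)))


# ---------------------------------------------------------------- align_pair

def test_align_pair_similarity_invariance(rng):
    target = rng.normal(size=(8, 2))
    moving = rotate(target, 37.0) * 3.0 + [5.0, -2.0]
    _, dist = pro.align_pair(moving, target)
    assert dist < 1e-10


def test_align_pair_reflection_semantics(rng):
    target = rng.normal(size=(6, 2))
    mirror = target * [-1.0, 1.0]
    _, dist = pro.align_pair(mirror, target, allow_reflection=False)
    assert dist > 1e-3
    _, dist_ref = pro.align_pair(mirror, target, allow_reflection=True)
    assert dist_ref < 1e-10


def grid_oracle_distance(moving, target, n_grid=2_000_000):
    """Brute-force partial Procrustes distance: exhaustive search over the
    rotation angle of the centered unit-size configurations."""
    def unitize(c):
        c = c - c.mean(axis=0)
        return c / np.sqrt(np.sum(c**2))
    m, t = unitize(np.asarray(moving, float)), unitize(np.asarray(target,
                                                                  float))
    # coarse-to-fine grid keeps the cost of a 1e-6-resolution search low
    best_theta, best = 0.0, np.inf
    lo, hi, steps = -np.pi, np.pi, 4000
    for _ in range(4):
        thetas = np.linspace(lo, hi, steps)
        cos, sin = np.cos(thetas), np.sin(thetas)
        # ||m R(theta) - t||^2 = 2 - 2 (a cos + b sin), precompute a, b
        a = np.sum(m * t)
        b = np.sum(m[:, 0] * t[:, 1] - m[:, 1] * t[:, 0])
        vals = 2.0 - 2.0 * (a * cos + b * sin)
        i = int(np.argmin(vals))
        best, best_theta = vals[i], thetas[i]
        width = (hi - lo) / steps
        lo, hi = best_theta - 2 * width, best_theta + 2 * width
    return float(np.sqrt(max(best, 0.0)))


def test_align_pair_matches_rotation_grid_oracle(rng):
    for _ in range(50):
        k = int(rng.integers(3, 9))
        moving = rng.normal(size=(k, 2))
        target = rng.normal(size=(k, 2))
        _, dist = pro.align_pair(moving, target)
        assert dist == pytest.approx(grid_oracle_distance(moving, target),
                                     abs=1e-6)


def test_three_landmark_example_against_grid():
    a = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    b = np.array([[0.0, 0.0], [1.0, 0.1], [-0.1, 1.0]])
    _, dist = pro.align_pair(a, b)
    assert dist == pytest.approx(grid_oracle_distance(a, b), abs=1e-6)


def test_procrustes_distance_is_semimetric(rng):
    shapes = [rng.normal(size=(5, 2)) for _ in range(30)]
    for _ in range(200):
        i, j, k = rng.integers(0, 30, size=3)
        dij = pro.align_pair(shapes[i], shapes[j])[1]
        dji = pro.align_pair(shapes[j], shapes[i])[1]
        assert dij == pytest.approx(dji, abs=1e-10)
        dik = pro.align_pair(shapes[i], shapes[k])[1]
        dkj = pro.align_pair(shapes[k], shapes[j])[1]
        assert dij <= dik + dkj + 1e-6


# ---------------------------------------------------------------- GPA

def test_gpa_identical_up_to_similarity(rng):
    base = rng.normal(size=(6, 2))
    configs = [rotate(base, float(rng.uniform(-180, 180)))
               * float(rng.uniform(0.5, 3.0)) + rng.normal(size=2)
               for _ in range(8)]
    res = pro.gpa(configs)
    total_ss = sum(np.sum((s - res.consensus) ** 2) for s in res.shapes)
    assert total_ss < 1e-18


def test_gpa_rotation_invariance_of_distances(rng):
    configs = [rng.normal(size=(7, 2)) for _ in range(10)]
    res1 = pro.gpa(configs)
    rotated = [rotate(c, float(rng.uniform(-180, 180))) for c in configs]
    res2 = pro.gpa(rotated)

    def pairwise(res):
        flat = res.shapes.reshape(len(configs), -1)
        return np.linalg.norm(flat[:, None] - flat[None, :], axis=2)

    np.testing.assert_allclose(pairwise(res1), pairwise(res2), atol=1e-9)


def test_gpa_order_invariance_of_consensus(rng):
    configs = [rng.normal(size=(5, 2)) for _ in range(10)]
    res1 = pro.gpa(configs)
    order = rng.permutation(10)
    res2 = pro.gpa([configs[i] for i in order])
    aligned, dist = pro.align_pair(res2.consensus, res1.consensus)
    assert dist < 1e-8


def test_gpa_aligned_shapes_centered_unit_size(aligned):
    for s in aligned.shapes:
        assert np.abs(s.mean(axis=0)).max() < 1e-9
        assert np.sqrt(np.sum(s**2)) == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(aligned.consensus.mean(axis=0), 0, atol=1e-9)


# ---------------------------------------------------------------- tangent space

def test_consensus_projects_to_zero(aligned):
    q = pro.nuisance_basis(aligned.consensus)
    v = np.zeros(aligned.consensus.size)  # consensus minus itself
    assert np.linalg.norm(v - (v @ q) @ q.T) == 0.0


def test_tangent_rank_bound(aligned, tangent):
    k = aligned.n_landmarks
    cov = np.cov(tangent.T)
    evals = np.linalg.eigvalsh(cov)
    big = evals > evals.max() * 1e-8
    assert big.sum() <= 2 * k - 4


def test_tangent_norm_matches_procrustes_distance_small_deviations(rng):
    base = rng.normal(size=(10, 2))
    base = (base - base.mean(0)) / pro.centroid_size(base)
    configs = [base + rng.normal(scale=0.002, size=base.shape)
               for _ in range(12)]
    res = pro.gpa(configs)
    tan = pro.project_tangent(res)
    for i, cfg in enumerate(configs):
        _, dist = pro.align_pair(cfg, res.consensus)
        assert np.linalg.norm(tan[i]) == pytest.approx(dist, abs=1e-4)


# ---------------------------------------------------------------- averaging

def test_average_of_identical_photos_is_the_photo(rng):
    base = rng.normal(size=(5, 2))
    configs = [base, base.copy(), base * 2.0 + 1.0]
    prov = pd.DataFrame({"individual_id": ["a", "a", "a"],
                         "species": ["s", "s", "s"]})
    res = pro.gpa(configs, provenance=prov)
    tan = pro.project_tangent(res)
    ds = pro.average_replicates(tan, res)
    assert ds.n_individuals == 1
    np.testing.assert_allclose(ds.shapes[0], tan[0], atol=1e-9)


def test_averaging_reduces_variance_by_replicate_count(rng):
    """Variance of 3-photo averages approaches photo variance / 3."""
    base = rng.normal(size=(8, 2))
    base = (base - base.mean(0)) / pro.centroid_size(base)
    n_ind = 1000
    configs, ids = [], []
    for i in range(n_ind):
        for j in range(3):
            configs.append(base + rng.normal(scale=0.003, size=base.shape))
            ids.append(f"i{i}")
    prov = pd.DataFrame({"individual_id": ids})
    res = pro.gpa(configs, tol=1e-8, max_iter=50, provenance=prov)
    tan = pro.project_tangent(res)
    ds = pro.average_replicates(tan, res)
    photo_var = np.sum(np.var(tan, axis=0))
    avg_var = np.sum(np.var(ds.shapes, axis=0))
    assert avg_var == pytest.approx(photo_var / 3.0, rel=0.15)


# ---------------------------------------------------------------- ANOVA

def _toy_hierarchy(rng, n_species=2, n_ind=3, n_photo=2, k=4):
    rows, configs = [], []
    for s in range(n_species):
        s_eff = rng.normal(scale=0.05, size=(k, 2))
        for i in range(n_ind):
            i_eff = rng.normal(scale=0.02, size=(k, 2))
            for p in range(n_photo):
                configs.append(rng.normal(scale=0.005, size=(k, 2))
                               + s_eff + i_eff + np.eye(k, 2) * 3)
                rows.append({"species": f"s{s}",
                             "individual_id": f"s{s}i{i}", "fixation": 1,
                             "photo": p})
    return configs, pd.DataFrame(rows)


def nested_anova_oracle(x, species, individual):
    """Independent two-level nested ANOVA computed per coordinate and
    summed (direct mean-based formulae, no shared code path)."""
    ss_sp = ss_ind = ss_res = 0.0
    grand = x.mean(axis=0)
    for s in np.unique(species):
        xs = x[species == s]
        ss_sp += len(xs) * np.sum((xs.mean(axis=0) - grand) ** 2)
        for i in np.unique(individual[species == s]):
            xi = x[(species == s) & (individual == i)]
            ss_ind += len(xi) * np.sum((xi.mean(axis=0)
                                        - xs.mean(axis=0)) ** 2)
            ss_res += np.sum((xi - xi.mean(axis=0)) ** 2)
    return ss_sp, ss_ind, ss_res


def test_anova_matches_per_coordinate_nested_oracle(rng):
    configs, prov = _toy_hierarchy(rng)
    res = pro.gpa(configs, provenance=prov)
    tan = pro.project_tangent(res)
    table = pro.procrustes_anova(tan, prov, include_fixation=False,
                                 n_permutations=99).table
    ss_sp, ss_ind, ss_res = nested_anova_oracle(
        tan, prov["species"].to_numpy(), prov["individual_id"].to_numpy())
    assert table.loc["species", "SS"] == pytest.approx(ss_sp, rel=1e-10)
    assert table.loc["individual", "SS"] == pytest.approx(ss_ind, rel=1e-10)
    assert table.loc["residual", "SS"] == pytest.approx(ss_res, rel=1e-10)


def test_anova_partition_identity_unbalanced(tangent, default_dataset):
    """SS additivity holds on the study's unbalanced 2+1 photo design."""
    res = pro.procrustes_anova(tangent, default_dataset.specimen_table,
                               n_permutations=99)
    table = res.table
    total = float(np.sum((tangent - tangent.mean(axis=0)) ** 2))
    assert table["SS"].sum() == pytest.approx(total, rel=1e-8)


def test_anova_zero_photo_noise_gives_zero_residual(rng):
    import wingmorph.synthetic as syn
    cfg = syn.default_config(seed=3, photo_noise_sd=0.0)
    ds = syn.simulate_dataset(cfg)
    res = pro.gpa([c.coords for c in ds.configurations],
                  provenance=ds.specimen_table)
    tan = pro.project_tangent(res)
    table = pro.procrustes_anova(tan, ds.specimen_table,
                                 n_permutations=99).table
    assert table.loc["residual", "SS"] < 1e-12 * table["SS"].sum()
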