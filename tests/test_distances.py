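"""Geographic, environmental, barrier matrices and PhiPT/AMOVA."""
import numpy as np
import pandas as pd
import pytest

from clonescape.distances import (
    DistanceMatrix,
    amova_pair,
    barrier_matrix,
    environment_pca,
    environmental_distances,
    geographic_distances,
    phi_pt_pairwise,
    subsample_robustness,
)
from clonescape.genotypes import BinaryMatrix


def _coords(points):
    return pd.DataFrame(points, columns=["lat", "lon"], index=[f"P{i}" for i in range(len(points))])


def _bm(values, ids=None):
    values = np.asarray(values, dtype=float)
    cols = [("L1", 100 + j) for j in range(values.shape[1])]
    return BinaryMatrix(ids or [f"i{k}" for k in range(len(values))], cols, values)


class TestGeographic:
    def test_analytic_cases(self):
        dm = geographic_distances(_coords([(0, 0), (0, 0), (90, 0), (0, 180)]))
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == pytest.approx(np.pi * 6371 / 2, rel=1e-9)
        assert dm.values[0, 3] == pytest.approx(np.pi * 6371, rel=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            geographic_distances(_coords([(91, 0), (0, 0)]))
        with pytest.raises(ValueError):
            geographic_distances(_coords([(0, 181), (0, 0)]))

    def test_symmetry_and_triangle_inequality(self, rng):
        pts = np.c_[rng.uniform(-80, 80, 12), rng.uniform(-170, 170, 12)]
        d = geographic_distances(_coords(pts)).values
        assert np.allclose(d, d.T)
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-6


class TestEnvironmentPCA:
    def test_perfectly_correlated_variables_load_on_one_axis(self):
        env = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]}, index=list("wxyz"))
        pca = environment_pca(env)
        assert pca.variance_fraction[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one_and_decrease(self, rng):
        env = pd.DataFrame(rng.standard_normal((10, 5)), columns=list("abcde"))
        pca = environment_pca(env)
        assert pca.variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(pca.variance_fraction) <= 1e-12).all()

    def test_scores_reconstruct_data_with_all_components(self, rng):
        env = pd.DataFrame(rng.standard_normal((8, 4)), columns=list("abcd"))
        pca = environment_pca(env, standardize=True)
        X = env.to_numpy()
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        assert np.allclose(pca.scores @ pca.loadings.T, X, atol=1e-10)

    def test_constant_variable_raises_by_name(self):
        env = pd.DataFrame({"a": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="flat"):
            environment_pca(env)

    def test_scale_invariance_of_environmental_distances(self, rng):
        env = pd.DataFrame(rng.standard_normal((9, 6)))
        env.columns = [f"v{i}" for i in range(6)]
        d1 = environmental_distances(environment_pca(env), 2).values
        d2 = environmental_distances(environment_pca(env * 2.0), 2).values
        assert np.allclose(d1, d2, atol=1e-10)

    def test_triangle_inequality(self, rng):
        env = pd.DataFrame(rng.standard_normal((7, 4)))
        env.columns = list("abcd")
        d = environmental_distances(environment_pca(env), 2).values
        n = len(d)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestBarrier:
    def test_three_site_example_and_complement_invariance(self):
        sides = pd.Series([0, 0, 1], index=["P1", "P2", "P3"])
        m = barrier_matrix(sides)
        assert m.values[0, 1] == 0 and m.values[0, 2] == 1 and m.values[1, 2] == 1
        comp = barrier_matrix(1 - sides)
        assert np.array_equal(m.values, comp.values)

    def test_all_same_side_is_zero_matrix(self):
        m = barrier_matrix(pd.Series([1, 1, 1, 1]))
        assert not m.values.any()

    def test_unlabeled_population_rejected(self):
        with pytest.raises(ValueError, match="unlabeled"):
            barrier_matrix(pd.Series([0, np.nan, 1], index=list("abc")))


class TestDistanceMatrixContainer:
    def test_rejects_asymmetry_negative_and_bad_barrier(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]]), kind="barrier")

    def test_csv_roundtrip(self, tmp_path, rng):
        pts = rng.standard_normal((5, 2))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix([f"P{i}" for i in range(5)], squareform(pdist(pts)))
        dm.to_csv(tmp_path / "d.csv")
        back = DistanceMatrix.read_csv(tmp_path / "d.csv")
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values)


class TestAMOVA:
    def test_complete_fixation_gives_phi_one(self):
        res = amova_pair(np.array([[1, 0], [1, 0]]), np.array([[0, 1], [0, 1]]), n_perm=0)
        assert res.ss_within == 0.0
        assert res.phi_pt == 1.0

    def test_all_identical_gives_phi_zero(self):
        x = np.array([[1, 0], [1, 0]])
        assert amova_pair(x, x, n_perm=0).phi_pt == 0.0

    def test_hand_worked_decomposition(self):
        # pops {(1,0),(1,0)} and {(1,0),(0,1)}: SS_total=1.5, SS_within=1,
        # MS_among = MS_within = 0.5 -> sigma2_among = 0 -> PhiPT = 0
        res = amova_pair(np.array([[1, 0], [1, 0]]), np.array([[1, 0], [0, 1]]), n_perm=0)
        assert res.ss_among + res.ss_within == pytest.approx(1.5, abs=1e-12)
        assert res.ss_within == pytest.approx(1.0, abs=1e-12)
        assert res.phi_pt == 0.0
        assert res.sigma2_among_raw == pytest.approx(0.0, abs=1e-12)

    def test_column_duplication_invariance(self, rng):
        x1 = rng.integers(0, 2, (4, 6)).astype(float)
        x2 = rng.integers(0, 2, (5, 6)).astype(float)
        base = amova_pair(x1, x2, n_perm=0).phi_pt
        dup = amova_pair(np.hstack([x1, x1]), np.hstack([x2, x2]), n_perm=0).phi_pt
        assert dup == pytest.approx(base, abs=1e-12)

    def test_group_swap_symmetry(self, rng):
        x1 = rng.integers(0, 2, (3, 5)).astype(float)
        x2 = rng.integers(0, 2, (6, 5)).astype(float)
        assert amova_pair(x1, x2, n_perm=0).phi_pt == pytest.approx(
            amova_pair(x2, x1, n_perm=0).phi_pt, abs=1e-12
        )

    def test_missing_columns_dropped_pairwise_complete(self):
        x1 = np.array([[1, 0, np.nan], [1, 0, 1]])
        x2 = np.array([[0, 1, 0], [0, 1, 1]])
        res = amova_pair(x1, x2, n_perm=0)
        assert res.n_columns == 2
        assert res.phi_pt == 1.0  # the complete columns are fully fixed

    def test_permutation_p_null_calibration(self, rng):
        # exchangeable groups: rejection rate at alpha=0.05 within MC slack
        n_rep, alpha = 200, 0.05
        rej = 0
        for _ in range(n_rep):
            x = rng.integers(0, 2, (10, 8)).astype(float)
            res = amova_pair(x[:5], x[5:], n_perm=99, rng=rng)
            rej += res.p_value <= alpha
        bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rej / n_rep <= bound


class TestPhiPTPairwise:
    def test_matrix_assembly_and_small_population_skip(self, rng):
        vals = rng.integers(0, 2, (13, 6)).astype(float)
        pops = ["a"] * 5 + ["b"] * 6 + ["tiny"] * 2
        res = phi_pt_pairwise(_bm(vals), pops, n_perm=49, seed=1, min_size=3)
        assert res.skipped == ["tiny"]
        assert res.phi.labels == ["a", "b"]
        assert 0 <= res.phi.values[0, 1] <= 1
        assert res.p_values.loc["a", "b"] >= 1 / 50

    def test_row_order_invariance(self, rng):
        vals = rng.integers(0, 2, (12, 5)).astype(float)
        pops = ["a"] * 6 + ["b"] * 6
        base = phi_pt_pairwise(_bm(vals), pops, n_perm=0).phi
        perm = rng.permutation(12)
        shuf = phi_pt_pairwise(_bm(vals[perm]), [pops[i] for i in perm], n_perm=0).phi
        assert np.allclose(base.values, shuf.reindex(base.labels).values)

    def test_fewer_than_two_populations_rejected(self, rng):
        vals = rng.integers(0, 2, (4, 3)).astype(float)
        with pytest.raises(ValueError):
            phi_pt_pairwise(_bm(vals), ["a"] * 4, n_perm=0)


class TestSubsampleRobustness:
    def test_two_replicates_give_one_correlation(self, rng):
        vals = rng.integers(0, 2, (36, 8)).astype(float)
        pops = ["a"] * 12 + ["b"] * 12 + ["c"] * 12
        rep = subsample_robustness(_bm(vals), pops, n_rep=2, size=6, seed=0)
        assert rep.n_replicates == 2 and len(rep.r_values) == 1

    def test_identical_rows_within_pops_give_perfect_correlation(self):
        vals = np.vstack([np.tile(v, (12, 1)) for v in ([1, 0, 0], [0, 1, 0], [0, 0, 1])])
        pops = ["a"] * 12 + ["b"] * 12 + ["c"] * 12
        rep = subsample_robustness(_bm(vals.astype(float)), pops, n_rep=5, size=6, seed=0)
        assert np.allclose(rep.r_values, 1.0)

    def test_seed_reproducibility(self, rng):
        vals = rng.integers(0, 2, (36, 6)).astype(float)
        pops = ["a"] * 12 + ["b"] * 12 + ["c"] * 12
        r1 = subsample_robustness(_bm(vals), pops, n_rep=4, size=6, seed=7)
        r2 = subsample_robustness(_bm(vals), pops, n_rep=4, size=6, seed=7)
        assert np.array_equal(r1.r_values, r2.r_values, equal_nan=True)

    def test_too_few_eligible_populations_rejected(self, rng):
        vals = rng.integers(0, 2, (14, 5)).astype(float)
        pops = ["a"] * 12 + ["b"] * 2
        with pytest.raises(ValueError):
            subsample_robustness(_bm(vals), pops, n_rep=3, size=6)
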