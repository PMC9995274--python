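"""PGLS correctness, OLS, harmonic-mean Ne and pi-based Ne."""

import dendropy
import numpy as np
import pytest
from scipy import stats

from gmrate.comparative import (
    NeTrajectory,
    PGLS,
    check_ultrametric,
    harmonic_mean_ne,
    ne_from_pi,
    ols_adjusted_r2,
    pgls_fit,
    phylo_covariance,
)


def tree_from(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


STAR5 = tree_from("(A:1,B:1,C:1,D:1,E:1);")
BAL4 = tree_from("((A:1,B:1):2,(C:2,D:1.0):1.0);")  # non-ultrametric on purpose
ULTRA4 = tree_from("((A:1,B:1):2,(C:2,D:2):1);")


class TestCovariance:
    def test_star_tree_identity_scaled(self):
        cov = phylo_covariance(STAR5, list("ABCDE"))
        assert np.allclose(cov, np.eye(5))

    def test_balanced_tree_shared_paths(self):
        cov = phylo_covariance(ULTRA4, list("ABCD"))
        # A,B share the 2-long stem; C,D share the 1-long stem; across clades 0
        expected = np.array(
            [[3, 2, 0, 0], [2, 3, 0, 0], [0, 0, 3, 1], [0, 0, 1, 3]], dtype=float
        )
        assert np.allclose(cov, expected)

    def test_missing_species_refused(self):
        with pytest.raises(ValueError, match="missing"):
            phylo_covariance(ULTRA4, ["A", "B", "Z"])

    def test_ultrametricity_check(self):
        assert check_ultrametric(ULTRA4)
        assert not check_ultrametric(BAL4)


class TestPGLS:
    def test_star_tree_equals_ols(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5)
        y = 2.0 * x + rng.normal(size=5)
        fit = pgls_fit(x, y, STAR5, list("ABCDE"))
        slope, adj_r2, p = ols_adjusted_r2(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-8)
        assert fit.adjusted_r2 == pytest.approx(adj_r2, abs=1e-8)
        assert fit.p_value == pytest.approx(p, abs=1e-8)

    def test_matches_explicit_gls_matrix_algebra(self):
        # independent oracle: textbook GLS solution on the 4-taxon tree
        rng = np.random.default_rng(1)
        x = rng.normal(size=4)
        y = rng.normal(size=4)
        fit = pgls_fit(x, y, ULTRA4, list("ABCD"))
        V = phylo_covariance(ULTRA4, list("ABCD"))
        X = np.column_stack([np.ones(4), x])
        Vinv = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-8)
        assert fit.slope == pytest.approx(beta[1], rel=1e-8)

    def test_branch_length_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=4)
        y = rng.normal(size=4)
        scaled = tree_from("((A:10,B:10):20,(C:20,D:20):10);")
        f1 = pgls_fit(x, y, ULTRA4, list("ABCD"))
        f2 = pgls_fit(x, y, scaled, list("ABCD"))
        assert f1.slope == pytest.approx(f2.slope, rel=1e-8)
        assert f1.adjusted_r2 == pytest.approx(f2.adjusted_r2, rel=1e-6)
        assert f1.p_value == pytest.approx(f2.p_value, rel=1e-6)

    def test_brownian_null_type_one_error_calibrated(self):
        """Slope p-values are uniform when y is Brownian and x independent."""
        from gmrate.simulate import random_ultrametric_tree

        rng = np.random.default_rng(12)
        labels = [f"s{i}" for i in range(15)]
        tree = random_ultrametric_tree(labels, 100.0, rng)
        V = phylo_covariance(tree, labels)
        L = np.linalg.cholesky(V + 1e-9 * np.eye(len(labels)))
        pvals = []
        for _ in range(300):
            y = L @ rng.standard_normal(len(labels))
            x = rng.standard_normal(len(labels))
            pvals.append(pgls_fit(x, y, tree, labels).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_lambda_zero_is_ols(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=4)
        y = rng.normal(size=4)
        fit = pgls_fit(x, y, ULTRA4, list("ABCD"), lam=0.0)
        slope, _, _ = ols_adjusted_r2(x, y)
        # lambda = 0 zeroes shared history but keeps unequal tip variances;
        # on an ultrametric tree tip variances are equal, so OLS results
        assert fit.slope == pytest.approx(slope, abs=1e-8)

    def test_refuses_too_few_species(self):
        with pytest.raises(ValueError):
            pgls_fit([1, 2, 3], [1, 2, 3], tree_from("(A:1,B:1,C:1);"), list("ABC"))

    def test_estimator_interface(self):
        model = PGLS(lam=0.5)
        assert model.get_params()["lam"] == 0.5
        rng = np.random.default_rng(4)
        model.fit(rng.normal(size=5), rng.normal(size=5), tree=STAR5, taxa=list("ABCDE"))
        assert hasattr(model, "slope_") and hasattr(model, "adjusted_r2_")


class TestOLS:
    def test_perfect_line(self):
        x = np.arange(10.0)
        slope, adj_r2, p = ols_adjusted_r2(x, 3 * x + 1)
        assert slope == pytest.approx(3.0)
        assert adj_r2 == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        _, adj_r2, _ = ols_adjusted_r2(x, y)
        assert abs(adj_r2) < 0.02

    def test_refusals(self):
        with pytest.raises(ValueError):
            ols_adjusted_r2([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            ols_adjusted_r2([1, 2], [1, 2])


class TestNe:
    def test_constant_trajectory(self):
        traj = NeTrajectory([(0, 1e6, 1e4)])
        for w in [(0, 1e6), (30_000, 1_000_000), (100, 200)]:
            assert harmonic_mean_ne(traj, *w) == pytest.approx(1e4)

    def test_two_equal_segments(self):
        traj = NeTrajectory([(0, 5e5, 1e4), (5e5, 1e6, 2e4)])
        hm = harmonic_mean_ne(traj, 0, 1e6)
        assert hm == pytest.approx(2 / (1 / 1e4 + 1 / 2e4))
        assert hm == pytest.approx(13_333.3, abs=0.5)

    def test_partial_overlap_clipping(self):
        traj = NeTrajectory([(0, 4e5, 1e4), (4e5, 1e6, 2e4)])
        # window 3e5..5e5: 1e5 years at 1e4, 1e5 years at 2e4
        hm = harmonic_mean_ne(traj, 3e5, 5e5)
        assert hm == pytest.approx(2 / (1 / 1e4 + 1 / 2e4))

    def test_harmonic_below_arithmetic(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            bounds = np.sort(rng.uniform(0, 1e6, 6))
            segs = [
                (float(bounds[i]), float(bounds[i + 1]), float(rng.uniform(1e3, 1e5)))
                for i in range(5)
            ]
            traj = NeTrajectory(segs)
            lo, hi = traj.support
            hm = harmonic_mean_ne(traj, lo, hi)
            total = hi - lo
            am = sum((e - s) * n for s, e, n in segs) / total
            assert hm <= am + 1e-9

    def test_matches_fine_grid_integration(self):
        rng = np.random.default_rng(7)
        bounds = np.sort(rng.uniform(0, 1e6, 9))
        segs = [
            (float(bounds[i]), float(bounds[i + 1]), float(rng.uniform(1e3, 1e5)))
            for i in range(8)
        ]
        traj = NeTrajectory(segs)
        lo, hi = traj.support
        w0, w1 = max(50_000.0, lo), min(900_000.0, hi)
        grid = np.linspace(w0, w1, 2_000_001)
        mid = 0.5 * (grid[:-1] + grid[1:])
        ne = np.full_like(mid, np.nan)
        for s, e, n in segs:
            ne[(mid >= s) & (mid < e)] = n
        dt = np.diff(grid)
        ok = ~np.isnan(ne)
        oracle = dt[ok].sum() / (dt[ok] / ne[ok]).sum()
        assert harmonic_mean_ne(traj, w0, w1) == pytest.approx(oracle, rel=1e-6)

    def test_window_outside_support_refused(self):
        traj = NeTrajectory([(0, 1e5, 1e4)])
        with pytest.raises(ValueError):
            harmonic_mean_ne(traj, 2e5, 3e5)

    def test_invalid_trajectories_refused(self):
        with pytest.raises(ValueError):
            NeTrajectory([(0, 1e5, 1e4), (5e4, 2e5, 1e4)])  # overlap
        with pytest.raises(ValueError):
            NeTrajectory([(0, 1e5, -5.0)])

    def test_ne_from_pi(self):
        assert ne_from_pi(0.001, 2.5e-8) == pytest.approx(10_000.0)
        assert ne_from_pi(0.0, 1e-8) == 0.0
        assert ne_from_pi(0.001, 2e-8) == pytest.approx(2 * ne_from_pi(0.001, 4e-8))
        with pytest.raises(ValueError):
            ne_from_pi(0.001, 0.0)
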