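import numpy as np
import pytest

from fishdiv import (
    PGLSConfig,
    bootstrap_ci,
    brownian_covariance,
    cell_means_design,
    compare_groups,
    gls_fit,
    significant_nonzero,
    slope_design,
)
from fishdiv.pgls import DesignMatrix, SingularDesignError

from conftest import make_record


def brute_force_gls(X, y, V):
    """Independent normal-equations oracle via explicit inversion."""
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    sigma2 = r @ Vi @ r / (X.shape[0] - X.shape[1])
    return beta, sigma2


class TestGLSFit:
    def test_identity_covariance_reduces_to_group_means(self):
        groups = np.array(["a", "a", "a", "b", "b"], dtype=object)
        y = np.array([1.0, 2.0, 3.0, 10.0, 14.0])
        fit = gls_fit(cell_means_design(groups), y, np.eye(5), nugget=0.0)
        assert fit.coef("a") == pytest.approx(2.0)
        assert fit.coef("b") == pytest.approx(12.0)

    def test_constant_response(self):
        groups = np.array(["a", "a", "b", "b"], dtype=object)
        y = np.full(4, 3.7)
        fit = gls_fit(cell_means_design(groups), y, np.eye(4), nugget=0.0)
        assert fit.coef("a") == pytest.approx(3.7)
        assert fit.coef("b") == pytest.approx(3.7)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_four_species_hand_oracle(self):
        """Congener pair at covariance 0.8, all other pairs unrelated,
        y=(1,2,3,4), two-level factor: explicit inversion gives
        beta=(1.5, 3.5), sigma2=1.5."""
        recs = [
            make_record("Gadus morhua"),
            make_record("Gadus macrocephalus"),
            make_record("Salmo salar", cls="C3", genus="Salmo",
                        family="Salmonidae", order="Salmoniformes",
                        habitat="freshwater"),
            make_record("Perca fluviatilis", cls="C4", genus="Perca",
                        family="Percidae", order="Perciformes",
                        habitat="freshwater"),
        ]
        V = brownian_covariance(recs)
        expected_V = np.eye(4)
        expected_V[0, 1] = expected_V[1, 0] = 0.8
        np.testing.assert_allclose(V.matrix, expected_V)
        habitats = np.array([r.habitat for r in recs], dtype=object)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fit = gls_fit(cell_means_design(habitats), y, V, nugget=0.0)
        assert fit.coef("marine") == pytest.approx(1.5, abs=1e-10)
        assert fit.coef("freshwater") == pytest.approx(3.5, abs=1e-10)
        assert fit.sigma2 == pytest.approx(1.5, abs=1e-10)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            X = rng.standard_normal((n, 2))
            y = rng.standard_normal(n)
            A = rng.standard_normal((n, n))
            V = A @ A.T + n * np.eye(n)
            d = DesignMatrix(X=X, labels=("b0", "b1"), factor=False)
            fit = gls_fit(d, y, V, nugget=0.0)
            beta, sigma2 = brute_force_gls(X, y, V)
            np.testing.assert_allclose(
                [fit.coef("b0"), fit.coef("b1")], beta, atol=1e-10
            )
            assert fit.sigma2 == pytest.approx(sigma2, abs=1e-10)

    def test_whitening_equivalence(self, rng):
        n = 12
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        A = rng.standard_normal((n, n))
        V = A @ A.T + n * np.eye(n)
        d = DesignMatrix(X=X, labels=("intercept", "slope"), factor=False)
        fit = gls_fit(d, y, V, nugget=0.0)
        L = np.linalg.cholesky(V)
        beta_w, *_ = np.linalg.lstsq(
            np.linalg.solve(L, X), np.linalg.solve(L, y), rcond=None
        )
        np.testing.assert_allclose(
            [fit.coef("intercept"), fit.coef("slope")], beta_w, atol=1e-12
        )

    def test_agrees_with_statsmodels_gls(self, rng):
        """Independent library cross-check of the GLS solution."""
        import statsmodels.api as sm

        n = 15
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        A = rng.standard_normal((n, n))
        V = A @ A.T + n * np.eye(n)
        d = DesignMatrix(X=X, labels=("intercept", "slope"), factor=False)
        fit = gls_fit(d, y, V, nugget=0.0)
        ref = sm.GLS(y, X, sigma=V).fit()
        np.testing.assert_allclose(
            [fit.coef("intercept"), fit.coef("slope")], ref.params, atol=1e-8
        )

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        d = DesignMatrix(X=X, labels=("a", "b"), factor=False)
        with pytest.raises(SingularDesignError):
            gls_fit(d, np.arange(4.0), np.eye(4))


class TestBootstrap:
    def test_iid_case_matches_classical_bootstrap(self, rng):
        """With V=I and one group, the species bootstrap is the classical
        i.i.d. percentile bootstrap of the sample mean."""
        n, B = 40, 2000
        y = rng.normal(5.0, 2.0, size=n)
        groups = np.array(["g"] * n, dtype=object)
        recs = [make_record(f"S{i} sp", genus=f"G{i}", family=f"F{i}",
                            order=f"O{i}", cls=f"C{i}") for i in range(n)]
        V = brownian_covariance(recs)  # no shared ranks -> identity
        assert np.allclose(V.matrix, np.eye(n))
        cfg = PGLSConfig(bootstrap_iterations=B, nugget=0.0)
        ci = bootstrap_ci(cell_means_design(groups), y, V, cfg, seed=9)

        oracle_rng = np.random.default_rng(909)
        means = np.array([
            y[oracle_rng.integers(0, n, n)].mean() for _ in range(20_000)
        ])
        lo, hi = np.percentile(means, [2.5, 97.5])
        width_se = y.std(ddof=1) / np.sqrt(n)
        assert ci.lower["g"] == pytest.approx(lo, abs=0.3 * width_se)
        assert ci.upper["g"] == pytest.approx(hi, abs=0.3 * width_se)

    def test_same_seed_identical(self, four_species):
        V = brownian_covariance(four_species)
        groups = np.array([r.habitat for r in four_species], dtype=object)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        cfg = PGLSConfig(bootstrap_iterations=150)
        a = bootstrap_ci(cell_means_design(groups), y, V, cfg, seed=5)
        b = bootstrap_ci(cell_means_design(groups), y, V, cfg, seed=5)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_iteration_count_affects_jitter_not_location(self, rng):
        n = 30
        y = rng.normal(0.0, 1.0, size=n)
        groups = np.array(["g"] * n, dtype=object)
        recs = [make_record(f"S{i} sp", genus=f"G{i}", family=f"F{i}",
                            order=f"O{i}", cls=f"C{i}") for i in range(n)]
        V = brownian_covariance(recs)
        d = cell_means_design(groups)
        small = bootstrap_ci(d, y, V, PGLSConfig(bootstrap_iterations=100), 1)
        large = bootstrap_ci(d, y, V, PGLSConfig(bootstrap_iterations=4000), 1)
        mid_small = (small.lower["g"] + small.upper["g"]) / 2
        mid_large = (large.lower["g"] + large.upper["g"]) / 2
        assert mid_small == pytest.approx(mid_large, abs=3 * y.std() / np.sqrt(n))

    def test_pgls_intervals_wider_than_ols_on_clustered_data(self, small_world):
        """Ignoring phylogenetic covariance is anti-conservative: on strongly
        clustered traits the identity-covariance bootstrap gives narrower
        intervals than the Brownian-covariance bootstrap on average."""
        recs = small_world.records
        n = len(recs)
        V = brownian_covariance(recs)
        gen = np.random.default_rng(42)
        L = np.linalg.cholesky(V.matrix + 1e-10 * np.eye(n))
        y = 5.0 + 3.0 * (L @ gen.standard_normal(n))
        groups = np.array(["g"] * n, dtype=object)
        d = cell_means_design(groups)
        cfg = PGLSConfig(bootstrap_iterations=400)
        pgls_ci = bootstrap_ci(d, y, V, cfg, seed=3)
        from fishdiv.taxonomy import BrownianCovariance

        iid = BrownianCovariance(np.eye(n), V.species_order)
        ols_ci = bootstrap_ci(d, y, iid, cfg, seed=3)
        pgls_width = pgls_ci.upper["g"] - pgls_ci.lower["g"]
        ols_width = ols_ci.upper["g"] - ols_ci.lower["g"]
        assert pgls_width > ols_width


class TestDecisions:
    @pytest.mark.parametrize(
        "interval,expected",
        [
            ((-1.70, -0.43), True),
            ((-0.006, 0.001), False),
            ((0.0, 1.0), False),   # closed-interval convention
        ],
    )
    def test_nonzero_coefficient_call(self, interval, expected):
        assert significant_nonzero(interval) is expected

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0.67, 0.70), (0.59, 0.62), True),
            ((12.80, 14.92), (10.98, 13.06), False),
            ((1.0, 2.0), (2.0, 3.0), False),  # touching endpoints overlap
        ],
    )
    def test_group_difference_call(self, a, b, expected):
        assert compare_groups(a, b) is expected
        assert compare_groups(b, a) is expected
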