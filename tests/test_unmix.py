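import itertools

import numpy as np
import pytest

from irmix import (
    BasisSet,
    Spectrum,
    WavenumberGrid,
    fit_ls,
    fit_nnls,
    pairwise_interpolation,
    solve,
)
from irmix.exceptions import IncompatibleGridsError, InvalidBasisError, InvalidParameterError


def make_basis(columns, grid=None):
    """Basis from non-negative column vectors, unit-area normalized."""
    cols = [np.asarray(c, dtype=float) for c in columns]
    if grid is None:
        grid = WavenumberGrid(0.0, 1.0, len(cols[0]))
    spectra = [
        Spectrum(grid, c / (c.sum() * grid.step), normalized=True) for c in cols
    ]
    return BasisSet([f"c{i}" for i in range(len(cols))], spectra)


def mixture_of(basis, weights):
    y = basis.matrix.T @ np.asarray(weights, dtype=float)
    return Spectrum(basis.grid, y)


def nnls_oracle(a, b):
    """Exhaustive active-set enumeration: solve unconstrained LS on every
    support, keep feasible (non-negative) solutions, return the best."""
    n = a.shape[1]
    best_c = np.zeros(n)
    best_sse = float(b @ b)
    for r in range(1, n + 1):
        for support in itertools.combinations(range(n), r):
            cs, *_ = np.linalg.lstsq(a[:, support], b, rcond=None)
            if (cs >= -1e-12).all():
                c = np.zeros(n)
                c[list(support)] = np.maximum(cs, 0.0)
                res = b - a @ c
                sse = float(res @ res)
                if sse < best_sse - 1e-14:
                    best_c, best_sse = c, sse
    return best_c, best_sse


class TestLs:
    def test_identity_member_of_orthogonal_basis(self):
        basis = make_basis([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 1]])
        y = Spectrum(basis.grid, basis.matrix[1])
        res = fit_ls(y, basis)
        np.testing.assert_allclose(
            list(res.coefficients.values()), [0.0, 1.0, 0.0], atol=1e-10
        )
        assert res.residual_sse == pytest.approx(0.0, abs=1e-18)

    def test_exact_two_component_recovery_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        basis = make_basis(rng.random((2, 12)))
        y = mixture_of(basis, [0.3, 0.7])
        res = fit_ls(y, basis)
        # independent oracle: solve the normal equations directly
        a = basis.matrix.T
        expected = np.linalg.solve(a.T @ a, a.T @ y.intensities)
        np.testing.assert_allclose(
            list(res.coefficients.values()), expected, atol=1e-8
        )
        np.testing.assert_allclose(list(res.coefficients.values()), [0.3, 0.7], atol=1e-8)

    def test_ridge_shrinks_coefficients_monotonically(self):
        rng = np.random.default_rng(6)
        basis = make_basis(rng.random((3, 10)))
        y = mixture_of(basis, [0.2, 0.5, 0.3])
        norms = [
            np.linalg.norm(fit_ls(y, basis, lam).coefficient_vector())
            for lam in (0.0, 1e-3, 1e-1, 10.0, 1e4)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3

    def test_grid_mismatch_rejected(self):
        basis = make_basis([[1, 0], [0, 1]])
        other = Spectrum(WavenumberGrid(0.0, 2.0, 2), np.array([1.0, 0.0]))
        with pytest.raises(IncompatibleGridsError):
            fit_ls(other, basis)


class TestNnls:
    def test_exact_convex_combination_recovered(self):
        rng = np.random.default_rng(7)
        basis = make_basis(rng.random((4, 16)))
        y = mixture_of(basis, [0.5, 0.5, 0.0, 0.0])
        res = fit_nnls(y, basis)
        np.testing.assert_allclose(
            list(res.coefficients.values()), [0.5, 0.5, 0.0, 0.0], atol=1e-8
        )
        assert res.residual_sse == pytest.approx(0.0, abs=1e-16)
        assert res.converged

    def test_unhelpful_anticorrelated_entry_pinned_at_zero(self):
        # 2-basis toy where unconstrained LS goes negative on c1:
        # overlapping bands [1,1,0] and [0,1,1] with a target on the first
        # channel only pull c1 below zero in the unconstrained solve
        basis = make_basis([[1, 1, 0], [0, 1, 1]])
        y = Spectrum(basis.grid, np.array([1.0, 0.0, 0.0]))
        ls = fit_ls(y, basis)
        assert list(ls.coefficients.values())[1] < 0
        res = fit_nnls(y, basis)
        assert list(res.coefficients.values())[1] == 0.0

    def test_zero_target_gives_zero_coefficients(self):
        basis = make_basis([[1, 2, 1], [2, 1, 0]])
        y = Spectrum(basis.grid, np.zeros(3))
        res = fit_nnls(y, basis)
        np.testing.assert_allclose(list(res.coefficients.values()), 0.0, atol=1e-12)

    def test_matches_ls_when_ls_already_nonnegative(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            basis = make_basis(rng.random((3, 12)))
            y = mixture_of(basis, rng.random(3) + 0.1)
            ls = fit_ls(y, basis)
            if (ls.coefficient_vector() >= 0).all():
                nn = fit_nnls(y, basis)
                np.testing.assert_allclose(
                    nn.coefficient_vector(), ls.coefficient_vector(), atol=1e-8
                )

    def test_residual_nonincreasing_in_nested_bases(self):
        rng = np.random.default_rng(9)
        cols = rng.random((5, 20))
        y = None
        prev = np.inf
        for n in range(1, 6):
            basis = make_basis(cols[:n])
            if y is None:
                y = Spectrum(basis.grid, rng.random(20))
            sse = fit_nnls(y, basis).residual_sse
            assert sse <= prev + 1e-12
            prev = sse

    def test_ridge_at_zero_equals_plain_and_path_is_continuous(self):
        rng = np.random.default_rng(10)
        basis = make_basis(rng.random((3, 10)))
        y = mixture_of(basis, [0.4, 0.1, 0.5])
        c0 = fit_nnls(y, basis, lam=0.0).coefficient_vector()
        np.testing.assert_allclose(
            fit_nnls(y, basis).coefficient_vector(), c0, atol=1e-12
        )
        lams = np.geomspace(1e-8, 1e-2, 61)
        path = np.array([fit_nnls(y, basis, lam=l).coefficient_vector() for l in lams])
        steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
        assert steps.max() < 0.02  # no jumps along a fine lambda path
        np.testing.assert_allclose(path[0], c0, atol=1e-4)

    def test_iteration_limit_surfaces_as_unconverged(self):
        rng = np.random.default_rng(11)
        basis = make_basis(rng.random((4, 16)))
        y = mixture_of(basis, [0.3, 0.3, 0.2, 0.2])
        res = fit_nnls(y, basis, max_iter=1)
        assert not res.converged
        np.testing.assert_allclose(res.coefficient_vector(), 0.0)

    def test_matches_active_set_enumeration_small_instances(self):
        """NNLS equals exhaustive active-set enumeration on random small
        problems (<= 3 basis entries, <= 8 grid points)."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            n_basis = int(rng.integers(1, 4))
            n_pts = int(rng.integers(max(2, n_basis), 9))
            basis = make_basis(rng.random((n_basis, n_pts)) + 1e-3)
            y = Spectrum(basis.grid, rng.normal(0.2, 0.5, size=n_pts))
            res = fit_nnls(y, basis)
            oracle_c, oracle_sse = nnls_oracle(basis.matrix.T, y.intensities)
            np.testing.assert_allclose(res.coefficient_vector(), oracle_c, atol=1e-8)
            assert res.residual_sse == pytest.approx(oracle_sse, abs=1e-10)


class TestPairwiseInterpolation:
    def test_even_mixture_recovered(self):
        rng = np.random.default_rng(13)
        basis = make_basis(rng.random((4, 16)))
        y = mixture_of(basis, [0.5, 0.5, 0.0, 0.0])
        best = pairwise_interpolation(y, basis)
        assert set(best.pair) == {"c0", "c1"}
        assert best.alpha == pytest.approx(0.5, abs=1e-9)
        assert best.residual_sse == pytest.approx(0.0, abs=1e-16)

    def test_pure_component_at_endpoint(self):
        rng = np.random.default_rng(14)
        basis = make_basis(rng.random((4, 16)))
        y = Spectrum(basis.grid, basis.matrix[2])
        best = pairwise_interpolation(y, basis)
        assert "c2" in best.pair
        weight = best.alpha if best.pair[0] == "c2" else 1.0 - best.alpha
        assert weight == pytest.approx(1.0, abs=1e-9)

    def test_identical_pair_uses_half(self):
        col = np.array([1.0, 2.0, 3.0, 1.0])
        basis = make_basis([col, col])
        best = pairwise_interpolation(Spectrum(basis.grid, col), basis)
        assert best.alpha == 0.5

    def test_single_entry_basis_rejected(self):
        basis = make_basis([[1, 2, 3]])
        with pytest.raises(InvalidBasisError):
            pairwise_interpolation(Spectrum(basis.grid, np.ones(3)), basis)

    def test_matches_dense_alpha_grid_search(self):
        """Closed-form alpha matches a brute-force grid over all pairs."""
        rng = np.random.default_rng(15)
        alphas = np.arange(0.0, 1.0 + 1e-9, 1e-3)
        for _ in range(10):
            basis = make_basis(rng.random((5, 12)))
            y = Spectrum(basis.grid, rng.random(12) * 0.3)
            best = pairwise_interpolation(y, basis)
            grid_best = np.inf
            x = basis.matrix
            for i in range(5):
                for j in range(i + 1, 5):
                    recon = np.outer(alphas, x[i]) + np.outer(1 - alphas, x[j])
                    sse = ((y.intensities - recon) ** 2).sum(axis=1).min()
                    grid_best = min(grid_best, sse)
            assert best.residual_sse == pytest.approx(grid_best, abs=1e-6)


class TestSolveDispatch:
    def test_named_algorithms(self):
        rng = np.random.default_rng(16)
        basis = make_basis(rng.random((3, 10)))
        y = mixture_of(basis, [0.6, 0.4, 0.0])
        for algo in ("ls", "nnls", "pairwise"):
            res = solve(y, basis, algorithm=algo)
            ranked = sorted(res.coefficients, key=res.coefficients.get, reverse=True)
            assert set(ranked[:2]) == {"c0", "c1"}

    def test_ridge_names_require_positive_lambda(self):
        basis = make_basis([[1, 0], [0, 1]])
        y = Spectrum(basis.grid, np.ones(2))
        with pytest.raises(InvalidParameterError):
            solve(y, basis, algorithm="nnls-ridge", lam=0.0)
        with pytest.raises(InvalidParameterError):
            solve(y, basis, algorithm="unknown")
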