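"""Linear deconvolution of mixture spectra against a pure-component basis.

Four algorithms are provided, all minimizing the same squared-error
objective ‖y − Xᵀc‖² + λ‖c‖² over coefficients c of the basis spectra X:

* :func:`fit_ls` — ordinary (optionally ridge-regularized) least squares;
  coefficients may be negative.
* :func:`fit_nnls` — the same objective with coefficients constrained
  non-negative (NNLS), the method of record for mixture identification.
  Ridge regularization is realized by augmenting the design with a √λ·I
  block; solver non-convergence is surfaced as a flagged result, never an
  exception, because the benchmarking layer counts such mixtures as
  incorrect predictions.
* :func:`pairwise_interpolation` — the brute-force baseline for binary
  mixtures: every unordered pair of basis spectra is fit as a convex
  interpolation α·xᵢ + (1−α)·xⱼ and the pair with the smallest residual
  wins.

Each mixture is solved independently; the matrix formulation over a set of
mixtures decouples row by row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .exceptions import IncompatibleGridsError, InvalidBasisError, InvalidParameterError
from .library import BasisSet
from .spectra import Spectrum

__all__ = ["UnmixResult", "PairInterpolation", "fit_ls", "fit_nnls", "pairwise_interpolation", "solve"]


@dataclass(frozen=True)
class UnmixResult:
    """Coefficients of one mixture against one basis.

    ``coefficients`` preserves basis order (dict insertion order), which
    downstream ranking uses for deterministic tie-breaking.
    ``residual_sse`` is the unregularized sum of squared residuals
    Σ(y − Σcᵢxᵢ)² over the grid.
    """

    coefficients: dict[str, float]
    residual_sse: float
    converged: bool
    regularization: float = 0.0

    def coefficient_vector(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()))


@dataclass(frozen=True)
class PairInterpolation:
    """Best convex two-component interpolation of a mixture spectrum."""

    pair: tuple[str, str]
    alpha: float
    residual_sse: float

    def as_result(self) -> UnmixResult:
        """View as an :class:`UnmixResult` with weights (α, 1−α)."""
        i, j = self.pair
        return UnmixResult(
            coefficients={i: self.alpha, j: 1.0 - self.alpha},
            residual_sse=self.residual_sse,
            converged=True,
        )


def _check(y: Spectrum, basis: BasisSet, lam: float) -> None:
    if y.grid != basis.grid:
        raise IncompatibleGridsError("mixture spectrum and basis are on different grids")
    if lam < 0:
        raise InvalidParameterError(f"regularization must be >= 0, got {lam}")


def _augment(basis: BasisSet, y: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (columns = basis spectra), ridge-augmented when λ > 0."""
    a = basis.matrix.T
    if lam > 0:
        a = np.vstack([a, np.sqrt(lam) * np.eye(len(basis))])
        y = np.concatenate([y, np.zeros(len(basis))])
    return a, y


def _residual_sse(y: np.ndarray, basis: BasisSet, c: np.ndarray) -> float:
    r = y - basis.matrix.T @ c
    return float(r @ r)


def fit_ls(y: Spectrum, basis: BasisSet, lam: float = 0.0) -> UnmixResult:
    """Unconstrained (ridge) least-squares coefficients; may be negative."""
    _check(y, basis, lam)
    a, target = _augment(basis, y.intensities, lam)
    c, *_ = np.linalg.lstsq(a, target, rcond=None)
    return UnmixResult(
        coefficients=dict(zip(basis.ids, c.tolist())),
        residual_sse=_residual_sse(y.intensities, basis, c),
        converged=True,
        regularization=lam,
    )


def default_max_iter(n_basis: int) -> int:
    """Conventional active-set iteration bound: 3 × basis size."""
    return 3 * n_basis


def fit_nnls(
    y: Spectrum,
    basis: BasisSet,
    lam: float = 0.0,
    max_iter: int | None = None,
) -> UnmixResult:
    """Non-negative least-squares coefficients.

    If the active-set solver hits ``max_iter`` (default 3 × basis size,
    reachable under strong basis collinearity) the result is returned with
    ``converged=False`` and all-zero coefficients rather than raising.
    """
    _check(y, basis, lam)
    if max_iter is None:
        max_iter = default_max_iter(len(basis))
    a, target = _augment(basis, y.intensities, lam)
    try:
        c, _ = _scipy_nnls(a, target, maxiter=max_iter)
        converged = True
    except RuntimeError:
        c = np.zeros(len(basis))
        converged = False
    return UnmixResult(
        coefficients=dict(zip(basis.ids, c.tolist())),
        residual_sse=_residual_sse(y.intensities, basis, c),
        converged=converged,
        regularization=lam,
    )


def pairwise_interpolation(y: Spectrum, basis: BasisSet) -> PairInterpolation:
    """Brute-force convex interpolation over all unordered basis pairs.

    For each pair (i, j) the optimal convex weight is the clamped projection
    α* = clamp₀¹(⟨y − xⱼ, xᵢ − xⱼ⟩ / ‖xᵢ − xⱼ‖²); the pair with the
    smallest residual wins, ties broken by library order.  Identical pair
    spectra get α = 0.5 by convention.
    """
    if y.grid != basis.grid:
        raise IncompatibleGridsError("mixture spectrum and basis are on different grids")
    if len(basis) < 2:
        raise InvalidBasisError("pairwise interpolation needs at least 2 basis entries")
    yv = y.intensities
    x = basis.matrix
    best: PairInterpolation | None = None
    for i in range(len(basis)):
        for j in range(i + 1, len(basis)):
            d = x[i] - x[j]
            denom = float(d @ d)
            if denom == 0.0:
                alpha = 0.5
            else:
                alpha = float(np.clip((yv - x[j]) @ d / denom, 0.0, 1.0))
            r = yv - (alpha * x[i] + (1.0 - alpha) * x[j])
            sse = float(r @ r)
            # strict < keeps the earliest pair on ties (library order)
            if best is None or sse < best.residual_sse:
                best = PairInterpolation((basis.ids[i], basis.ids[j]), alpha, sse)
    assert best is not None
    return best


def solve(
    y: Spectrum,
    basis: BasisSet,
    algorithm: str = "nnls",
    lam: float = 0.0,
    max_iter: int | None = None,
) -> UnmixResult:
    """Dispatch to a deconvolution algorithm by name.

    ``algorithm`` is one of ``"ls"``, ``"nnls"``, ``"ls-ridge"``,
    ``"nnls-ridge"`` or ``"pairwise"``.  The ridge names are the same code
    paths with λ > 0 required.
    """
    if algorithm in ("ls", "ls-ridge"):
        if algorithm == "ls-ridge" and lam <= 0:
            raise InvalidParameterError("ls-ridge requires lambda > 0")
        return fit_ls(y, basis, lam)
    if algorithm in ("nnls", "nnls-ridge"):
        if algorithm == "nnls-ridge" and lam <= 0:
            raise InvalidParameterError("nnls-ridge requires lambda > 0")
        return fit_nnls(y, basis, lam, max_iter)
    if algorithm == "pairwise":
        return pairwise_interpolation(y, basis).as_result()
    raise InvalidParameterError(f"unknown algorithm {algorithm!r}")
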