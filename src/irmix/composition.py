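"""Cumulative reconstruction analysis and component-count inference.

Given the coefficients of a mixture deconvolution, pure-component spectra
are added back one at a time in descending coefficient order, each scaled
by its coefficient, starting from a zero-intensity spectrum.  After each
addition three metrics compare the partial reconstruction ŷ to the target
mixture y:

* fractional spectral variance R² = 1 − Σ(y − ŷ)² / Σ(y − ȳ)², with ȳ the
  mean intensity of y — the fraction of the mixture spectrum's variance the
  partial reconstruction explains;
* mean squared error;
* signed average cumulative-intensity difference.

Once every real component has been added, R² plateaus: further components
contribute almost nothing.  :func:`infer_component_count` turns that
plateau into an estimate of the (unknown) number of components.  A
complementary leave-one-out analysis quantifies each component's
importance by the degradation in fit when it is removed from the basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError
from .library import BasisSet
from .spectra import Spectrum, raw_cdf
from .unmix import UnmixResult, solve

__all__ = [
    "TraceStep",
    "ReconstructionTrace",
    "reconstruction_trace",
    "infer_component_count",
    "leave_one_out_importance",
]


@dataclass(frozen=True)
class TraceStep:
    """State of the cumulative reconstruction after adding one component."""

    component_id: str
    coefficient: float
    r_squared: float
    mse: float
    avg_cdf_diff: float


@dataclass(frozen=True)
class ReconstructionTrace:
    """Per-step metrics of a cumulative reconstruction.

    ``baseline_r_squared`` is R² of the empty (all-zero) reconstruction,
    1 − Σy²/Σ(y−ȳ)², a fixed property of the target spectrum.
    """

    steps: tuple[TraceStep, ...]
    baseline_r_squared: float

    def __len__(self) -> int:
        return len(self.steps)

    def r_squared_path(self) -> np.ndarray:
        return np.array([s.r_squared for s in self.steps])

    def increments(self) -> np.ndarray:
        """Stepwise R² gains; the first entry is relative to the baseline."""
        path = np.concatenate([[self.baseline_r_squared], self.r_squared_path()])
        return np.diff(path)


def _metrics(y: Spectrum, yhat: np.ndarray, ss_tot: float) -> tuple[float, float, float]:
    r = y.intensities - yhat
    ss_res = float(r @ r)
    r2 = 1.0 - ss_res / ss_tot
    mse = ss_res / y.grid.n_points
    cdf_gap = float(
        np.mean(raw_cdf(y) - np.cumsum(yhat) * y.grid.step)
    )
    return r2, mse, cdf_gap


def reconstruction_trace(
    y: Spectrum,
    result: UnmixResult,
    basis: BasisSet,
    max_steps: int | None = None,
) -> ReconstructionTrace:
    """Cumulative coefficient-weighted reconstruction of ``y``.

    Components with nonzero coefficients are added in descending
    |coefficient| order (ties by basis order); the trace ends early when the
    nonzero coefficients run out or after ``max_steps`` additions.
    """
    if y.grid != basis.grid:
        raise InvalidInputError("target spectrum and basis are on different grids")
    centered = y.intensities - y.intensities.mean()
    ss_tot = float(centered @ centered)
    if ss_tot <= 0:
        raise InvalidInputError("target spectrum has zero variance")
    items = list(result.coefficients.items())
    order = sorted(
        (i for i in range(len(items)) if items[i][1] != 0.0),
        key=lambda i: (-abs(items[i][1]), i),
    )
    if max_steps is not None:
        order = order[:max_steps]
    baseline_r2, _, _ = _metrics(y, np.zeros(y.grid.n_points), ss_tot)
    yhat = np.zeros(y.grid.n_points)
    steps: list[TraceStep] = []
    for i in order:
        cid, coef = items[i]
        yhat = yhat + coef * basis.matrix[basis.index_of(cid)]
        r2, mse, cdf_gap = _metrics(y, yhat, ss_tot)
        steps.append(TraceStep(cid, coef, r2, mse, cdf_gap))
    return ReconstructionTrace(tuple(steps), baseline_r2)


def infer_component_count(trace: ReconstructionTrace, increment_threshold: float = 0.01) -> int:
    """Number of components suggested by the R² plateau.

    Returns the smallest n whose *next* step improves R² by less than
    ``increment_threshold``; if no step falls below the threshold, the full
    trace length is returned.  A threshold of 0 therefore always returns
    the trace length (increments are non-negative for non-negative
    coefficients and basis spectra).
    """
    if len(trace) == 0:
        raise InvalidInputError("empty reconstruction trace")
    inc = trace.increments()
    for n in range(1, len(trace)):
        if inc[n] < increment_threshold:
            return n
    return len(trace)


def leave_one_out_importance(
    y: Spectrum,
    basis: BasisSet,
    component_id: str,
    algorithm: str = "nnls",
    lam: float = 0.0,
) -> tuple[float, float, float]:
    """Fit degradation when one component is removed from the basis.

    Returns ``(ΔR², ΔMSE, ΔavgCDF)`` where ΔR² = R²(full) − R²(reduced) and
    the MSE/CDF deltas are the corresponding *increases* on removal
    (reduced − full, with the CDF gap compared in absolute value).  All
    deltas are ≈ 0 for an inactive or spectrally duplicated component;
    strictly positive ΔR² marks an important one.
    """
    centered = y.intensities - y.intensities.mean()
    ss_tot = float(centered @ centered)
    if ss_tot <= 0:
        raise InvalidInputError("target spectrum has zero variance")

    def fitted(b: BasisSet) -> np.ndarray:
        res = solve(y, b, algorithm=algorithm, lam=lam)
        return b.matrix.T @ res.coefficient_vector()

    reduced = basis.without(component_id)  # raises UnknownComponentError if absent
    r2_full, mse_full, cdf_full = _metrics(y, fitted(basis), ss_tot)
    r2_red, mse_red, cdf_red = _metrics(y, fitted(reduced), ss_tot)
    return (
        r2_full - r2_red,
        mse_red - mse_full,
        abs(cdf_red) - abs(cdf_full),
    )
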