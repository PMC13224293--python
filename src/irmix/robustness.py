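"""Peak-shift robustness studies and misidentification profiling.

Identification must tolerate the band shifts real spectra exhibit (solvent
effects, temperature, instrument calibration).  The perturbation model is a
rigid whole-spectrum translation of fixed magnitude and random sign applied
to each pure-component spectrum *before* mixing, while the identification
basis keeps the unperturbed spectra — emulating reference data that do not
quite match the measurement conditions.

Misidentification profiling explains failed identifications chemically:
each unmatched true component is paired with the spectrally closest false
positive (minimal MSE) and the pair is classified by formula relation
(isomer / single-atom substitution / one-carbon difference / other); a
mixture whose pairs span two or more of the named classes is labeled
"mixed".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError
from .formulas import CATEGORIES, MolecularFormula, classify_misidentification, parse_formula
from .identify import BenchmarkReport, MixtureRecord, evaluate_exact, rank_candidates
from .library import SpectralLibrary
from .spectra import Spectrum, spectral_mse
from .unmix import solve

__all__ = [
    "apply_random_shift",
    "shift_robustness_curve",
    "nearest_spectral_neighbors",
    "MisidRecord",
    "profile_misidentifications",
]


def apply_random_shift(
    spec: Spectrum,
    magnitude: float,
    rng: np.random.Generator,
    sign: int | None = None,
) -> Spectrum:
    """Rigid translation by ±magnitude cm⁻¹ (sign drawn from ``rng``).

    The shift is realized on-grid by rounding magnitude/step; vacated bins
    are zero-filled and the result is renormalized to unit area.  A
    ``sign`` of +1/−1 forces the direction (used in tests and curve
    construction replays).
    """
    if magnitude < 0:
        raise InvalidParameterError("shift magnitude must be >= 0")
    if magnitude > spec.grid.span / 2:
        raise InvalidParameterError(
            f"shift {magnitude} exceeds half the grid span {spec.grid.span / 2}"
        )
    bins = int(round(magnitude / spec.grid.step))
    if sign is None:
        sign = int(rng.choice([-1, 1]))
    bins *= sign
    if bins == 0:
        return spec
    x = np.zeros_like(spec.intensities)
    if bins > 0:
        x[bins:] = spec.intensities[:-bins]
    else:
        x[:bins] = spec.intensities[-bins:]
    area = x.sum() * spec.grid.step
    if area <= 0:
        raise InvalidParameterError("shift moved all intensity off the grid")
    return Spectrum(spec.grid, x / area, normalized=True)


def shift_robustness_curve(
    mixture_specs: list[tuple[tuple[str, ...], tuple[float, ...]]],
    library: SpectralLibrary,
    algorithm: str = "nnls",
    magnitudes: tuple[float, ...] = (0.0, 4.0, 8.0, 16.0, 32.0),
    seed: int = 0,
    lam: float = 0.0,
) -> dict[float, float]:
    """Exact top-k identification accuracy as a function of peak-shift magnitude.

    For each magnitude, every mixture is rebuilt as a fraction-weighted sum
    of *independently shifted* pure spectra, while the identification basis
    keeps the whole library unshifted.  k is each mixture's component count.
    Returns {magnitude: accuracy}; magnitude 0 reproduces the unperturbed
    benchmark exactly.
    """
    if any(m < 0 for m in magnitudes) or list(magnitudes) != sorted(magnitudes):
        raise InvalidParameterError("magnitudes must be non-negative and sorted")
    basis = library.to_basis()
    curve: dict[float, float] = {}
    children = np.random.SeedSequence(seed).spawn(len(magnitudes))
    for magnitude, child in zip(magnitudes, children):
        rng = np.random.default_rng(child)
        n_correct = 0
        for components, fractions in mixture_specs:
            x = np.zeros(library.grid.n_points)
            for cid, frac in zip(components, fractions):
                shifted = apply_random_shift(library[cid].spectrum, magnitude, rng)
                x += frac * shifted.intensities
            mixture = Spectrum(library.grid, x / (x.sum() * library.grid.step), normalized=True)
            pred = rank_candidates(solve(mixture, basis, algorithm=algorithm, lam=lam))
            if evaluate_exact(pred, components, len(components)):
                n_correct += 1
        curve[float(magnitude)] = n_correct / len(mixture_specs)
    return curve


def nearest_spectral_neighbors(
    query_id: str,
    library: SpectralLibrary,
    m: int = 3,
) -> list[tuple[str, float]]:
    """The m library spectra closest to the query by MSE, ascending.

    The query itself is excluded; ties keep library order.
    """
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    query = library[query_id].spectrum
    dists = [
        (e.id, spectral_mse(query, e.spectrum))
        for e in library
        if e.id != query_id
    ]
    order = sorted(range(len(dists)), key=lambda i: (dists[i][1], i))
    return [dists[i] for i in order[:m]]


@dataclass(frozen=True)
class MisidRecord:
    """One true-component / false-positive pair from a failed mixture."""

    mixture_id: str
    true_id: str
    predicted_id: str
    category: str
    spectral_mse: float


def profile_misidentifications(
    report: BenchmarkReport,
    library: SpectralLibrary,
) -> tuple[dict[str, float], list[MisidRecord]]:
    """Category percentages over failed mixtures, plus per-pair records.

    For each failure in the report, true components absent from the top-k
    prediction are paired with false-positive candidates by globally
    minimal spectral MSE; each pair is classified at the formula level.  A
    mixture is labeled "mixed" when its pairs span at least two of the
    isomer / substitution / carbon-difference classes, otherwise it takes
    its single named class or "other".  Percentages are over failed,
    converged mixtures and sum to 100 (empty when nothing failed).
    """
    formulas: dict[str, MolecularFormula] = {}

    def formula_of(cid: str) -> MolecularFormula:
        if cid not in formulas:
            text = library[cid].formula
            if text is None:
                raise InvalidParameterError(f"library entry {cid!r} has no formula")
            formulas[cid] = parse_formula(text)
        return formulas[cid]

    records: list[MisidRecord] = []
    labels: list[str] = []
    for fail in report.failures:
        if not fail.converged:
            continue
        predicted = set(fail.predicted_topk)
        unmatched = [c for c in fail.true_components if c not in predicted]
        false_pos = [c for c in fail.predicted_topk if c not in set(fail.true_components)]
        if not unmatched or not false_pos:
            continue
        # greedy pairing by globally minimal spectral MSE
        pairs: list[tuple[str, str, float]] = []
        candidates = [
            (spectral_mse(library[t].spectrum, library[f].spectrum), t, f)
            for t in unmatched
            for f in false_pos
        ]
        used_t: set[str] = set()
        used_f: set[str] = set()
        for d, t, f in sorted(candidates, key=lambda c: c[0]):
            if t in used_t or f in used_f:
                continue
            pairs.append((t, f, d))
            used_t.add(t)
            used_f.add(f)
        cats: set[str] = set()
        for t, f, d in pairs:
            cat = classify_misidentification(formula_of(t), formula_of(f))
            cats.add(cat)
            records.append(MisidRecord(fail.mixture_id, t, f, cat, d))
        named = cats & {"isomer", "substitution", "carbon_difference"}
        if len(named) >= 2:
            labels.append("mixed")
        elif named:
            labels.append(next(iter(named)))
        else:
            labels.append("other")
    profile = {
        cat: 100.0 * labels.count(cat) / len(labels) if labels else 0.0
        for cat in CATEGORIES
    }
    if not labels:
        profile = {}
    return profile, records
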