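"""Component identification from deconvolution coefficients, and benchmarks.

Coefficients from a deconvolution are ranked by descending absolute value;
a mixture is identified when its true components appear among the top-k
ranked candidates.  Two evaluation criteria are used:

* ``exact`` — all true components are within the top k;
* ``any``   — at least one true component is within the top k.

An unconverged fit is always counted as incorrect under both criteria.

Two benchmark protocols are implemented.  The *distractor* protocol builds
a basis from every true component plus an equal number of randomly drawn
spectra of molecules absent from all mixtures, repeated several times with
fresh draws.  The *basis sweep* protocol grows nested basis sets from the
minimal one (exactly the union of all mixtures' components) by adding
seeded-random library spectra, and records accuracy per basis size,
criterion and k.

The atom filter re-ranks candidates using knowledge of which elements the
mixture contains (as elemental analysis or mass spectrometry would
provide): the highest-joint-coefficient combination of k candidates whose
element sets union to the mixture's element set is promoted to the top.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidConfigurationError, InvalidInputError, MissingMetadataError
from .formulas import MolecularFormula, parse_formula
from .library import BasisSet, SpectralLibrary
from .spectra import Spectrum
from .unmix import UnmixResult, solve

__all__ = [
    "MixtureRecord",
    "Prediction",
    "AccuracyRecord",
    "FailureRecord",
    "BenchmarkReport",
    "rank_candidates",
    "evaluate_exact",
    "evaluate_any",
    "atom_filter",
    "run_distractor_benchmark",
    "run_basis_sweep",
]


@dataclass(frozen=True)
class MixtureRecord:
    """Ground-truth mixture: identities, mole fractions and observed spectrum."""

    id: str
    true_components: tuple[str, ...]
    mole_fractions: tuple[float, ...]
    spectrum: Spectrum

    def __post_init__(self) -> None:
        if len(self.true_components) != len(self.mole_fractions):
            raise InvalidInputError("one mole fraction per component required")
        if len(set(self.true_components)) != len(self.true_components):
            raise InvalidInputError("true components must be distinct")
        if abs(sum(self.mole_fractions) - 1.0) > 1e-9:
            raise InvalidInputError("mole fractions must sum to 1")

    @property
    def n_components(self) -> int:
        return len(self.true_components)


@dataclass(frozen=True)
class Prediction:
    """Candidate components ranked by descending absolute coefficient."""

    ranked_ids: tuple[str, ...]
    coefficients: tuple[float, ...]
    converged: bool = True
    filter_fallback: bool = False  # atom filter found no compatible combination

    def top(self, k: int) -> tuple[str, ...]:
        return self.ranked_ids[:k]


def rank_candidates(result: UnmixResult) -> Prediction:
    """Rank basis components by descending |coefficient|, ties by basis order."""
    items = list(result.coefficients.items())
    order = sorted(range(len(items)), key=lambda i: (-abs(items[i][1]), i))
    return Prediction(
        ranked_ids=tuple(items[i][0] for i in order),
        coefficients=tuple(items[i][1] for i in order),
        converged=result.converged,
    )


def evaluate_exact(prediction: Prediction, truth: set[str] | tuple[str, ...], k: int) -> bool:
    """True when every true component is within the top-k candidates."""
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if not prediction.converged:
        return False
    return set(truth) <= set(prediction.top(k))


def evaluate_any(prediction: Prediction, truth: set[str] | tuple[str, ...], k: int) -> bool:
    """True when at least one true component is within the top-k candidates."""
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if not prediction.converged:
        return False
    return bool(set(truth) & set(prediction.top(k)))


def atom_filter(
    prediction: Prediction,
    mixture_elements: set[str] | dict[str, int],
    formulas: dict[str, MolecularFormula],
    k: int,
    pool_size: int = 10,
    strict_counts: bool = False,
) -> Prediction:
    """Promote the best element-compatible k-combination of candidates.

    Combinations of size k from the top ``pool_size`` candidates are scanned
    in descending joint-|coefficient| order; the first whose union of element
    sets equals ``mixture_elements`` becomes the new top-k (internal order by
    original rank).  When no combination qualifies the unfiltered prediction
    is returned with ``filter_fallback=True``.

    With ``strict_counts=True`` the comparison is on summed atom counts
    instead of element sets: ``mixture_elements`` must then be an
    element → total-atom-count mapping (as would follow from known mole
    ratios), and a combination matches when its formulas sum to it exactly.
    """
    if not prediction.converged:
        return prediction
    if strict_counts and not isinstance(mixture_elements, dict):
        raise MissingMetadataError("strict_counts requires an element->count mapping")
    pool = list(range(min(pool_size, len(prediction.ranked_ids))))
    for i in pool:
        cid = prediction.ranked_ids[i]
        if cid not in formulas:
            raise MissingMetadataError(f"no formula for candidate {cid!r}")
    combos = sorted(
        itertools.combinations(pool, k),
        key=lambda c: (-sum(abs(prediction.coefficients[i]) for i in c), c),
    )
    for combo in combos:
        if strict_counts:
            total: dict[str, int] = {}
            for i in combo:
                for sym, n in formulas[prediction.ranked_ids[i]].as_dict().items():
                    total[sym] = total.get(sym, 0) + n
            matched = total == dict(mixture_elements)
        else:
            union: set[str] = set()
            for i in combo:
                union |= formulas[prediction.ranked_ids[i]].elements
            matched = union == set(mixture_elements)
        if matched:
            chosen = list(combo)
            rest = [i for i in range(len(prediction.ranked_ids)) if i not in set(chosen)]
            order = chosen + rest
            return Prediction(
                ranked_ids=tuple(prediction.ranked_ids[i] for i in order),
                coefficients=tuple(prediction.coefficients[i] for i in order),
                converged=True,
            )
    return Prediction(
        ranked_ids=prediction.ranked_ids,
        coefficients=prediction.coefficients,
        converged=prediction.converged,
        filter_fallback=True,
    )


@dataclass(frozen=True)
class AccuracyRecord:
    """Accuracy under one (criterion, k, basis size, repeat) condition."""

    criterion: str
    k: int
    basis_size: int
    repeat: int
    accuracy: float
    n_mixtures: int
    n_unconverged: int


@dataclass(frozen=True)
class FailureRecord:
    """A mixture missed under the exact criterion, with its top-k prediction."""

    mixture_id: str
    true_components: tuple[str, ...]
    predicted_topk: tuple[str, ...]
    k: int
    basis_size: int
    repeat: int
    converged: bool


@dataclass
class BenchmarkReport:
    """Accuracy records plus per-failure detail for misidentification profiling."""

    protocol: str
    records: list[AccuracyRecord] = field(default_factory=list)
    failures: list[FailureRecord] = field(default_factory=list)

    def accuracies(self, criterion: str = "exact", k: int | None = None) -> list[float]:
        return [
            r.accuracy
            for r in self.records
            if r.criterion == criterion and (k is None or r.k == k)
        ]

    def mean_accuracy(self, criterion: str = "exact", k: int | None = None) -> float:
        vals = self.accuracies(criterion, k)
        if not vals:
            raise InvalidConfigurationError("no records match the requested condition")
        return float(np.mean(vals))

    def std_accuracy(self, criterion: str = "exact", k: int | None = None) -> float:
        return float(np.std(self.accuracies(criterion, k)))

    def to_dict(self) -> dict:
        return {
            "schema": "irmix-report/1",
            "protocol": self.protocol,
            "records": [vars(r) for r in self.records],
            "failures": [
                {**vars(f), "true_components": list(f.true_components),
                 "predicted_topk": list(f.predicted_topk)}
                for f in self.failures
            ],
        }


def _true_union(mixtures: list[MixtureRecord], library: SpectralLibrary) -> list[str]:
    """Union of all mixtures' true components, in library order."""
    wanted = {c for m in mixtures for c in m.true_components}
    missing = wanted - set(library.ids)
    if missing:
        raise InvalidConfigurationError(f"mixture components missing from library: {sorted(missing)}")
    return [cid for cid in library.ids if cid in wanted]


def _evaluate_mixture(
    mixture: MixtureRecord,
    basis: BasisSet,
    algorithm: str,
    lam: float,
) -> Prediction:
    result = solve(mixture.spectrum, basis, algorithm=algorithm, lam=lam)
    return rank_candidates(result)


def run_distractor_benchmark(
    mixtures: list[MixtureRecord],
    library: SpectralLibrary,
    algorithm: str = "nnls",
    k: int | None = None,
    n_repeats: int = 8,
    seed: int = 0,
    lam: float = 0.0,
    n_distractors: int | None = None,
) -> BenchmarkReport:
    """Distractor protocol: true components + equally many random non-components.

    Each repeat draws distractors without replacement with a repeat-specific
    generator derived from ``seed``; accuracy is the fraction of mixtures
    passing the exact criterion at ``k`` (default: each mixture's own size).
    Reports are bit-identical for a fixed (seed, configuration).
    """
    true_ids = _true_union(mixtures, library)
    pool = [cid for cid in library.ids if cid not in set(true_ids)]
    if n_distractors is None:
        n_distractors = len(true_ids)
    if n_distractors > len(pool):
        raise InvalidConfigurationError(
            f"need {n_distractors} distractors but only {len(pool)} non-component spectra exist"
        )
    report = BenchmarkReport(protocol="distractor")
    children = np.random.SeedSequence(seed).spawn(n_repeats)
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        chosen = set(rng.choice(len(pool), size=n_distractors, replace=False).tolist())
        basis_ids = set(true_ids) | {pool[i] for i in chosen}
        basis = library.to_basis([cid for cid in library.ids if cid in basis_ids])
        n_correct = 0
        n_unconverged = 0
        for m in mixtures:
            km = k if k is not None else m.n_components
            pred = _evaluate_mixture(m, basis, algorithm, lam)
            if not pred.converged:
                n_unconverged += 1
            if evaluate_exact(pred, m.true_components, km):
                n_correct += 1
            else:
                report.failures.append(
                    FailureRecord(
                        mixture_id=m.id,
                        true_components=m.true_components,
                        predicted_topk=pred.top(km),
                        k=km,
                        basis_size=len(basis),
                        repeat=rep,
                        converged=pred.converged,
                    )
                )
        report.records.append(
            AccuracyRecord(
                criterion="exact",
                k=k if k is not None else -1,
                basis_size=len(basis),
                repeat=rep,
                accuracy=n_correct / len(mixtures),
                n_mixtures=len(mixtures),
                n_unconverged=n_unconverged,
            )
        )
    return report


def run_basis_sweep(
    mixtures: list[MixtureRecord],
    library: SpectralLibrary,
    algorithm: str = "nnls",
    sizes: list[int] | None = None,
    criteria: tuple[str, ...] = ("exact", "any"),
    k_values: tuple[int, ...] = (2,),
    seed: int = 0,
    lam: float = 0.0,
    use_atom_filter: bool = False,
) -> BenchmarkReport:
    """Nested-basis sweep: accuracy per (basis size, criterion, k).

    The smallest basis is exactly the union of all mixtures' true
    components; each larger basis adds seeded-random further library spectra
    while preserving nesting.  Unconverged fits are counted incorrect and
    tallied.  With ``use_atom_filter`` a third criterion ``"exact_atom"``
    (exact after element-set filtering) is recorded; library formulas are
    then required.
    """
    true_ids = _true_union(mixtures, library)
    if sizes is None:
        sizes = [len(true_ids), len(library)]
    sizes = sorted(sizes)
    if sizes[0] < len(true_ids):
        raise InvalidConfigurationError(
            f"smallest size {sizes[0]} is below the {len(true_ids)} distinct true components"
        )
    if sizes[-1] > len(library):
        raise InvalidConfigurationError(
            f"size {sizes[-1]} exceeds the library ({len(library)} spectra)"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    remaining = [cid for cid in library.ids if cid not in set(true_ids)]
    growth = [remaining[i] for i in rng.permutation(len(remaining))]

    formulas: dict[str, MolecularFormula] = {}
    if use_atom_filter:
        for e in library:
            if e.formula is None:
                raise MissingMetadataError(f"atom filter requested but {e.id!r} has no formula")
            formulas[e.id] = parse_formula(e.formula)

    report = BenchmarkReport(protocol="sweep")
    max_k = max(k_values)
    for size in sizes:
        basis_ids = set(true_ids) | set(growth[: size - len(true_ids)])
        basis = library.to_basis([cid for cid in library.ids if cid in basis_ids])
        preds: list[Prediction] = []
        n_unconverged = 0
        for m in mixtures:
            pred = _evaluate_mixture(m, basis, algorithm, lam)
            if not pred.converged:
                n_unconverged += 1
            preds.append(pred)
        for criterion in criteria:
            evaluate = evaluate_exact if criterion == "exact" else evaluate_any
            for kv in k_values:
                n_correct = sum(
                    evaluate(p, m.true_components, kv) for p, m in zip(preds, mixtures)
                )
                report.records.append(
                    AccuracyRecord(
                        criterion=criterion,
                        k=kv,
                        basis_size=len(basis),
                        repeat=0,
                        accuracy=n_correct / len(mixtures),
                        n_mixtures=len(mixtures),
                        n_unconverged=n_unconverged,
                    )
                )
        if use_atom_filter:
            for kv in k_values:
                n_correct = 0
                for p, m in zip(preds, mixtures):
                    elements: set[str] = set()
                    for cid in m.true_components:
                        elements |= formulas[cid].elements
                    fp = atom_filter(p, elements, formulas, kv)
                    if evaluate_exact(fp, m.true_components, kv):
                        n_correct += 1
                report.records.append(
                    AccuracyRecord(
                        criterion="exact_atom",
                        k=kv,
                        basis_size=len(basis),
                        repeat=0,
                        accuracy=n_correct / len(mixtures),
                        n_mixtures=len(mixtures),
                        n_unconverged=n_unconverged,
                    )
                )
        # failure detail at the smallest k, for misidentification profiling
        for p, m in zip(preds, mixtures):
            km = min(k_values)
            if not evaluate_exact(p, m.true_components, km):
                report.failures.append(
                    FailureRecord(
                        mixture_id=m.id,
                        true_components=m.true_components,
                        predicted_topk=p.top(km),
                        k=km,
                        basis_size=len(basis),
                        repeat=0,
                        converged=p.converged,
                    )
                )
    return report
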