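"""Seeded synthetic spectra: gas-like, liquid-like, and their mixtures.

The generator emulates the statistics that matter for identification
benchmarks rather than specific functional-group chemistry: a molecule is a
random set of vibrational bands (Gaussian or Lorentzian peaks on the common
wavenumber grid) plus a molecular formula.  Gas-like spectra have sharp,
distinct peaks; the liquid-like counterpart of the same molecule has the
same bands broadened (×2–6) and rigidly shifted (−30…+30 cm⁻¹), mimicking
condensed-phase intermolecular interactions.  Formulas are sampled over
C/H/N/O/S/Cl/Br with configurable rates of planted isomer and single-atom
substitution traps, so misidentification profiling has known ground truth.

Mixtures are equimolar by default.  With zero nonlinearity a mixture is the
exact mole-fraction-weighted sum of its pure spectra (the linear, gas-phase
regime); nonzero nonlinearity shifts each component's peaks and jitters
their intensities before summation, emulating liquid-phase mixing effects.
Everything is deterministic from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidConfigurationError, InvalidParameterError
from .formulas import MolecularFormula
from .identify import MixtureRecord
from .library import LibraryEntry, SpectralLibrary
from .spectra import DEFAULT_GRID, Spectrum, WavenumberGrid

__all__ = [
    "PeakModel",
    "SyntheticMolecule",
    "GeneratorConfig",
    "SuiteConfig",
    "BenchmarkSuite",
    "generate_molecules",
    "render_pure_spectrum",
    "generate_library",
    "make_mixture",
    "generate_benchmark_suite",
]


@dataclass(frozen=True)
class PeakModel:
    """One vibrational band: center and width in cm⁻¹, relative intensity."""

    center: float
    sigma: float
    intensity: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.intensity <= 0:
            raise InvalidParameterError("peak sigma and intensity must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise InvalidParameterError(f"unknown peak shape {self.shape!r}")


@dataclass(frozen=True)
class SyntheticMolecule:
    """A molecule's gas-phase bands plus its gas→liquid transform.

    ``liquid_shift`` (cm⁻¹, may be negative = red shift) and ``broadening``
    (≥ 1, multiplies every peak width) turn the gas-phase bands into the
    liquid-phase spectrum.
    """

    id: str
    formula: MolecularFormula
    peaks: tuple[PeakModel, ...]
    liquid_shift: float = 0.0
    broadening: float = 1.0

    def __post_init__(self) -> None:
        if not self.peaks:
            raise InvalidParameterError("a molecule needs at least one peak")
        if self.broadening < 1.0:
            raise InvalidParameterError("broadening factor must be >= 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling ranges for synthetic molecules.

    Defaults give sharp gas-like peaks (σ 4–10 cm⁻¹) within the informative
    200–3800 cm⁻¹ region, liquid broadening ×2–6 and liquid shifts biased
    slightly toward red (hydrogen-bond-like) via ``shift_red_bias``.
    """

    n_peaks: tuple[int, int] = (3, 8)
    sigma_range: tuple[float, float] = (4.0, 10.0)
    center_range: tuple[float, float] = (200.0, 3800.0)
    intensity_range: tuple[float, float] = (0.2, 1.0)
    broadening_range: tuple[float, float] = (2.0, 6.0)
    liquid_shift_range: tuple[float, float] = (-30.0, 30.0)
    shift_red_bias: float = 0.0  # cm⁻¹ subtracted from every liquid shift
    lorentzian_fraction: float = 0.2
    isomer_rate: float = 0.05
    substitution_rate: float = 0.05
    carbon_range: tuple[int, int] = (2, 10)
    hetero_elements: tuple[str, ...] = ("N", "O", "S", "Cl", "Br")
    hetero_prob: float = 0.35

    def __post_init__(self) -> None:
        for lo, hi in (self.n_peaks, self.sigma_range, self.center_range,
                       self.intensity_range, self.broadening_range,
                       self.liquid_shift_range, self.carbon_range):
            if lo > hi:
                raise InvalidConfigurationError(f"invalid range ({lo}, {hi})")
        if self.sigma_range[0] <= 0 or self.broadening_range[0] < 1:
            raise InvalidConfigurationError("sigma must be positive and broadening >= 1")


def _sample_formula(rng: np.random.Generator, config: GeneratorConfig,
                    previous: list[MolecularFormula]) -> MolecularFormula:
    u = rng.random()
    if previous and u < config.isomer_rate:
        return previous[rng.integers(len(previous))]  # planted isomer trap
    if previous and u < config.isomer_rate + config.substitution_rate:
        base = dict(previous[rng.integers(len(previous))].as_dict())
        for a, b in (("Cl", "Br"), ("Br", "Cl"), ("O", "S"), ("S", "O"), ("N", "O")):
            if a in base and b not in base:
                base[b] = base.pop(a)  # planted single-atom substitution trap
                return MolecularFormula.from_dict(base)
    c = int(rng.integers(config.carbon_range[0], config.carbon_range[1] + 1))
    counts = {"C": c, "H": int(rng.integers(c, 2 * c + 3))}
    for sym in config.hetero_elements:
        if rng.random() < config.hetero_prob:
            counts[sym] = int(rng.integers(1, 3))
    return MolecularFormula.from_dict(counts)


def generate_molecules(
    n_molecules: int,
    config: GeneratorConfig = GeneratorConfig(),
    seed: int = 0,
) -> list[SyntheticMolecule]:
    """Sample ``n_molecules`` synthetic molecules, deterministic from seed."""
    if n_molecules < 1:
        raise InvalidConfigurationError("n_molecules must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    molecules: list[SyntheticMolecule] = []
    formulas: list[MolecularFormula] = []
    width = max(3, len(str(n_molecules - 1)))
    for i in range(n_molecules):
        n_peaks = int(rng.integers(config.n_peaks[0], config.n_peaks[1] + 1))
        peaks = tuple(
            PeakModel(
                center=float(rng.uniform(*config.center_range)),
                sigma=float(rng.uniform(*config.sigma_range)),
                intensity=float(rng.uniform(*config.intensity_range)),
                shape="lorentzian" if rng.random() < config.lorentzian_fraction else "gaussian",
            )
            for _ in range(n_peaks)
        )
        formula = _sample_formula(rng, config, formulas)
        formulas.append(formula)
        molecules.append(
            SyntheticMolecule(
                id=f"mol{i:0{width}d}",
                formula=formula,
                peaks=peaks,
                liquid_shift=float(rng.uniform(*config.liquid_shift_range) - config.shift_red_bias),
                broadening=float(rng.uniform(*config.broadening_range)),
            )
        )
    return molecules


def _profile(grid: WavenumberGrid, center: float, sigma: float,
             intensity: float, shape: str) -> np.ndarray:
    nu = grid.wavenumbers
    if shape == "gaussian":
        return intensity * np.exp(-0.5 * ((nu - center) / sigma) ** 2)
    return intensity * sigma**2 / ((nu - center) ** 2 + sigma**2)


def render_pure_spectrum(
    mol: SyntheticMolecule,
    grid: WavenumberGrid = DEFAULT_GRID,
    phase: str = "gas",
    peak_shifts: np.ndarray | None = None,
    intensity_factors: np.ndarray | None = None,
) -> Spectrum:
    """Render a molecule's unit-area spectrum in the given phase.

    ``peak_shifts`` / ``intensity_factors`` (one per peak) perturb the bands
    before rendering; used by the nonlinear mixing model.
    """
    if phase not in ("gas", "liquid"):
        raise InvalidParameterError(f"phase must be 'gas' or 'liquid', got {phase!r}")
    shifts = np.zeros(len(mol.peaks)) if peak_shifts is None else np.asarray(peak_shifts)
    factors = np.ones(len(mol.peaks)) if intensity_factors is None else np.asarray(intensity_factors)
    x = np.zeros(grid.n_points)
    for peak, ds, fac in zip(mol.peaks, shifts, factors):
        center = peak.center + ds
        sigma = peak.sigma
        if phase == "liquid":
            center += mol.liquid_shift
            sigma *= mol.broadening
        x += _profile(grid, center, sigma, fac * peak.intensity, peak.shape)
    area = x.sum() * grid.step
    if area <= 0:
        raise InvalidParameterError(f"molecule {mol.id} renders to an empty spectrum")
    return Spectrum(grid, x / area, normalized=True)


def generate_library(
    n_molecules: int,
    grid: WavenumberGrid = DEFAULT_GRID,
    phase: str = "gas",
    config: GeneratorConfig = GeneratorConfig(),
    seed: int = 0,
) -> tuple[SpectralLibrary, list[SyntheticMolecule]]:
    """Seeded library of pure-component spectra plus the molecule metadata."""
    molecules = generate_molecules(n_molecules, config, seed)
    entries = [
        LibraryEntry(
            id=m.id,
            spectrum=render_pure_spectrum(m, grid, phase),
            name=m.id,
            formula=m.formula.hill(),
            phase=phase,
        )
        for m in molecules
    ]
    return SpectralLibrary(entries), molecules


def make_mixture(
    molecules: dict[str, SyntheticMolecule],
    components: tuple[str, ...],
    fractions: tuple[float, ...],
    grid: WavenumberGrid = DEFAULT_GRID,
    phase: str = "gas",
    nonlinearity: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    mixture_id: str | None = None,
) -> MixtureRecord:
    """Compose a mixture spectrum from pure components.

    ``nonlinearity = (shift_sd, jitter_sd)``: each component's peaks are
    rigidly shifted by N(0, shift_sd²) cm⁻¹ and each peak's intensity
    multiplied by exp(N(0, jitter_sd²)) before summation.  With (0, 0) the
    mixture is exactly the fraction-weighted sum of the pure unit-area
    spectra rendered by :func:`render_pure_spectrum` (and hence of the
    matching library entries).
    """
    if len(components) != len(fractions):
        raise InvalidConfigurationError("one fraction per component required")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidConfigurationError(f"fractions must sum to 1, got {sum(fractions)}")
    shift_sd, jitter_sd = nonlinearity
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = np.zeros(grid.n_points)
    for cid, frac in zip(components, fractions):
        mol = molecules[cid]
        if shift_sd > 0 or jitter_sd > 0:
            ds = rng.normal(0.0, shift_sd) * np.ones(len(mol.peaks))
            fac = np.exp(rng.normal(0.0, jitter_sd, size=len(mol.peaks)))
            pure = render_pure_spectrum(mol, grid, phase, peak_shifts=ds, intensity_factors=fac)
        else:
            pure = render_pure_spectrum(mol, grid, phase)
        x += frac * pure.intensities
    area = x.sum() * grid.step
    x = x / area  # area == 1 up to rounding in the linear case
    return MixtureRecord(
        id=mixture_id or "+".join(components),
        true_components=tuple(components),
        mole_fractions=tuple(float(f) for f in fractions),
        spectrum=Spectrum(grid, x, normalized=True),
    )


@dataclass(frozen=True)
class SuiteConfig:
    """Sizes and conditions of a benchmark input set.

    Mixture components are drawn from the first ``component_pool`` molecules
    so that the rest of the library can serve as distractors.
    """

    n_molecules: int = 200
    n_binary: int = 100
    n_ternary: int = 50
    component_pool: int = 80
    phase: str = "gas"
    nonlinearity: tuple[float, float] = (0.0, 0.0)
    grid: WavenumberGrid = DEFAULT_GRID
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if self.component_pool > self.n_molecules:
            raise InvalidConfigurationError("component_pool exceeds n_molecules")
        if self.component_pool < 3 and self.n_ternary > 0:
            raise InvalidConfigurationError("ternary mixtures need a pool of >= 3 molecules")


@dataclass(frozen=True)
class BenchmarkSuite:
    """A library, its molecule metadata, and ground-truth mixtures."""

    library: SpectralLibrary
    molecules: list[SyntheticMolecule]
    mixtures: list[MixtureRecord]


def generate_benchmark_suite(config: SuiteConfig = SuiteConfig(), seed: int = 0) -> BenchmarkSuite:
    """Full benchmark input set: library + equimolar binary/ternary mixtures."""
    ss = np.random.SeedSequence(seed)
    lib_seed, mix_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    library, molecules = generate_library(
        config.n_molecules, config.grid, config.phase, config.generator, seed=lib_seed
    )
    by_id = {m.id: m for m in molecules}
    pool = [m.id for m in molecules[: config.component_pool]]
    rng = np.random.default_rng(np.random.SeedSequence(mix_seed))
    mixtures: list[MixtureRecord] = []
    seen: set[tuple[str, ...]] = set()
    sizes = [2] * config.n_binary + [3] * config.n_ternary
    for i, size in enumerate(sizes):
        while True:
            picks = tuple(sorted(rng.choice(len(pool), size=size, replace=False).tolist()))
            components = tuple(pool[j] for j in picks)
            if components not in seen:
                seen.add(components)
                break
        fractions = tuple([1.0 / size] * size)
        mixtures.append(
            make_mixture(
                by_id,
                components,
                fractions,
                grid=config.grid,
                phase=config.phase,
                nonlinearity=config.nonlinearity,
                seed=int(rng.integers(2**31)),
                mixture_id=f"mix{i:04d}",
            )
        )
    return BenchmarkSuite(library=library, molecules=molecules, mixtures=mixtures)
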