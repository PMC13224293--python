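# Methods

## Spectral representation

Every spectrum is a vector of intensities on a uniform wavenumber grid.
The default grid places 1250 points at νᵢ = 4i cm⁻¹, i = 0…1249, covering
0–4996 cm⁻¹; grids are first-class objects and fully configurable. A
"grid span" of step × n_points (5000 cm⁻¹ for the default) is used in the
cumulative-distribution shift identity below, treating each grid point as
a bin of width `step`.

Preprocessing applies, in order: Gaussian smoothing (a discrete
convolution with reflective edges, truncated at 4σ, which conserves total
intensity), clipping of negative intensities to zero, and normalization
by the rectangle-rule area `sum × step` to unit integrated intensity.
The smoothing width is expressed in cm⁻¹; the default of 8 cm⁻¹ (two grid
steps) suppresses pointwise noise without merging neighboring bands at
the 4 cm⁻¹ resolution. Rectangle-rule area was chosen over the trapezoid
rule as the simplest consistent reading of "total integrated intensity";
all downstream identities (CDF ending at exactly 1, the shift identity)
are exact under it.

Three metrics compare spectra:

- **MSE** — mean over grid points of the squared intensity difference.
  Reported values are means of squared unit-area intensities and thus
  dimensionless; reports quote them as conventionally printed.
- **CDF** — the running sum of `intensity × step` of a unit-area
  spectrum; non-decreasing and ending at 1.
- **Mean CDF difference** — mean over grid points of CDF(a) − CDF(b),
  optionally as mean absolute value. The sign convention is fixed so a
  positive signed value means spectrum *a* is concentrated at lower
  wavenumbers (red-shifted) relative to *b*; for a rigid on-grid shift by
  Δ the signed value is exactly Δ / span, and in general
  signed gap × span equals the difference of spectral first moments.
  Both the signed and absolute variants are exposed because either is a
  defensible reading of an "average distance between CDFs"; the signed
  form carries shift direction and is the default in reconstruction
  traces.

## IR spectra from dipole trajectories

For a simulated system, the IR absorbance follows from the total dipole
M(t): the autocorrelation C(τ) = ⟨M(t)·M(t+τ)⟩ is estimated without bias
(each lag divided by its count of valid time origins; FFT-accelerated),
tapered with a Hann window over lags (configurable, with a "none"
option), zero-padded so the transform resolves a quarter grid step, and
transformed with the cosine transform of its even extension,
C̃(ν) = 2·Re(rfft) − C(0). Using the raw real part of the one-sided FFT
instead would leave a spurious flat +C(0)/2 offset that the subsequent ν²
weighting amplifies into a large high-wavenumber floor; the even-extension
form removes it exactly. The quantum-corrected spectrum is
S_qm(ν) = C̃(ν)·ν², with the field-coupling and thermal-correction
factors folded into the single ν² weighting; the optional trajectory
temperature is retained as metadata only. The frequency axis converts to
wavenumber as ν[cm⁻¹] = f/c with f in cycles/fs and
c = 2.99792458×10⁻⁵ cm/fs; requesting grid wavenumbers at or beyond the
trajectory's Nyquist limit 1/(2cΔt) is an error rather than silent
aliasing. The default maximum lag is half the trajectory — the
conventional compromise between spectral resolution and estimator
variance. The result is regridded, clipped and unit-area normalized like
any other spectrum.

Gas-phase mixtures are composed as mole-fraction-weighted sums of pure
spectra: with uncorrelated molecular dipoles the cross-correlations
vanish and mixing is exactly linear.

## Deconvolution

All algorithms minimize ‖y − Xᵀc‖² + λ‖c‖² per mixture (the multi-mixture
matrix form decouples row by row, so each mixture is solved
independently):

- **LS** (λ = 0 by default): unconstrained; coefficients may be negative.
- **NNLS**: the same objective under c ≥ 0, solved by the active-set
  method. Ridge regularization augments the design with a √λ·I block and
  zeros on the target, which reduces exactly to plain NNLS at λ = 0.
  The iteration cap defaults to 3 × basis size (the conventional
  active-set bound); hitting it — which happens under strong basis
  collinearity — is surfaced as `converged=False` with zero coefficients,
  never an exception, and the benchmark layer counts such mixtures as
  incorrect.
- **Ridge variants**: the same code paths with λ > 0; λ defaults to 0
  and is a run-configuration value.
- **Pairwise interpolation** (binary baseline): for every unordered pair
  (i, j), the optimal convex weight has the closed form
  α* = clamp₀¹(⟨y − xⱼ, xᵢ − xⱼ⟩/‖xᵢ − xⱼ‖²); the minimal-residual pair
  wins, ties resolved by library order, and identical pair spectra take
  α = 0.5 by convention.

Candidates are ranked by descending |coefficient| with ties broken by
basis order, making every report a deterministic function of (inputs,
seed, configuration).

## Identification benchmarks

Two protocols measure identification accuracy:

- **Distractor protocol** — the basis contains every true component of
  the mixture suite plus an equal number of spectra of molecules absent
  from all mixtures, drawn without replacement with a repeat-specific
  generator spawned from the master seed; 8 repeats by default. Accuracy
  is the fraction of mixtures whose true components all appear in the
  top k, with k defaulting to each mixture's known size.
- **Basis sweep** — nested basis sets grow from the minimal one (exactly
  the union of all mixtures' components) by adding library spectra in a
  seeded random order (the growth order is not otherwise specified, so a
  seeded shuffle keeps it reproducible); accuracy is recorded per
  (size, criterion, k). The *any* criterion (at least one true component
  in the top k) is recorded alongside *exact*.

The **atom filter** models the elemental knowledge that mass spectrometry
or elemental analysis provides: combinations of k candidates from the
top-10 pool are scanned in descending joint-coefficient order, and the
first whose element sets union to the mixture's element set is promoted.
Element-*set* compatibility was chosen over strict atom counts because
presence/absence of elements is what experiments typically establish
(e.g. I vs Cl), and strict counts would require known mole ratios; a
strict count mode exists behind a flag as an interpretation alternative.
When no combination qualifies, the unfiltered prediction stands, flagged.

## Component-count inference

Starting from a zero-intensity spectrum, components are added in
descending coefficient order, each scaled by its coefficient. After each
addition the partial reconstruction ŷ is scored against the target y by

    R² = 1 − Σ(y − ŷ)² / Σ(y − ȳ)²,

with ȳ the mean intensity of y over the grid, plus MSE and the signed
mean cumulative-intensity gap (computed on raw cumulative sums, since a
partial reconstruction is not yet unit-area). The inferred component
count is the smallest n whose next step improves R² by less than a
threshold, 1% by default; the threshold is a first-class configuration
value because the appropriate plateau sensitivity depends on the noise
level of the data at hand. A complementary leave-one-out analysis refits
the basis without one component and reports the drop in R² and the
increases in MSE and |CDF gap| as that component's importance.

## Robustness model

Spectral perturbations are rigid whole-spectrum translations with fixed
magnitude and random sign, realized on-grid (vacated bins zero-filled,
result renormalized). Per-peak independent shifting is deliberately out
of scope: measured or simulated spectra do not individuate peaks in this
data model. The robustness curve rebuilds each mixture from independently
shifted pure spectra while the identification basis keeps the unshifted
library — emulating reference data that do not match the measurement
conditions — and records exact top-k accuracy per magnitude.

## Misidentification profiling

For each failed mixture, true components missing from the top-k are
paired with false-positive candidates by globally minimal spectral MSE
(a pairing rule is needed when two or more components are wrong, and
spectral proximity is the quantity the solver itself confuses). Pairs are
classified at the formula level: *isomer* (identical formulas),
*substitution* (exactly one atom of one element swapped for one of
another), *carbon difference* (only the carbon count differs, by exactly
one — read literally, hydrogens equal; a tolerance mode allowing ΔH ≤ 2
exists behind a flag and is flagged as an interpretation risk), otherwise
*other*. A mixture whose pairs span two or more named classes is labeled
*mixed*. Percentages are reported over failed, converged mixtures.

## Synthetic data generator

The generator emulates the statistics that drive identification — band
sharpness, overlap, phase broadening and shifts, formula collisions —
not specific functional-group chemistry. A molecule is 3–8 random bands
(Gaussian, with a 20% Lorentzian fraction) with centers in
200–3800 cm⁻¹, widths σ of 4–10 cm⁻¹ and relative intensities 0.2–1.
The liquid-phase counterpart broadens every band by a factor of 2–6 and
rigidly shifts the spectrum by −30…+30 cm⁻¹, with an optional red bias
mimicking hydrogen bonding. Formulas are sampled over C/H/N/O/S/Cl/Br
with planted isomer and single-atom-substitution traps at 5% each by
default, giving misidentification profiling known ground truth.
Mixtures are equimolar by default; with zero nonlinearity they are exact
fraction-weighted sums of unit-area pure spectra (the gas-phase regime),
and the nonlinearity knob (per-component center shift SD, per-peak
log-normal intensity jitter) emulates liquid-phase mixing effects.

The default suite — 200 molecules, 100 binary and 50 ternary mixtures,
with mixture components drawn from an 80-molecule pool so the rest of
the library can serve as distractors — keeps a full benchmark run within
seconds while leaving the distractor protocol well-posed. All sizes are
configurable.

What passing tests on this generator establish: the solvers, ranking,
counting and profiling machinery are correct under exactly the linear
and perturbed conditions they model. What they do not establish:
performance on real condensed-phase data, whose nonlinear mixing,
anharmonic couplings, baseline artifacts and correlated band structure
the generator only caricatures. Real-data accuracy is bounded by
spectral degeneracy — distinct molecules with nearly identical liquid
spectra — which the generator reproduces only when traps are planted.

## Numerical choices and degenerate inputs

- Normalizing an all-zero (post-clip) spectrum, a zero-variance
  deconvolution target, or an empty reconstruction trace raises a typed
  error rather than producing NaNs.
- Coefficient ties rank by basis order; pairwise-interpolation ties keep
  the earliest pair; nearest-neighbor ties keep library order.
- All randomness flows through `numpy.random.SeedSequence` spawning, so
  every report is bit-identical for a fixed (seed, configuration) and
  independent draws (repeats, magnitudes) do not share streams.
- NNLS/LS coefficient agreement with the exhaustive active-set oracle is
  asserted to 1e-8 on small instances; unit-area checks use 1e-9.

## Known limitations

- Whole-spectrum rigid shifts understate the complexity of real
  solvent-induced band movements, which are mode-specific.
- The ν² quantum-correction form is the combined factor; alternative
  field/thermal correction factorizations are not implemented separately.
- The pairwise baseline is O(p²) in library size and is intended as a
  baseline, not a production identifier.
- Formula-level isomer classification cannot distinguish true structural
  isomers from identical-formula coincidences; connectivity is out of
  scope.
- JCAMP-DX and vendor binary spectrum formats are not read; baseline and
  ATR penetration-depth corrections are out of scope.
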