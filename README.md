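# irmix

Automatic identification of the molecular components of liquid- and
gas-phase mixtures from their infrared spectra, by linear deconvolution
against a library of pure-component spectra.

## The problem

Infrared spectroscopy is fast and nondestructive, but interpreting the IR
spectrum of a liquid mixture is still expert work: condensed-phase bands
broaden, shift, and mix nonlinearly, so a mixture spectrum is not simply
the sum of its parts. `irmix` implements and benchmarks the algorithmic
alternative: treat a set of identified pure-component spectra
x₁, …, x_p (all unit-area vectors on a common wavenumber grid) as a basis,
and decompose an observed mixture spectrum y by non-negative least squares,

    min_{c ≥ 0} ‖y − Σᵢ cᵢ xᵢ‖² + λ‖c‖²,

ranking components by |cᵢ| and reading the top-k as the predicted mixture
composition. Ordinary least squares, ridge-regularized variants, and a
brute-force pairwise convex-interpolation baseline are provided for
comparison, along with:

- **spectral preprocessing** — regridding to a uniform 4 cm⁻¹ grid
  (0–4996 cm⁻¹ by default), Gaussian smoothing, clipping, unit-area
  normalization, and three comparison metrics (MSE, CDF, signed mean CDF
  difference, whose value for a rigid band shift of Δ cm⁻¹ is exactly
  Δ / grid span);
- **spectra from simulated dipoles** — S_qm(ν) = C̃(ν)·ν², the
  ν²-weighted Fourier transform of the total-dipole autocorrelation of a
  molecular-dynamics trajectory;
- **benchmark protocols** — distractor repeats (true components plus an
  equal number of random non-components) and nested basis-size sweeps,
  under *exact* (all true components in the top k) and *any* (at least
  one) criteria, with an optional element-composition filter;
- **component-count inference** — cumulative explained spectral variance
  R² = 1 − Σ(y − ŷ)²/Σ(y − ȳ)² along the coefficient-ranked
  reconstruction, whose plateau names the number of components;
- **robustness and misidentification analysis** — accuracy under rigid
  random band shifts, and classification of failures into structural
  isomers, single-atom substitutions, one-carbon homologues, mixed, and
  other, paired by spectral distance;
- **synthetic fixtures** — a seeded generator of gas-like (sharp-peak)
  and liquid-like (broadened, shifted) spectra, formulas with planted
  isomer/substitution traps, and linear or nonlinear mixtures, so every
  analysis runs without any external download.

## Worked example

```python
from irmix import (SuiteConfig, generate_benchmark_suite, fit_nnls,
                   rank_candidates, reconstruction_trace,
                   infer_component_count, run_distractor_benchmark)

suite = generate_benchmark_suite(SuiteConfig(phase="gas"), seed=1)
mix = next(m for m in suite.mixtures if m.n_components == 3)
basis = suite.library.to_basis()

result = fit_nnls(mix.spectrum, basis)
pred = rank_candidates(result)
print("true components:", mix.true_components)
for cid, c in zip(pred.ranked_ids[:4], pred.coefficients[:4]):
    print(f"  {cid}  coefficient = {c:.4f}")

trace = reconstruction_trace(mix.spectrum, result, basis)
print("cumulative R^2:", [round(s.r_squared, 4) for s in trace.steps[:4]])
print("inferred component count:", infer_component_count(trace))

binaries = [m for m in suite.mixtures if m.n_components == 2]
report = run_distractor_benchmark(binaries, suite.library, algorithm="nnls",
                                  k=2, n_repeats=8, seed=1)
print(f"top-2 exact accuracy: {100*report.mean_accuracy('exact'):.1f}% "
      f"+/- {100*report.std_accuracy('exact'):.1f}% over 8 repeats")
```

prints

```
true components: ('mol008', 'mol012', 'mol054')
  mol012  coefficient = 0.3333
  mol008  coefficient = 0.3333
  mol054  coefficient = 0.3333
  mol011  coefficient = 0.0000
cumulative R^2: [0.4027, 0.6133, 1.0, 1.0]
inferred component count: 3
top-2 exact accuracy: 100.0% +/- 0.0% over 8 repeats
```

The equimolar ternary mixture is recovered with coefficients 1/3 each
(unit-area basis spectra make NNLS coefficients proportional to mole
fractions in the linear regime), the explained-variance plateau at step 3
names the component count, and strictly linear binary mixtures are
identified perfectly across all distractor draws.

## Command line

The same functionality is exposed as `irmix` subcommands — `simulate`,
`dipole2ir`, `deconvolve`, `identify`, `count`, `benchmark`, `perturb`,
`profile-misid`, `adapt` — operating on two-column spectrum CSVs and a
versioned JSON library format. Every run writes a manifest (config hash,
seed, package versions) sufficient to reproduce its output. The `adapt`
subcommand maps a locally downloaded external spectra deposit onto the
library schema through a declarative YAML mapping; nothing is ever
downloaded by the package itself.

```bash
irmix simulate --seed 1 --out-dir fixtures/
irmix benchmark --mixtures fixtures/mixtures.json --library fixtures/library.json \
      --protocol distractor --k 2 --repeats 8 --seed 1 --report report.json
```

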