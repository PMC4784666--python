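# Methods

## Model and conventions

A SAD observation is a merged Bijvoet amplitude pair (F⁺, σ⁺, F⁻, σ⁻) per
unique reflection.  The complex structure factor is decomposed as

* **F_P** — all ordinary atoms (real scattering f⁰(s) + f′),
* **F_H** — real scattering of the substructure atoms,
* **F_A** — imaginary scattering of the substructure (the f″ part), a vector
  perpendicular to F_H with |F_A|/|F_H| = f″/(f⁰+f′) for a single-element
  substructure.

Writing F_n for the full non-anomalous structure factor and A for the
complex f″-weighted substructure sum, the exact mates are F⁺ = |F_n + iA|
and F⁻ = |F_n − iA|.  To first order in F_A/F the anomalous difference is
Δ_ano ≈ −2 F_A sin α with α = phase(F_H) − φc.

Conventions fixed once and used everywhere:

* s = sinθ/λ = 1/(2d); Debye-Waller attenuation exp(−B s²).
* Fractional coordinates wrapped to [0,1); of a Friedel pair the
  lexicographically greater index triple is stored (h>0 preferred, then k,
  then l).  A reflection is centric iff a rotation maps h to −h; centric
  reflections carry no anomalous difference and are excluded from all
  anomalous statistics.  N_refl counts unique *acentric* entries.
* φc defaults to the phase of F_P + F_H (full non-anomalous structure
  factor).  The alternative phase(F_P) is available
  (`phase_convention="protein"`); for protein-like compositions the two
  differ negligibly because |F_H| ≪ |F_P|, and the default is what a
  refined-model phase set actually provides.
* Symmetry is an explicit operator list (P1 default; P1̄, P2, P2₁
  constructors provided).  No space-group symbol parsing, no centering
  translations, no anisotropic B.  Special positions get site weights
  1/(number of fixing operators).

## The anomalous difference Fourier and S_ano

Map coefficients are Δ_ano,h·exp[i(φc,h − π/2)] on the stored Friedel
representatives with Hermitian mates implied; density is synthesized as
ρ(x) = (1/V)Σ_full-sphere c_h e^{−2πi h·x} and is therefore real.  Site
values are evaluated by direct summation at the exact model coordinates —
no grid, no interpolation, no peak search — so S_ano = mean(ρ(x_j))/rms is
free of gridding artifacts.  The rms comes from the Parseval identity
⟨ρ²⟩ = Σ|c_h|²/V² = 2ΣΔ²/V²; an FFT grid synthesis (`adf_grid`) exists as an
independent cross-check and for visualization.

With this normalization the expected site peak of noise-free data is
N⟨f_{h,B}⟩/V (N counting the full sphere = 2·N_refl in P1) and the expected
mean square is 2·N·n·⟨f²_{h,B}⟩/V², which gives

    S_ano(ideal) = √(N_refl / n_sites) / f_B,      f_B = rms(f_{h,B})/mean(f_{h,B}),

and, with errors, S_ano = CC_ano·√(N_refl/n_sites)/f_B, since uncorrelated
errors inflate the map variance by 1+E² while leaving the expected peak
unchanged, and CC_ano = 1/√(1+E²).

f_B is computed over unique acentric reflections using the *mean*
substructure B when sites have unequal B factors; CC_ano is the plain
Pearson correlation (mean-subtracted — with zero-mean differences this
coincides with the uncentred form but is robust to scale offsets in real
data).  σ values are carried through the I/O but the core metrics are
unweighted.

## Scattering factors

f⁰(s) is a sum of Gaussians + constant; coefficients default to the
International Tables parameterization shipped with gemmi, may be loaded
from a CSV table, or constructed as a one-Gaussian synthetic element.
f′ and f″ are user-supplied scalars, constant with resolution (the
imaginary scattering arises from core electrons, so its transform is flat);
no wavelength-dependent dispersion curves.

## The synthetic-data generator

`SimulationConfig` defaults emulate a reasonably measured SeMet SAD
experiment on a mid-size protein crystal, chosen once on physical grounds:

| parameter | default | why |
|---|---|---|
| cell | 50 Å cube, P1 | mid-size protein cell; P1 exercises every formula |
| d_min | 2.5 Å | typical SAD resolution; ~17k unique acentric pairs |
| light atoms | 1200 (C:N:O ≈ 62:17:21) | ~1 Se per 300 non-H atoms, the stoichiometry of natural Met abundance |
| substructure | 4 Se, f′ = −3.0, f″ = 3.8 e | Se K-edge high-energy remote values |
| B factors | ordinary 10–40 Ų, substructure 30–60 Ų | substructure sites are usually more disordered |
| minor sites | 8 × S at f″ = 0.38 e | the "true but useless" anomalous background |
| noise | σ = 1% of ⟨F⟩ per amplitude | good synchrotron data |
| min distance | 1.5 Å | physical non-bonded contact floor |

This puts the overall Bijvoet ratio ⟨|ΔF|⟩/⟨F⟩ near 4%, inside the 1–5%
band typical of real SAD data, and the realized CC_ano near 0.94.

Noise is Gaussian on each *amplitude* (not intensity), because every
quantity in scope is an amplitude difference and this keeps the variance
bookkeeping exact: var(ε_Δ) = 2σ².  Three mutually exclusive noise modes are
accepted — absolute σ, σ relative to ⟨F⟩, or a target normalized variance E²
(σ is then solved from the realized ms(Δ_ano) of the crystal, which is what
lets tests dial in an exact expected CC_ano).  Negative noisy amplitudes are
clamped to zero, counted, and retained.  Radiation damage is not modeled
separately; it is part of ε.  The Δ_ano^other term is generated as explicit
weak anomalous minor sites (a physical mechanism) rather than i.i.d. noise;
the dataset records the realized E² and CC_ano from the truth decomposition.

What the generator does *not* emulate: bulk solvent, anisotropy,
resolution-dependent error profiles, partiality/scaling artifacts, unmerged
multiplicity, and intensity-domain statistics.  Passing tests therefore
demonstrate the internal consistency of the theory and its implementation
under the stated error model, not robustness to every pathology of real
data.

## Numerical choices and accuracy limits

* Structure factors by direct summation (vectorized, 128-atom blocks);
  "ideal Δ_ano" is always the *exact* amplitude difference of the
  substructure-only-anomalous model, not the first-order expression, which
  is kept as a separate checkable operation.
* The first-order theory carries a small systematic deficit of the measured
  peak relative to N⟨f_{h,B}⟩/V (weak reflections violate F_A ≪ F).  At
  protein-like compositions (~1 anomalous scatterer per 300 light atoms)
  the deficit in S_ano is ~1–2%; it grows when the substructure dominates
  the scattering.  Validation targets therefore keep protein-like
  stoichiometry, and tolerance choices (5–7%) reflect this plus Monte-Carlo
  sampling error.
* Degenerate inputs raise typed errors rather than returning NaN: cells
  with non-positive volume, the (0,0,0) reflection, empty substructures,
  zero-variance correlations, zero-rms maps, f_B < 1 (clamped at exactly 1
  against rounding when all factors are equal).
* Seeds: crystal generation uses `seed`, measurement noise `seed + 1`, so
  the same crystal can be re-measured; all runs are bit-reproducible.

## Solvability calibration

P(solved | S_ano) = logistic((S_ano − s50)/width) with defaults s50 = 9,
width = 1.5, anchored to the observed behavior of real SAD data sets: ~50%
success at signal 9, few successes below ~7 (P(7) ≈ 0.21), most above ~13
(P(13) ≈ 0.93), P(0) ≈ 0.003.  The logistic form and the width are an
interpretation of those published bands — the underlying evidence is binned
success fractions, not a fitted curve — so both are configuration
(JSON-loadable), and the solved-site criterion (≥50% of sites within 3 Å,
symmetry allowing) is recorded with them.  The package deliberately does
not run a substructure-search program to re-derive the curve.

## Validation problem sizes

The predicted-vs-measured sweep uses 20 seeded P1 simulations (cells
40–60 Å, 1–16 Se sites, substructure B 10–60 Ų, d_min 2.0–3.0 Å, target E²
0–99 so realized CC_ano spans ~0.1–1.0, N_refl ≈ 13k–37k, 800 light atoms);
observed agreement: Pearson r ≈ 0.999, regression slope ≈ 0.99.  The √N law
is checked at N_refl ≈ 5k/10k/20k, the site-scaling law at 1/4/16 sites with
light atoms scaled 300:1 to keep the small-F_A regime uniform, and the
CC_ano(E²) closed form at E² ∈ {0,1,3} with ≥5000 pairs.  These sizes keep
the whole suite within a few minutes on one core while leaving the
statistical tolerances comfortably non-binding.
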