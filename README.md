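# sadsignal

Quantifying the useful information in a single-wavelength anomalous
diffraction (SAD) experiment.

## The problem

SAD phasing determines macromolecular crystal structures from the tiny
intensity differences between Bijvoet mates F(h,k,l) and F(−h,−k,−l) caused
by anomalous scatterers (Se, S, metals).  Whether an experiment will succeed
hinges on two questions: how *accurate* the measured anomalous differences
are, and how much *total information per substructure site* they carry.
`sadsignal` implements two metrics that answer them, and the closed form
that ties them together:

* **CC_ano**, the *useful anomalous correlation* — the Pearson correlation
  between the observed anomalous differences ΔF = F⁺ − F⁻ and the ideal
  differences of a model in which the only anomalous scatterers are the
  substructure atoms.
* **S_ano**, the *anomalous signal* — the mean height of a model-phased
  anomalous difference Fourier map (coefficients ΔF·e^{i(φc − π/2)}) at the
  substructure coordinates, in units of the map rms.
* The prediction

      S_ano = CC_ano · √(N_refl / n_sites) / f_B

  where N_refl is the number of unique acentric reflections, n_sites the
  number of unique substructure sites, and f_B = rms⟨f″e^{−Bs²}⟩ /
  mean⟨f″e^{−Bs²}⟩ ≥ 1 the second moment of the B-attenuated anomalous
  scattering factors over the data.  With perfect data (CC_ano = 1) this
  reduces to √(N_refl/n_sites)/f_B, and for a single site with B = 0 to the
  hard ceiling √N_refl.  Writing the error budget per site,
  S_ano = √(N_refl / (n_sites + e²)) / f_B with E² = e²/n_sites and
  CC_ano = 1/√(1+E²).

The anomalous signal maps onto an empirical probability of solving the
substructure (a logistic calibration crossing 50% at S_ano ≈ 9), making the
formula usable for planning: given cell, resolution, site count, f″ and B,
you can bound the signal before collecting a single image.

The package contains a full synthetic-data path — crystal generator, exact
direct-summation Bijvoet pairs, Gaussian measurement noise with a target E²
— so every statement above is verifiable end to end against ground truth.

## Worked example

```python
import sadsignal as ss

config = ss.SimulationConfig(seed=7)   # 50 Å P1 cell, d_min 2.5 Å, 4 Se sites,
                                       # 1200 light atoms, 1% amplitude noise
dataset = ss.simulate(config)
report = ss.estimate_signal(dataset.reflections, dataset.model,
                            ss.SolvabilityCalibration())
```

which prints (via `python examples/simulate_and_estimate.py`):

```
unique acentric Bijvoet pairs N_refl : 16700
substructure sites n_sites           : 4
useful anomalous correlation CC_ano  : 0.9394
second moment f_B                    : 1.1056
S_ano predicted  (closed form)       : 54.90
S_ano measured   (difference Fourier): 54.28
P(substructure solvable)             : 1.000
```

The closed-form prediction (54.9) and the value actually measured from the
anomalous difference Fourier (54.3) agree to about 1%; both sit far above
the ≈9 threshold at which half of real SAD experiments succeed, so this
simulated data set would be trivially solvable.

The `examples/` directory holds one short script per capability:
simulation + estimation, experiment planning, the √N and 1/√n_sites scaling
laws, a resolution-truncation scan, and the solvability curve.  A thin CLI
wraps the same functions:

```
sadsignal simulate --out sim
sadsignal estimate --reflections sim.csv --model sim.pdb --fprime -3 --fdprime 3.8
sadsignal scan --reflections sim.csv --model sim.pdb --d-min 2.5 --d-min 3 --d-min 4
sadsignal predict --d-min 2.8 --n-sites 8 --fdprime 3.8 --b-factor 45
```

Reflections travel as MTZ or a documented CSV dialect
(`h,k,l,d,centric,Fplus,sigFplus,Fminus,sigFminus`); models as PDB.

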