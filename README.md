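# soilntrace

Gross soil nitrogen transformation rates from paired ¹⁵N labelling
incubations, for soil biogeochemists studying how land use shapes the
nitrogen cycle.

Net rate measurements cannot separate simultaneous production and consumption
of NH₄⁺ and NO₃⁻. The ¹⁵N pool-dilution approach can: one treatment receives
¹⁵NH₄NO₃, a parallel treatment NH₄¹⁵NO₃, and the joint time course of pool
sizes and ¹⁵N enrichments resolves the one-directional ("gross") rates.
`soilntrace` implements the full numerical workflow around that design:

- **Forward model** — five pools (NH₄⁺, NO₃⁻, labile organic N *N_lab*,
  recalcitrant organic N *N_rec*, adsorbed NH₄⁺) connected by ten
  simultaneously occurring processes: mineralization *M_Nlab*, *M_Nrec*;
  NH₄⁺ immobilization *I_NH4_Nlab*, *I_NH4_Nrec*; adsorption/release
  *A_NH4*, *R_NH4*; autotrophic nitrification *O_NH4*; heterotrophic
  nitrification *O_Nrec*; DNRA *D_NO3*; NO₃⁻ immobilization *I_NO3*.
  Each process runs with zero-order, first-order or Michaelis–Menten
  kinetics; every flux carries the ¹⁵N atom fraction of its source pool.
- **Calibration** — a random-walk Metropolis sampler minimizes/samples the
  weighted misfit J = Σ[(modelled − observed)/sd]² over concentrations and
  atom%-excess of both inorganic pools in both treatments jointly, with
  J read as −2 log likelihood (acceptance exp(−ΔJ/2), AIC = J + 2p).
- **Reporting** — 48-h average gross rates (1/T)∫₀ᵀ flux dt per process with
  posterior uncertainties, AIC ranking of kinetic variants, derived indices
  (nitrification capacity O_NH4/M_N, NO₃⁻ retention capacity
  (I_NO3+D_NO3)/(O_NH4+O_Nrec), O_NH4/I_NH4), cohort t tests and Pearson
  correlations, and annual runoff NO₃⁻ loss Q = Σ Cᵢ·qᵢ/100 (kg N ha⁻¹ yr⁻¹).
- **Synthetic data** — generators for the full incubation design (20 mg N kg⁻¹
  amendments at 9.44/9.75 atom% excess, sampling at 0.5/12/24/48 h, three
  replicates) and for a two-land-use soil cohort (11 forestland, 8 cropland)
  with realistic property/rate contrasts, so the whole pipeline is testable
  from known ground truth.

## Worked example

Simulate a cropland-like soil at known gross rates, add measurement noise,
and re-estimate the rates by MCMC:

```python
from soilntrace import fit_tracer_model
from soilntrace.synthetic_data import (
    land_use_truth, generate_tracer_dataset, design_for, recovery_structure,
)
from soilntrace.indices import derive_indices

truth = land_use_truth("cropland")          # M_N 4.84, I_NH4 0.34, O_NH4 14.54
obs, stored = generate_tracer_dataset(truth, seed=7)
structure = recovery_structure()
fit = fit_tracer_model(
    structure, structure.default_parameters(fit_n_lab=False),
    design_for(truth), obs, n_chains=3, n_iter=30000, seed=7,
)
rates = fit.gross_rates(n_draws=400)
print(rates.as_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

prints (about 40 s on one CPU):

```
   process   rate    sd
    M_Nlab  0.000 0.000
    M_Nrec  4.828 0.050
I_NH4_Nlab  0.000 0.000
I_NH4_Nrec  0.505 0.124
     A_NH4  0.000 0.000
     R_NH4  0.000 0.000
     O_NH4 14.379 0.126
    O_Nrec  0.000 0.000
     D_NO3  0.111 0.038
     I_NO3  0.746 0.397
       M_N  4.828 0.050
     I_NH4  0.505 0.124
```

The posterior-mean 48-h average rates (mg N kg⁻¹ day⁻¹, ± posterior sd)
recover the generating truth: total mineralization M_N 4.83 vs 4.84,
autotrophic nitrification O_NH4 14.38 vs 14.54, and the weakly identified
small rates with honest wide uncertainties. The derived indices for this soil
follow directly:

```python
idx = derive_indices(rates, nh4_conc=truth.nh4, no3_conc=truth.no3)
# nitrification capacity  O_NH4/M_N = 2.98
# NO3- retention capacity (I_NO3+D_NO3)/(O_NH4+O_Nrec) = 0.060
```

— the high-nitrification, low-retention fingerprint of a fertilized cropland
Regosol.

A command-line interface wraps the same steps
(`soilntrace synth | simulate | fit | rates | indices | flux | run`); e.g.

```bash
soilntrace synth --seed 1 --out demo/
soilntrace fit --obs demo/observations.csv --seed 1 --out demo/fit/
soilntrace flux --events demo/events.csv --out demo/q.csv
```

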