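# Methods

## Model

The tracer model tracks five nitrogen pools — NH₄⁺, NO₃⁻, labile organic N,
recalcitrant organic N, and exchange-site-adsorbed NH₄⁺ — each as a pair
(total N in mg N kg⁻¹ dry soil, absolute ¹⁵N atom fraction). Ten processes
connect them (see `model_core.PROCESS_TOPOLOGY`); each is assigned zero-order
(flux = k, mg N kg⁻¹ d⁻¹), first-order (flux = k·S, k in d⁻¹) or
Michaelis–Menten kinetics (flux = vmax·S/(km+S)) on its source pool S.

Assumptions:

- **Closed system.** No gaseous losses and no leaching during the 48-h
  incubation; total N and total ¹⁵N are conserved exactly (this is also the
  main numerical regression check — conservation holds to ~1e-14 relative).
- **Source-fraction routing, no fractionation.** Every flux carries the
  instantaneous ¹⁵N atom fraction of its source pool — the standard
  pool-dilution assumption. Kinetic isotope fractionation is negligible at
  tracer-level enrichments against ~9 atom%-excess labels.
- **Constant environment.** The incubation runs at fixed temperature and
  moisture, so no environmental response functions appear; rate parameters
  are those of the incubated soil.
- **Natural abundance is fixed at 0.3663 atom% ¹⁵N** (atmospheric N₂
  standard). All "atom% excess" (APE) values are relative to this constant.

Initial conditions: the inorganic pools are soil background plus 20 mg N kg⁻¹
amendment each, with atom fractions given by amount-weighted mixing of
natural-abundance soil N and the labelled (9.44 APE ¹⁵NH₄NO₃ treatment /
9.75 APE NH₄¹⁵NO₃ treatment) or unlabelled amendment species. Organic pools
start at natural abundance; adsorbed NH₄⁺ starts at 0 (no defensible
independent estimate exists, and the A/R pair equilibrates quickly);
recalcitrant organic N closes the total-N balance
(N_rec = TN·1000 − N_lab − NH₄⁺ − NO₃⁻). The initial labile organic N is a
fittable parameter (default bounds 0–200 mg N kg⁻¹), following common
practice for this model family.

## Integration

Fixed-step classical 4th-order Runge–Kutta, default step 0.001 d, time in
days internally (hour-valued inputs converted on read). Within every step the
total outgoing flux of each pool is clipped so it cannot exceed the pool's
stock over the step — the physical substrate limit that makes zero-order
kinetics well-posed at exhaustion. Sub-femtogram negative excursions at
exhaustion are zeroed; anything below −1e−6 mg N kg⁻¹ or non-finite aborts
with an error naming the failing time. Per-process flux time-integrals are
accumulated trapezoidally on the integration grid; 48-h average gross rates
are these integrals divided by the horizon.

The misfit evaluated inside MCMC uses a 0.01 d grid: the RK4 global error at
these rate scales (k ≲ 3 d⁻¹) is ~(k·h)⁴ ≈ 1e−9 relative, orders of
magnitude below measurement noise, and the coarser grid is what makes a
90,000-evaluation fit take tens of seconds rather than tens of minutes.
Final rate reporting re-integrates posterior draws on the 0.001 d grid.
Halving the default step changes outputs by <1e−6 relative (tested).

## Calibration

Both labelling treatments are fitted jointly with one shared parameter set
per soil — that is what the paired design is for. The fitting targets are
the per-(treatment, time, pool) replicate means ± standard deviations of
concentration and APE, combined as

J(θ) = Σ [(predicted − mean)/sd]²,

interpreted as −2 log likelihood up to a constant (independent Gaussians
with known sds). This fixes a coherent triple: Metropolis acceptance
min(1, exp(−ΔJ/2)), uniform-box prior via bound rejection, and
AIC = J_best + 2p (AICc available as a flag). SD floors —
max(0.05 mg N kg⁻¹, 2% of mean) for concentrations, 0.02 APE for
enrichments — guard against infinite weights from zero replicate variance;
missing sds are replaced by the floors.

Sampler defaults: 3 chains × 30,000 iterations, first 50% burn-in,
per-parameter proposal sd = scale × bound width with the scale adapted every
200 iterations toward 20–45% acceptance during burn-in only (frozen
afterwards, preserving detailed balance for retained draws). The adapted
scale is clamped to [1e−5, 0.5]: an unclamped scale can collapse to zero and
freeze a chain inside a poor mode. Each chain's random start is first
improved by a short bounded Nelder–Mead descent, and chains whose
post-burn-in median J exceeds the best chain's median by more than 20 (on
the −2 log-likelihood scale, i.e. an e⁻¹⁰ likelihood ratio) are flagged
unconverged and excluded from the pooled posterior; all chains remain
inspectable on the result object. Reported point estimate is the posterior
mean; uncertainty is the posterior sd.

Identical (seed, data, config) gives bit-identical chains.

## Identifiability

Four sampling times × 2 pools × 2 treatments × 2 observable kinds give 64
residual terms. The full ten-process network is not identifiable from them
(notably the adsorption/release pair); parameter-recovery studies therefore
use a reduced five-process structure — M_Nrec zero-order carrying total
mineralization, I_NH4_Nrec, O_NH4, I_NO3 and D_NO3 first-order — which is
well identified. A rate is treated as *identifiable* when its true 48-h
average is ≥1 mg N kg⁻¹ d⁻¹; smaller rates (e.g. cropland I_NH4 = 0.34,
which moves the NH₄⁺ pool by ~0.7 mg over 48 h, below the 3% concentration
noise) are estimated and reported with their wide posteriors but not held to
point-accuracy checks.

## Synthetic data generator

`generate_tracer_dataset` simulates both treatments at known parameters and
draws per-record replicates (default 3) with Gaussian noise — concentration
cv 0.03, APE sd 0.05 absolute, truncated at the physical bounds (0 for
concentrations, −natural abundance for APE) — emitting replicate means ± sds,
the shape real distillation/IRMS data arrive in. The defaults are stated
assumptions: no instrument error model is published for this design.

`generate_cohort` draws 11 forestland + 8 cropland soils. Soil properties
(pH, SOC, TN, NH₄⁺, NO₃⁻) are Gaussian around the study-area group means
with per-soil sds reconstructed as SE·√n from the reported group standard
errors (cross-checked against the reported ranges); draws ≤0 are redrawn (at
most 100 attempts); C/N is recomputed as SOC/TN, never drawn independently.
Rate targets (M_N, I_NH4, O_NH4, O_Nrec, I_NO3, D_NO3) are drawn
*lognormally* with exact arithmetic means: a truncated Gaussian would bias
low-mean/high-sd rates (forestland O_NH4: 1.99 ± 1.86) upward by ~25%.
Within each group, I_NH4 couples positively and O_NH4 negatively to the
soil's SOC z-score (|ρ| = 0.6), so cohort-level Pearson signs reproduce the
field pattern; I_NO3, D_NO3, O_Nrec and M_N carry no built-in land-use
difference. Aggregate targets are split evenly over their component
processes; the adsorption pair runs at fixed small rate constants.

True kinetic parameters are back-solved from the drawn 48-h average-rate
targets by deterministic Gauss–Seidel with Brent root-finding on the 1-D
k → average-rate map per process (zero-order processes with unexhausted
substrate are exact in one assignment). A closed amended incubation caps any
consuming process at its substrate supply: average O_NH4 cannot exceed
(initial NH₄⁺ + 48 h of mineralization + DNRA)/2 ≈ 16 mg N kg⁻¹ d⁻¹ for
cropland-like soils, so upper-tail draws (roughly 2 of 19 soils per cohort)
are supply-capped at a rate constant of 50 d⁻¹; each soil stores both its
drawn targets (used for cohort statistics, which are therefore mean-exact)
and the rates its parameters actually achieve. Cohort truths are solved to a
2% relative tolerance — well inside the 3% measurement noise — because
Gauss–Seidel converges slowly when a capped nitrification stiffens the NH₄⁺
competition; the deterministic reference truths used in recovery studies
converge to 1e−5.

What the generator does *not* emulate: spatial slope-position structure,
within-field heterogeneity, replicate-level correlations between pools
measured on the same extract, drift or calibration error in the isotope
measurements, and any rainfall–runoff dynamics (the runoff event table is a
toy fixture). Passing tests therefore demonstrate the estimator's behaviour
under the stated noise model, not under every failure mode of real
incubation data.

## Statistics

Group contrasts use the two-sided independent-samples t test (equal-variance
by default, Welch optional) between land uses, with a Kolmogorov–Smirnov
normality check attached per group — implemented as the Lilliefors variant
since group moments are estimated from the data (the table needs n ≥ 4;
smaller groups get no verdict). Normality is reported but never gates the
t test. Relationships use Pearson product-moment correlation with two-sided
p values. Undefined ratios (zero denominators) are NaN-flagged and excluded
pairwise, never imputed. No multiple-testing correction is applied.

Degenerate edge: when both groups have zero within-group variance and equal
means, the t statistic is reported as 0 with p = 1 (the no-evidence reading
of a no-variation dataset).

## Runoff flux

Annual NO₃⁻ loss is Q = Σ Cᵢ·qᵢ/100 over monitored runoff events, with Cᵢ in
mg L⁻¹, qᵢ (discharge depth) in mm, and the literal /100 converting
mg L⁻¹·mm to kg ha⁻¹. Interflow and overland pathways are stored separately
and summed; a whole-catchment weir series is its own pathway label.
Discharge must be supplied as depth (mm) for every pathway, including
weir-gauged catchments (volume normalized by catchment area upstream of this
package).

## Problem sizes used in the validation studies

Conservation: 100 random parameterizations of the full ten-process model,
nine output times over 48 h. Sampler calibration: 5 seeds × 50,000
iterations on the 1-D quadratic misfit (a standard-normal posterior), with
batch-means standard errors. Parameter recovery: 5 seeds per land-use truth,
each fit 3 chains × 30,000 iterations; coverage counted per identifiable
rate across seeds. Kinetic-form selection: 20 low-noise replicates
(cv 0.005, APE sd 0.01), each fitted with first- and zero-order O_NH4
variants (2 chains × 3,000 iterations plus a Nelder–Mead polish of the best
draw before AIC). Cohort statistics: 20 cohort seeds at the default
11 + 8 design. These sizes hold the complete validation run to a few minutes
on one CPU while leaving every pass/fail margin wide.

## Known limitations

- The full ten-process model is provided for simulation and structure
  exploration, but only reduced structures should be fitted to a single
  4-time-point dual-label experiment; the package deliberately does not try
  to regularize an unidentifiable fit.
- Random-walk Metropolis with box bounds is the calibration method by
  design; posteriors with strong curved ridges would mix slowly. The chain
  filter removes clearly non-converged chains but is no substitute for
  inspecting chains on real data.
- Fitting replicate means weighted by replicate sds (n = 3) makes weights
  themselves noisy; the sd floors bound, but do not remove, this effect.
- The supply cap means cohort rate *parameters* cannot represent average
  nitrification rates beyond the closed-system ceiling, although drawn
  target rates (used for statistics) can exceed it.
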