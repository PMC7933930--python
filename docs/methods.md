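# Methods

This note records the models behind each module, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical choices that matter. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data and the noise model

Every generator is driven by a `GeneratorConfig` (seed, noise CV,
replicate count, optional grids) and returns the data together with a
truth dictionary, so recovery tests compare against recorded — never
re-derived — ground truth. A fixed seed reproduces byte-identical output.

Noise is multiplicative log-normal with the configured coefficient of
variation and unit mean (`σ² = ln(1+CV²)`, location `−σ²/2`). This is the
plate-reader-like choice: fluorescence and LC-MS readouts scale with
signal, and the mean-one construction keeps noisy data unbiased around the
model curve. Default grids follow the stated assay conditions where the
protocol fixes them (hepatocyte depletion sampled at 0/20/40/60/120/240
min at 0.5×10⁶ cells/ml; 1 °C/min thermal ramps; 5 nM analyte in the
polymerisation end-point assay); elsewhere (dilution ladders, dose
ladders, competitor titrations) they are ordinary 3-fold or log-spaced
designs a screening lab would use. Replicate/noise structure is not
published for any of these assays, so CVs (1–3% depending on assay) are
package defaults, chosen once as typical plate-reader variability.

What the generators deliberately do **not** emulate: plate-layout and
edge effects, instrument drift, non-equilibrium immunoassay kinetics,
heteroscedastic LC-MS calibration error, or biological between-animal
variability. Passing recovery tests therefore demonstrate estimator
correctness and noise robustness under idealised error, not robustness to
structured real-world artefacts.

## Binding kinetics

Progress curves are fitted to `F(t) = baseline + amplitude·e^(−k_obs t)`
by least squares, initialised from a log-linearisation of the first/last
quartiles (tolerances 1e-10, max 10 000 evaluations). A trace whose
apparent amplitude is within 3σ of the local noise floor (estimated from
lag-1 differences) raises a distinct no-signal error rather than a fit
failure. `k_on` is the unweighted OLS slope of `k_obs` against compound
concentration — unweighted because per-point variances are not modelled; a
weighted option can be layered on the same interface. A negative slope is
flagged but the result is retained for inspection.

`k_off = k_on·10^(−pKD)` is computed from the independently measured
affinity, exactly as stated; the identity
`log10 k_off = log10 k_on − pKD` holds to machine precision.

Half-times `t½ = ln2 / k_obs` carry a "faster than dead time" flag at the
10 s dead time of manual-mixing fluorimetry. The flag is advisory: the
stopped-flow concentration-series traces used for `k_on` regression have
millisecond dead times and sub-10-s half-times by design, so the kinetics
pipeline does not auto-exclude flagged traces; callers analysing
manual-mixing variant comparisons should.

## Competition binding

The receptor–tracer–competitor system is solved exactly. Mass balance in
free receptor,

    R_t = R_f · (1 + L_t/(K_L + R_f) + C_t/(K_C + R_f)),

is monotone in `R_f` on `[0, R_t]` and always brackets the unique physical
root, so Brent's method converges unconditionally — no cubic-discriminant
case analysis, no approximation at high receptor occupancy. An infinite Kd
encodes a non-binding species (the polymeric conformer). Conservation and
both Kd relations hold to better than 1e-9 relative; an independent damped
fixed-point oracle confirms this on 1 000 random instances in the tests.

Competition curves are fitted for pKD with the exact model evaluated at
every point. Plateau signals are fitted by default because polarization
units are instrument-specific; the assay constants (receptor 10 nM, tracer
2 nM, tracer Kd 5 nM) are declared synthetic defaults — the physical
assay's concentrations are not published, so recovery is always against
the declared constants. Curves with under 20% of the signal window raise a
no-displacement error instead of returning a meaningless pKD.

## Sandwich immunoassay and deconvolution

The four-antibody sandwich (primary + labelled secondary each side) is
collapsed to an effective two-antibody model: secondaries are in excess at
the published concentrations, so the limiting primary totals define the
effective capture/detection totals. Polymer is modelled in subunit
equivalents, one epitope per subunit per antibody class. For each
antibody, free concentration solves single-site conservation over all
epitopes (bracketed root), and the signal is
`background + scale·Σ_s [s]·p_cap(s)·p_det(s)`. This reproduces the two
asymptotic regimes — linear at trace analyte, `1/analyte` in the hook
regime — and gives exactly one interior maximum versus dilution whenever a
species binds both sides.

Peak finding uses a quadratic in log-dilution around the grid argmax. The
default is the exact 3-point interpolation (best on noiseless curves,
error O(h²) in the grid spacing); for noisy plate data a least-squares
window of ±3 points averages readout noise at the cost of a small
systematic shift, and the window is an explicit argument everywhere. Ties
break toward lower dilution; edge maxima raise a no-interior-peak error.

Calibration regresses the log peak *dilution fraction* (1/factor) on log
concentration; dilution invariance of the equilibrium model makes the
theoretical slope −1 (the analyte concentration at the peak is a property
of the assay alone), and doubling a sample's concentration doubles its
peak dilution factor. The calibration also stores the pooled ascending
branch of net signal versus in-well concentration, anchored at the
interpolated peak.

Deconvolution of monomer given the polymer-assay result offers two
methods. The default, `peak_inversion`, reads the *combined* analyte
concentration off the total-assay peak position and subtracts the polymer
in concentration space. When the total assay binds both conformers with
the same affinity (the default configuration — shared anti-total
antibodies), signal depends only on the summed subunit concentration and
this inversion is exact; it is also well-conditioned, because peak
position moves linearly with concentration while the signal *value* at a
maximum is stationary. The alternative `signal_subtraction` follows the
classical recipe — subtract the polymer's predicted net signal at the
sample's peak dilution and invert the residual through the monomer
calibration. Because antibody depletion couples the species,
single-species signal curves are sub-additive at the mixture peak and this
route systematically underestimates monomer; the bias is quantified in the
test suite rather than hidden.

Two idealisations are explicit. First, the polymer-specific assay is by
default fully polymer-specific: in the physical assay the polyclonal
detection antibody binds every conformer, so abundant monomer silently
depletes it and shifts the polymer-assay peak; `polymer_assay(
detection_sees_monomer=True)` enables that cross-reactivity for bias
studies. Second, the polyclonal's molar concentration is unpublished
(given only as a dilution), so detection-side totals are configuration
constants.

4PL fitting uses `y = bottom + (top−bottom)/(1+(x/XC50)^h)` with free
plateaus by default; `fix_top`/`fix_bottom` anchor them for responses
already normalised to controls (percent-of-control inhibition), which
substantially reduces the variance of midpoint estimates on short dose
ladders. Fitted midpoints outside the dosed range are flagged. The
maximal fold effect of an ascending (secretion-type) curve is reported as
the ratio of the high-dose to low-dose plateau, resolved through the
fitted Hill sign.

## Stability and stoichiometry

Three-state unfolding uses Boltzmann-weighted fractions of N, I, U with
linear free-energy dependence `ΔG_i(D) = ΔG_i − m_i·D` at RT = 0.5925
kcal/mol (25 °C), computed in a max-subtracted form so normalisation is
exact. The intermediate-occupancy maximum has the closed form
`D* = (ΔG1 + ΔG2 + RT·ln(m1/m2)) / (m1+m2)` (from d fI/dD = 0 ⇔
K1K2 = m1/m2), which both the generator (truth records the analytic peak)
and the fitter (peak of the fitted surface) use; `params_for_peak` places
midpoints symmetrically about a requested peak. The dye response is
intermediate-weighted with optional linear N/U baselines — the bis-ANS
readout reports the intermediate and published profiles are normalised, so
baselines default to zero and the published fit equation (not printed) is
not assumed. m-value defaults (3 and 2 kcal/mol/M) are typical for a
~45 kDa two-domain unfolding problem.

Thermal-shift midpoints come from a Boltzmann sigmoid; temperature
dependence of ΔG across the ramp is not modelled because the readout is
used comparatively (ΔTm between apo and ligand-bound).

SI titrations regress residual activity on molar ratio within the
activity band [0.1, 0.9] — avoiding the upper plateau and the zero-
activity censoring — and report the x-intercept. Percent activity loss is
`100·(1 − SI_ref/SI_treated)`, 100% in the limit of a fully inactivated
serpin.

## Pharmacokinetics

The in vivo model is one-compartment oral PK with quasi-equilibrium
target binding: total drug partitions as
`C_t = C_f/fu_ns + S·C_f/(K_d + C_f)` (solved by the numerically stable
quadratic branch; closed-form inverse; round trip to 1e-12), and both
absorption-driven input and clearance `CLu·C_f` act on the amount ODE,
with free concentration recomputed algebraically at every step. The
quasi-equilibrium simplification (rather than full kinetic TMDD) matches
the available description of the sink — a capacity and an affinity, with
no binding rate constants — and the interface isolates the sink so a
kinetic variant can replace it. Sink defaults are 5 µM capacity and 1.5 nM
affinity, the circulating Z α1-antitrypsin pool.

Doses are gut boluses of `F·dose` at the regimen times (default three
daily at 8-h intervals), integrated with LSODA at rtol 1e-9 between dose
events. The mouse disposition parameters are **not** published; the
defaults (ka 1.5 h⁻¹, V 3 L/kg, CLu 15 L/h/kg referenced to free drug,
fu_ns 0.12, F 0.5, MW 450) are plausible for a lipophilic acid-like small
molecule and were chosen once so that the simulated 10/30/100 mg/kg TID
regimens reproduce the qualitative dose pattern the in vivo study
describes: free drug pinned far below the 300 nM cellular EC50 at 10
mg/kg, intermediate coverage at 30, and at-or-above-EC50 for the majority
of the interval only at 100 mg/kg. No claim is made to reproduce measured
blood concentrations. The 300 nM threshold is configuration-level and
corresponds to the hepatocyte-model secretion EC50 (pEC50 6.5).

NCA uses the linear-up/log-down trapezoid over the final interval.
Intrinsic clearance scales the depletion slope through
`CLint/10⁶cells = |k|/density·10⁶` and a hepatocellularity of 120×10⁶
cells/g — a standard scaling constant, exposed in the interface and shared
between generator and fitter so recovery is self-consistent. TDI is the
ratio IC50(0 min)/IC50(pre-incubated), ≥ 1 when pre-incubation intensifies
inhibition.

## Pipeline, I/O, and reproducibility

All tables are CSV with declared column schemas and fixed
12-significant-digit float formatting (byte-stable round trips); ground
truth and results are JSON. `RunConfig` (pydantic, unknown keys rejected)
drives `run_pipeline`, which logs seed, config hash and package version;
per-scenario failures are recorded in the bundle, and only infrastructure
errors raise. All randomness derives from one integer seed through
spawned 31-bit substreams, so bundles are bit-reproducible.

Problem sizes throughout (traces of 200–500 points, 5–20 seed replicates
per recovery, dilution ladders of 46–433 points, 6-day PK at 10 samples/h)
were chosen as the smallest designs at which the estimators are
comfortably inside their documented tolerances; the full recovery preset
runs in well under a minute on one core.

## Known limitations

- The deconvolution's exactness guarantee rests on conformer-equivalence
  in the total assay; epitope masking in polymers would violate it and is
  only representable through per-species Kds.
- The PK model has no liver compartment and no first-pass term, so it
  cannot represent portal-exposure effects; disposition parameters are
  illustrative defaults, not estimates.
- Printed dissociation rate constants in the source campaign derive from
  unpublished per-experiment affinities; `derive_koff` implements the
  defining identity and makes no attempt to reproduce those exact values.
- The SI regression assumes the titration is linear between the activity
  bounds; strongly curved titrations (partial-loop-insertion mechanisms)
  would need a different estimator.
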