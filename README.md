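# a1atkit

Quantitative analysis toolkit for small-molecule *corrector* campaigns
against Z α1-antitrypsin deficiency — the misfolding disease in which the
Glu342Lys (Z) variant of α1-antitrypsin polymerises in hepatocytes instead
of being secreted. A corrector binds a cryptic pocket on the monomer,
blocks polymerisation, and restores secretion; characterising such a
molecule requires a specific set of quantitative assays, and this package
implements the analysis layer for all of them, together with seeded
synthetic-data generators with known ground truth for every assay type.

## What it computes

| capability | module | model |
|---|---|---|
| association kinetics | `a1atkit.kinetics` | pseudo-first-order `k_obs = k_on·[C] + k_off`; exponential trace fits; `k_off = k_on·10^-pKD`; selectivity `10^(pKD_a − pKD_b)` |
| competition binding | `a1atkit.equilibrium` | exact ternary R+L+C mass-action equilibrium (bracketed root in free receptor); FP signal affine in bound-tracer fraction; nonlinear fit of pKD |
| sandwich TR-FRET / hook effect | `a1atkit.immunoassay` | per-antibody single-site depletion; bell-shaped signal-vs-dilution curves; peak-position calibration (log-log slope −1); monomer/polymer deconvolution |
| potency | `a1atkit.immunoassay` | 4PL `y = bottom + (top−bottom)/(1+(x/XC50)^h)`, free or anchored plateaus |
| conformational stability | `a1atkit.stability` | three-state N⇌I⇌U unfolding, ΔG_i(D) = ΔG_i − m_i·D; closed-form intermediate peak `D* = (ΔG1+ΔG2+RT·ln(m1/m2))/(m1+m2)`; Boltzmann Tm |
| inhibitory stoichiometry | `a1atkit.stability` | SI from the x-intercept of the residual-activity titration |
| pharmacokinetics | `a1atkit.pk` | one-compartment oral PK with a saturable circulating sink (quasi-equilibrium TMDD, 5 µM / 1.5 nM); NCA; hepatocyte CL_int scaling; CYP TDI IC50 shift |
| data generation | `a1atkit.synthetic` | every assay above, with mean-one multiplicative log-normal noise and a JSON-able truth record |

## Worked example

Each script in `examples/` builds a small synthetic input, runs one
capability, and prints what it finds. For instance:

```bash
$ python examples/01_association_kinetics.py
Z protein: kon = 4.18e+04 M^-1 s^-1 (truth 4.1e+04), derived koff = 0.00013 s^-1
M protein: kon = 214 M^-1 s^-1 (truth 2.1e+02), derived koff = 3.4e-05 s^-1
Affinity selectivity Z over M: 50-fold
```

The Z-variant rate constant is ~200-fold larger than wild-type M while the
derived off-rates are of the same order: the compound's preference for the
disease variant is driven by association, consistent with a binding pocket
that is more accessible in the polymerisation-prone conformer.

```bash
$ python examples/06_pk_sink_simulation.py
steady-state day 6, TID at 8-h intervals:
     10 mg/kg: total Cmax   6.86 uM, free at Cmax   227.71 nM, free >= 300 nM for   0% of the interval
     30 mg/kg: total Cmax  11.02 uM, free at Cmax   724.22 nM, free >= 300 nM for  39% of the interval
    100 mg/kg: total Cmax  25.35 uM, free at Cmax  2442.42 nM, free >= 300 nM for  66% of the interval
```

The ~5 µM circulating target acts as a high-affinity sink: below its
capacity free drug is pinned to nanomolar levels, and only the highest dose
keeps free drug at or above the 300 nM cellular secretion EC50 for most of
the dosing interval.

A thin CLI mirrors the common operations
(`a1at simulate|fit|pk|acceptance`).

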