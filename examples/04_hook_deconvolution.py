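"""Hook-effect deconvolution: monomer vs polymer in a plasma-like sample.

Sandwich TR-FRET signal collapses at high analyte (the hook effect), so
signal-vs-dilution curves are bell-shaped and the peak position scales with
the analyte concentration.  Polymer is quantified with the polymer-specific
assay; its contribution is then removed from the total assay to give the
monomer concentration - the readout used to demonstrate target engagement
in vivo.
"""

import numpy as np

from a1atkit import immunoassay as ia
from a1atkit import synthetic as syn

dilutions = np.logspace(0, 4.5, 109)  # 24 points per decade
pol_assay = ia.polymer_assay()
tot_assay = ia.total_assay()
stocks = [0.25e-6, 0.5e-6, 1e-6, 2e-6, 4e-6, 8e-6, 16e-6]

cal_pol = ia.calibrate_peaks(
    syn.gen_calibration_standards(pol_assay, stocks[:-1], "polymer", dilutions,
                                  syn.GeneratorConfig(seed=1)),
    background=pol_assay.background)
cal_tot_mono = ia.calibrate_peaks(
    syn.gen_calibration_standards(tot_assay, stocks, "monomer", dilutions,
                                  syn.GeneratorConfig(seed=2)),
    background=tot_assay.background)
cal_tot_pol = ia.calibrate_peaks(
    syn.gen_calibration_standards(tot_assay, stocks, "polymer", dilutions,
                                  syn.GeneratorConfig(seed=3)),
    background=tot_assay.background)
print(f"calibration: log-log peak slope {cal_pol.slope:.3f} (theory -1)")

# a plasma-like sample: mostly polymer before treatment, monomer rises 7x after
pre = ia.SpeciesMix(monomer=1e-6, polymer=2e-6)
post = ia.SpeciesMix(monomer=7e-6, polymer=2e-6)
for name, mix in (("pre-dose", pre), ("post-dose", post)):
    ps, _ = syn.gen_dilution_series(mix, pol_assay, dilutions,
                                    syn.GeneratorConfig(seed=11, noise_cv=0.02))
    ts, _ = syn.gen_dilution_series(mix, tot_assay, dilutions,
                                    syn.GeneratorConfig(seed=12, noise_cv=0.02))
    p_est, _ = ia.quantify_polymer(ps, cal_pol, peak_window=3)
    m_est, _ = ia.deconvolve_monomer(ts, p_est, cal_tot_pol, cal_tot_mono,
                                     peak_window=3)
    print(f"{name}: polymer {p_est*1e6:.2f} uM (truth {mix.polymer*1e6:.1f}), "
          f"monomer {m_est*1e6:.2f} uM (truth {mix.monomer*1e6:.1f})")
print("-> the monomer rise is recovered even though no antibody distinguishes"
      " monomer directly; it is inferred from the two peak positions.")
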