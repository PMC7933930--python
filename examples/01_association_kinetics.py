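"""Association kinetics: kobs per trace, kon from the concentration series.

Simulates stopped-flow quenching traces for the fast-associating Z protein
and the slow-associating wild-type M protein, fits each progress curve to a
single exponential, and regresses kobs on compound concentration to get the
second-order association rate constant kon.  The derived koff = kon * Kd
uses the affinity from the competition assay.
"""

import numpy as np

from a1atkit import kinetics as kin
from a1atkit import synthetic as syn

for variant, concs in (("Z", [2.5e-6, 5e-6, 10e-6, 20e-6]),
                       ("M", [10e-6, 20e-6, 40e-6, 80e-6])):
    sc = syn.scenario(variant)
    truth = {"kon": sc["kon"], "koff": kin.derive_koff(sc["kon"], sc["pKD"])}
    cfg = syn.GeneratorConfig(seed=1, noise_cv=0.02)
    traces, _ = syn.gen_association_traces(truth, concs, cfg)
    kobs = [kin.fit_single_exponential(t).kobs for t in traces]
    res = kin.fit_kon(kobs, concs)
    koff = kin.derive_koff(res.kon, sc["pKD"])
    print(f"{variant} protein: kon = {res.kon:.3g} M^-1 s^-1 "
          f"(truth {sc['kon']:.2g}), derived koff = {koff:.2g} s^-1")

fold = kin.selectivity_fold(syn.Z_PKD, syn.M_PKD)
print(f"Affinity selectivity Z over M: {fold:.0f}-fold")
print("-> the compound prefers the disease variant almost entirely through"
      " a faster on-rate; off-rates are of the same order.")
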