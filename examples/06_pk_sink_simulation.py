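"""Oral TID pharmacokinetics against a saturable circulating target sink.

The circulating target (~5 uM, Kd 1.5 nM) sequesters drug until it
saturates, so free drug rises much more than dose-proportionally across
10/30/100 mg/kg three-times-daily regimens.  The question the simulation
answers: for how much of the dosing interval does free drug stay at or
above the 300 nM cellular secretion EC50?
"""

from a1atkit import pk

params = pk.PKParams()       # one-compartment oral defaults
sink = pk.SinkParams()       # 5 uM circulating sink, Kd 1.5 nM

print("in vitro anchors:")
from a1atkit import synthetic as syn

series, _ = syn.gen_depletion_series({"CLint_per_g": syn.MOUSE_CLINT},
                                     cfg=syn.GeneratorConfig(seed=1, noise_cv=0.01))
res = pk.clint_from_depletion(series)
print(f"  mouse hepatocyte CLint = {res.CLint_per_g:.2f} ml/min/g "
      f"(t1/2 {res.t_half:.0f} min)")

print("steady-state day 6, TID at 8-h intervals:")
for dose in (10.0, 30.0, 100.0):
    prof = pk.simulate_tid_pk(params, sink, pk.DoseRegimen(dose=dose, duration=6.0))
    metrics = pk.nca(prof, pk.DoseRegimen(dose=dose))
    frac = pk.fraction_interval_above(prof, 3e-7, which="free")
    i = prof.total.argmax()
    print(f"  {dose:5.0f} mg/kg: total Cmax {metrics['Cmax']*1e6:6.2f} uM, "
          f"free at Cmax {prof.free[i]*1e9:8.2f} nM, "
          f"free >= 300 nM for {frac:4.0%} of the interval")
print("-> only the top dose keeps free drug above the cellular EC50 for most"
      " of the interval; below sink saturation free drug is pinned to nM levels.")
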