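"""Suboptimal flux variability analysis and measured-flux containment.

Runs FVA with the growth objective held at 90% of its optimum — the setting
used when confronting model predictions with measured intracellular fluxes —
normalizes the intervals to the substrate uptake in percent, and checks
whether a hypothetical measured flux falls inside its predicted band.
"""

from megaflux import (
    fva,
    interval_contains,
    make_branched_toy,
    normalize_to_reference,
    solve_fba,
)

model = make_branched_toy()
uptake = solve_fba(model).fluxes["EX_A"]  # -10: uptake is negative by convention

bands = fva(model, fraction=0.9)
percent = normalize_to_reference(dict(bands.intervals), reference=uptake)
print("flux intervals as % of substrate uptake (objective >= 90% of optimum):")
for rid, (lo, hi) in sorted(percent.items()):
    print(f"  {rid:8s} [{lo:8.2f}, {hi:8.2f}]")
# R1 spans [90, 100]: at least 90% of the carbon must feed growth, the rest
# may divert to the product branch R2 (its band is [0, 10]).

measured = 9.5  # a measured flux, mmol/gDW/h
print(f"measured R1 flux {measured} inside the 90% band:",
      interval_contains(bands, "R1", measured))
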