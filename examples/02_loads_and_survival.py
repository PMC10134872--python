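"""From a plasmid standard curve to microbiota loads and kill rates.

Fits Ct = intercept + slope*log10(copies), converts sample Cts to copy
numbers, scales them to copies per mL with the extraction bookkeeping, and
summarises treated-vs-control survival.
"""

from viamet import (
    ct_to_copies,
    fit_standard_curve,
    mean_killed_percent,
    microbiota_load,
    survival_percent,
)

# Plasmid dilution series (log10 copies, observed Ct)
points = [(3, 27.1), (4, 23.8), (5, 20.4), (6, 17.1), (7, 13.8)]
curve = fit_standard_curve(points)
print(f"slope={curve.slope:.3f}  E={curve.efficiency:.3f}  R^2={curve.r_squared:.4f}")

# Mean Ct of each saliva sample's universal-16S triplicate -> copies per mL.
# 1 uL of a 50-uL eluate from 1 mL of saliva, no predilution.
samples = {"host1_control": 12.1, "host1_treated": 13.5}
loads = {}
for name, ct in samples.items():
    copies = ct_to_copies(ct, curve)
    loads[name] = microbiota_load(copies, 1.0, 50.0, 1.0, "per_mL", sample_id=name)
    print(f"{name:15s} Ct={ct:5.2f} -> {loads[name].copies_per_unit:.3e} copies/mL")

surv = survival_percent(loads["host1_treated"], loads["host1_control"])
print(f"treated load = {surv}% of control")

# Across three hosts the printed per-host survivals aggregate to a mean
# dead/injured percentage of the whole community:
print("mean killed:", mean_killed_percent([39.8, 44.7, 36.3]), "%")
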