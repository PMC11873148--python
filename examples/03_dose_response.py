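"""Fit a 4PL dose-response curve and compute control-normalized EC50 ratios.

Simulates a triplicate dose series at an ATR-inhibitor-like potency
(EC50 1.936 µM), refits it, then reproduces the published potency ratios
from the bundled mean-EC50 table.
"""

from drugscreen import fit_4pl, relative_ec50
from drugscreen.datasets import load_t24_ec50_table
from drugscreen.simulate import DoseResponseSimConfig, gen_dose_response

records, truth = gen_dose_response(DoseResponseSimConfig(n_doses=8), seed=5)
fit = fit_4pl(records["dose_uM"], records["viability_pct"])
print(f"true EC50 {truth['ec50'][0]:.3f} uM -> fitted {fit.ec50:.3f} uM "
      f"(hill {fit.hill:.2f}, asymptotes {fit.lower:.1f}-{fit.upper:.1f} %)")
print("The fitted EC50 is the dose at the curve's asymptote midpoint; at 5-point")
print("viability noise it typically lands within ~10 % of the generating truth.")
print()

tab = load_t24_ec50_table().rename(columns={"ec50_mean_uM": "ec50_uM"})
tab["replicate"] = 1
for drug in ("Berzosertib", "PI-103"):
    ratios = relative_ec50(tab[tab.drug == drug], "Control A6")
    pooled = ratios[ratios.replicate == "pooled"].set_index("cell_line")["ratio"]
    parts = ", ".join(f"{line}: {r:.2f}" for line, r in pooled.items())
    print(f"{drug}: {parts}")
print()
print("A ratio below 1 means the line is more sensitive than control: STAG2 loss")
print("sensitizes to the ATR inhibitor (0.53/0.40) but protects against the")
print("PI3K inhibitor (ratios above 1).")
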