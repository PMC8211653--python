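"""Quantify a dual-luciferase end-joining reporter dose-response.

Simulates NanoLuc/Firefly well pairs over a 10-point 3-fold dilution from
12 uM (NanoLuc reports microhomology-mediated repair of the transfected
substrate; Firefly reports cell density and transfection efficiency),
normalizes, and fits the cellular EC50.
"""

import numpy as np

from assaykit import fit_4pl, tmej_activity
from assaykit.simulate import GeneratorConfig, gen_reporter

reporter, truth = gen_reporter(150e-9, config=GeneratorConfig(seed=6))
act = tmej_activity(reporter)
doses = act[~act["is_dmso"]]
fit = fit_4pl(doses["conc_molar"], doses["activity"])

print(f"DMSO wells: median activity {np.median(act.loc[act['is_dmso'], 'activity']):.3f} (=1 by construction)")
per_dose = doses.groupby("conc_molar")["activity"].mean()
for c, a in per_dose.items():
    print(f"  {c * 1e6:8.4f} uM -> repair activity {a:.3f}")
print(f"\ntrue EC50:   {truth['xc50'] * 1e9:.0f} nM")
print(f"fitted EC50: {fit.xc50 * 1e9:.0f} nM  (hill {fit.hill:.2f})")
print(
    "\nActivity is NanoLuc/Firefly scaled to the DMSO median, so 1.0 = full\n"
    "end-joining repair capacity and the EC50 is the compound concentration\n"
    "halving repair of the reporter substrate in cells."
)
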