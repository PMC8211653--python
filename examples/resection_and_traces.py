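"""Resection ssDNA% from qPCR Ct pairs, plus recruitment and apoptosis traces.

Three small cell-assay quantifications: (1) percent ssDNA at a cut-site-
adjacent locus from digested vs mock-digested qPCR reactions, (2) a
laser-microirradiation recruitment trace normalized to same-nucleus
background, (3) live-cell apoptosis fraction from caspase-green and
confluence areas.
"""

import numpy as np

from assaykit import apoptosis_fraction, recruitment_curve, resection_ssdna
from assaykit.simulate import GeneratorConfig, gen_resection

# 1. resection: higher ssDNA% = more nucleolytic end-resection at the break
ct, truth = gen_resection([5.0, 12.0, 30.0], site_ids=["siCON", "siBRCA1", "siBRCA1+si53BP1"], config=GeneratorConfig(seed=7))
res = resection_ssdna(ct["ct_digested"], ct["ct_mock"], site_id=ct["site_id"])
print("resection at the cut-site-adjacent locus:")
for _, r in res.iterrows():
    print(f"  {r['site_id']:>16}: dCt {r['delta_ct']:+.2f} -> ssDNA {r['ssdna_pct']:.1f}%")

# 2. recruitment: ratio > 1 means protein accumulates at the damage site
t = np.arange(0.0, 241.0, 3.0)
ratio_true = 1 + 0.8 * (1 - np.exp(-t / 30.0))
bleach = np.exp(-0.002 * t)  # common photobleaching cancels in the ratio
res2 = recruitment_curve(t, 100 * ratio_true * bleach, 100 * bleach, summary=True)
print(f"\nrecruitment: plateau ratio {res2.plateau:.2f}, half-rise at {res2.t_half:.0f} s")

# 3. apoptosis fraction over a 48 h live-cell run
hours = np.arange(0, 49, 2)
confluence = 20 + hours
green = 0.5 + 0.15 * hours
apo = apoptosis_fraction(confluence, green)
print(f"apoptosis%: {apo[0]:.1f}% at 0 h -> {apo[-1]:.1f}% at 48 h")
print(
    "\nssDNA% rises when resection is unleashed (e.g. BRCA1+53BP1 loss);\n"
    "a recruitment plateau ~1.8x background with ~21 s half-rise indicates\n"
    "rapid, stable accumulation at damage; the apoptosis trace is the green\n"
    "caspase area as a share of occupied area at each timepoint."
)
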