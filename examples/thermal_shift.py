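"""Extract thermal-shift (DSF) Tm values and compound-induced shifts.

Simulates 20 -> 99 C melt ramps for protein +/- DNA +/- a DNA-dependent
stabilizer over a 10-point dose series, extracts each Tm as the derivative
inflection, and tabulates delta-Tm against the matched DMSO references.
"""

from assaykit import delta_tm
from assaykit.simulate import GeneratorConfig, gen_melt

melt, truth = gen_melt(
    tm_protein=48.0, dna_bonus=2.0, dtm_max=3.0, dna_dependent=True,
    config=GeneratorConfig(seed=5),
)
shifts = delta_tm(melt)

print("delta-Tm (C) vs matched DMSO reference:")
for with_dna, label in ((True, "+DNA"), (False, "-DNA")):
    sub = shifts[shifts["with_dna"] == with_dna].sort_values("conc_nM")
    doses = ", ".join(f"{c / 1000:.2g}uM:{d:+.2f}" for c, d in zip(sub["conc_nM"], sub["delta_tm"]))
    print(f"  {label}: {doses}")

print(
    "\nA saturating, dose-responsive stabilization that appears only in the\n"
    "+DNA rows means the compound binds (and thermally stabilizes) the\n"
    "protein-DNA complex, not the apo protein -- consistent with the\n"
    "uncompetitive kinetics in examples/inhibition_modality.py."
)
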