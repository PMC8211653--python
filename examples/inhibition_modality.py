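"""Classify an inhibitor's mechanism of action from progress-curve grids.

Simulates quenched time-course grids (6 timepoints, 8 substrate x 7 inhibitor
levels) for an inhibitor that is uncompetitive with respect to DNA and
noncompetitive with respect to dNTPs, extracts initial rates, and globally
fits the four steady-state rate laws.
"""

import numpy as np

from assaykit import apparent_ic50, classify_modality, initial_rates
from assaykit.simulate import GeneratorConfig, gen_progress_grid

for grid, modality, substrate in (
    ("dna_grid", "uncompetitive", "DNA (nM)"),
    ("dntp_grid", "noncompetitive", "dNTP (uM)"),
):
    prog, truth = gen_progress_grid(modality, grid=grid, config=GeneratorConfig(seed=4))
    rates = initial_rates(prog)
    fit = classify_modality(rates)
    p = fit.params[fit.winner]
    print(f"varied substrate {substrate}: generated {modality}")
    print(
        f"  winner: {fit.winner}  (margin to rival law: {fit.delta_aicc:.1f} AICc)\n"
        f"  Vmax {p['vmax']:.1f} signal/min, Km {p['km']:.2f}, Ki {p['ki']:.2f} nM"
    )
    s_lo, s_hi = rates["substrate_conc"].min(), rates["substrate_conc"].max()
    ic = apparent_ic50(np.array([s_lo, s_hi]), km=p["km"], ki=p["ki"], modality=fit.winner)
    print(f"  apparent IC50 from S={s_lo:g} to S={s_hi:g}: {ic[0]:.1f} -> {ic[1]:.1f} nM\n")

print(
    "Uncompetitive inhibition (apparent IC50 falling with substrate) means the\n"
    "inhibitor binds the enzyme-DNA complex rather than competing with DNA --\n"
    "the signature of an allosteric site; noncompetitive behaviour vs dNTPs\n"
    "(flat apparent IC50) means it does not contest the nucleotide site either."
)
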