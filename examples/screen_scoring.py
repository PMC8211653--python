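"""Score a simulated drug-vs-vehicle siRNA chemosensitization screen.

Simulates a triplicate 1418-siRNA screen with five spiked sensitizers
(drug-specific log2 effect -2), runs plate-median normalization, Drug Effect
scoring and MAD Z-standardization, and calls hits at Z < -2.
"""

import numpy as np

from assaykit import plate_median_normalize, score_screen, screen_qc
from assaykit.simulate import GeneratorConfig, gen_screen

spiked = [f"siRNA_{i:04d}" for i in (77, 312, 640, 1001, 1400)]
wells, truth = gen_screen(
    1418,
    GeneratorConfig(seed=1),
    effects={s: (0.0, -2.0) for s in spiked},
)
results = score_screen(wells)
qc = screen_qc(plate_median_normalize(wells))

print(f"wells simulated: {len(wells)}, siRNAs scored: {len(results)}")
print(f"plates passing control QC: {(~qc['flagged']).sum()}/{len(qc)}")
print(f"hits at Z < -2: {results['hit'].sum()}")
print("\nstrongest sensitizers (most negative DE Z):")
print(results.head(8).to_string(index=False, float_format=lambda v: f"{v:.3f}"))
recovered = set(results.loc[results["hit"], "perturbation_id"]) & set(spiked)
print(f"\nspiked sensitizers recovered: {len(recovered)}/5")
print(
    "A DE score is the log2 viability change the drug adds on top of the siRNA\n"
    "alone; Z standardizes against the screen median/MAD, so Z < -2 reads\n"
    "'at least two MADs more sensitizing than the typical siRNA'. The ~9% of\n"
    "null siRNAs crossing the threshold is the expected false-positive load of\n"
    "an unscaled-MAD cutoff; spiked true effects rank far below them:",
)
print(results[results["perturbation_id"].isin(spiked)][["perturbation_id", "de", "de_z"]].to_string(index=False))
print(f"\nmedian null |Z|: {np.median(np.abs(results['de_z'])):.2f} (MAD-standardized, so ~1 by construction)")
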