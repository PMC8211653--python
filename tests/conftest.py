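import numpy as np
import pandas as pd
import pytest

from assaykit.simulate import GeneratorConfig


@pytest.fixture
def cfg0():
    """Noiseless generator config (exact-recovery paths)."""
    return GeneratorConfig(seed=11, cv=0.0, ct_sd=0.0)


@pytest.fixture
def cfg():
    """Default-noise generator config (5% CV, 0.15-cycle Ct SD)."""
    return GeneratorConfig(seed=11)


def make_plate(
    lib_signals,
    *,
    plate_id="P1",
    arm="drug",
    replicate=1,
    neg_signals=(),
    pos_signals=(),
    start_id=1,
):
    """Hand-built single screen plate in the `screen` schema."""
    rows = "ABCDEFGHIJKLMNOP"
    recs = []
    for i, s in enumerate(lib_signals):
        recs.append(
            dict(
                plate_id=plate_id,
                row=rows[i % 16],
                col=1 + i // 16,
                role="library",
                perturbation_id=f"siRNA_{start_id + i:04d}",
                arm=arm,
                replicate=replicate,
                signal=float(s),
            )
        )
    for j, s in enumerate(neg_signals):
        recs.append(
            dict(
                plate_id=plate_id,
                row=rows[j],
                col=24,
                role="negative_control",
                perturbation_id="siCONTROL",
                arm=arm,
                replicate=replicate,
                signal=float(s),
            )
        )
    for j, s in enumerate(pos_signals):
        recs.append(
            dict(
                plate_id=plate_id,
                row=rows[12 + j],
                col=24,
                role="positive_control",
                perturbation_id="siKILL",
                arm=arm,
                replicate=replicate,
                signal=float(s),
            )
        )
    return pd.DataFrame(recs)


@pytest.fixture
def two_arm_plate():
    """Matched drug/vehicle single-replicate plates with a known sensitizer."""
    drug = make_plate([500.0, 1000.0, 2000.0, 1000.0, 1000.0])
    veh = make_plate([1000.0, 1000.0, 2000.0, 1000.0, 1000.0], arm="vehicle")
    return pd.concat([drug, veh], ignore_index=True)


def boltzmann_curve(tm, temps=None, *, width=1.5, amp=1000.0, floor=100.0, slope=2.0):
    """Noise-free sigmoid melt curve with known midpoint."""
    T = np.arange(20.0, 99.0 + 1e-9, 0.5) if temps is None else np.asarray(temps, float)
    F = floor + slope * (T - T[0]) + amp / (1.0 + np.exp((tm - T) / width))
    return T, F
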