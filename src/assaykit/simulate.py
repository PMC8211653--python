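"""Seeded synthetic-data generators emulating each assay's statistical structure.

Every generator is a deterministic function of its parameters and a
:class:`GeneratorConfig` seed, returns its measurements in the matching CSV
schema (round-trippable through :func:`assaykit.plates.read_measurements`),
and returns its ground truth alongside the data so parameter-recovery tests
can consume only the measurement table and compare afterwards.

Defaults encode the experimental designs the generators emulate: 384-well
screen plates carrying 368 library + 12 negative-control + 4 positive-control
wells, triplicate screens over a 1418-siRNA library, 10-point half-log
dilutions from 120 or 12 uM and 10-point 3-fold dilutions from 12 uM,
mechanism-of-action grids (DNA 200 -> 1.563 nM and dNTP 10 -> 0.078125 uM
two-fold; inhibitor 50 -> 1.563 nM plus DMSO; quenches at 0/5/15/30/45/60
min) and a 20 -> 99 C melt ramp.  Assay noise defaults to multiplicative
log-normal with 5% CV for plate-reader signals and additive SD 0.15 cycles
for qPCR Ct values — typical instrument behaviour.

The single config seed fans out to a named substream per assay, so adding one
generator call never shifts another generator's draws.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cellassays import delta_ct_for_ssdna
from .doseresponse import four_pl
from .enzymology import MODALITIES, modality_rate
from .plates import ROWS_384, ValidationError

__all__ = [
    "GeneratorConfig",
    "concentration_scheme",
    "gen_screen",
    "gen_dose_response",
    "gen_reporter",
    "gen_progress_grid",
    "gen_rate_table",
    "gen_melt",
    "gen_resection",
    "DNA_GRID_NM",
    "DNTP_GRID_UM",
    "INHIBITOR_GRID_NM",
    "TIMEPOINTS_MIN",
]

#: Mechanism-of-action grids: varied-substrate and inhibitor concentrations.
DNA_GRID_NM = (200.0, 100.0, 50.0, 25.0, 12.5, 6.25, 3.125, 1.563)
DNTP_GRID_UM = (10.0, 5.0, 2.5, 1.25, 0.625, 0.3125, 0.15625, 0.078125)
INHIBITOR_GRID_NM = (50.0, 25.0, 12.5, 6.25, 3.125, 1.563, 0.0)
TIMEPOINTS_MIN = (0.0, 5.0, 15.0, 30.0, 45.0, 60.0)

_LIB_WELLS_PER_PLATE = 368  # 384 minus 12 negative + 4 positive control wells


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared generator settings: seed, noise model and magnitudes.

    ``noise_model='lognormal_cv'`` multiplies signals by a mean-one
    log-normal factor with coefficient of variation ``cv``;
    ``'additive_gaussian'`` adds zero-mean Gaussian noise with SD
    ``cv * signal mean``.  ``ct_sd`` is the additive SD (cycles) on simulated
    qPCR Ct values.  ``effect_table`` optionally maps perturbation id ->
    (vehicle log2 effect, drug-specific log2 effect) for the screen
    generator.
    """

    seed: int = 0
    noise_model: str = "lognormal_cv"
    cv: float = 0.05
    ct_sd: float = 0.15
    effect_table: Mapping[str, tuple[float, float]] | None = field(default=None)

    def __post_init__(self):
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")
        if self.noise_model not in ("lognormal_cv", "additive_gaussian"):
            raise ValidationError("noise_model must be 'lognormal_cv' or 'additive_gaussian'")


def _stream(config: GeneratorConfig, name: str) -> np.random.Generator:
    """Independent, named, reproducible random substream."""
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % 2**31, zlib.crc32(name.encode())])
    )


def _noise_factor(rng: np.random.Generator, config: GeneratorConfig, n: int) -> np.ndarray:
    """Mean-one multiplicative log-normal factors with CV = config.cv."""
    if config.cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(config.cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))


def _apply_noise(rng: np.random.Generator, config: GeneratorConfig, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if config.noise_model == "lognormal_cv":
        return values * _noise_factor(rng, config, values.size).reshape(values.shape)
    scale = config.cv * float(np.mean(np.abs(values))) if values.size else 0.0
    return values + rng.normal(0.0, scale, size=values.shape)


def log2_sd_to_cv(sd_log2: float) -> float:
    """CV of the log-normal noise model that yields the given SD on the log2 scale."""
    return math.sqrt(math.exp((sd_log2 * math.log(2)) ** 2) - 1.0)


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------


def _plate_layout() -> list[tuple[str, int, str]]:
    """(row, col, role) for one 384-well screen plate.

    Columns 1-23 hold library wells (row-major); column 24 holds 12 negative
    controls (rows A-L) and 4 positive controls (rows M-P).
    """
    layout = [(r, c, "library") for r in ROWS_384 for c in range(1, 24)]
    layout += [(r, 24, "negative_control") for r in ROWS_384[:12]]
    layout += [(r, 24, "positive_control") for r in ROWS_384[12:]]
    return layout


def gen_screen(
    n_sirnas: int = 1418,
    config: GeneratorConfig | None = None,
    *,
    effects: Mapping[str, tuple[float, float]] | None = None,
    n_replicates: int = 3,
    baseline: float = 10_000.0,
    kill_fraction: float = 0.1,
    plate_factor_range: tuple[float, float] = (0.7, 1.3),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a drug-vs-vehicle siRNA chemosensitization screen.

    Library siRNAs (``siRNA_0001`` ...) fill 384-well plates at 368 library
    wells per plate; unused positions on the last plate become ``empty``
    wells.  Each (arm, replicate, plate) gets its own multiplicative baseline
    factor drawn from ``U(plate_factor_range)`` so plate-median normalization
    is genuinely exercised.  Positive-control wells (a transfection control
    killing most cells) read ``kill_fraction`` of baseline.

    ``effects`` (or ``config.effect_table``) maps siRNA id ->
    ``(vehicle_log2, drug_log2)``: the vehicle effect applies in both arms,
    the drug-specific effect only in the drug arm, so a spiked sensitizer
    with drug effect -2 has pipeline DE exactly -2 at cv = 0.

    Returns ``(wells, truth)``: wells in the ``screen`` schema, truth with
    one row per siRNA (``perturbation_id, vehicle_log2, drug_log2``).
    """
    config = config or GeneratorConfig()
    if n_sirnas < 1:
        raise ValidationError("n_sirnas must be >= 1")
    effects = dict(effects if effects is not None else (config.effect_table or {}))
    ids = [f"siRNA_{i + 1:04d}" for i in range(n_sirnas)]
    unknown = set(effects) - set(ids)
    if unknown:
        raise ValidationError(f"effect assigned to unknown perturbation(s): {sorted(unknown)[:5]}")
    veh = np.array([effects.get(i, (0.0, 0.0))[0] for i in ids])
    drg = np.array([effects.get(i, (0.0, 0.0))[1] for i in ids])

    layout = _plate_layout()
    n_plates = math.ceil(n_sirnas / _LIB_WELLS_PER_PLATE)
    rng_plate = _stream(config, "screen.plate")
    rng_noise = _stream(config, "screen.noise")

    recs: list[dict] = []
    for arm in ("drug", "vehicle"):
        for rep in range(1, n_replicates + 1):
            for p in range(n_plates):
                pf = rng_plate.uniform(*plate_factor_range)
                plate_id = f"P{p + 1:02d}"
                lib_slot = 0
                means, meta = [], []
                for row, col, role in layout:
                    if role == "library":
                        i = p * _LIB_WELLS_PER_PLATE + lib_slot
                        lib_slot += 1
                        if i >= n_sirnas:
                            meta.append((row, col, "empty", ""))
                            means.append(0.0)
                            continue
                        eff = veh[i] + (drg[i] if arm == "drug" else 0.0)
                        meta.append((row, col, "library", ids[i]))
                        means.append(baseline * pf * 2.0**eff)
                    elif role == "negative_control":
                        meta.append((row, col, role, "siCONTROL"))
                        means.append(baseline * pf)
                    else:
                        meta.append((row, col, role, "siKILL"))
                        means.append(baseline * pf * kill_fraction)
                signals = _apply_noise(rng_noise, config, np.asarray(means))
                signals = np.maximum(signals, 0.0)
                for (row, col, role, pid), sig in zip(meta, signals):
                    recs.append(
                        dict(
                            plate_id=plate_id,
                            row=row,
                            col=col,
                            role=role,
                            perturbation_id=pid,
                            arm=arm,
                            replicate=rep,
                            signal=0.0 if role == "empty" else float(sig),
                        )
                    )
    wells = pd.DataFrame(recs)
    truth = pd.DataFrame({"perturbation_id": ids, "vehicle_log2": veh, "drug_log2": drg})
    return wells, truth


# ---------------------------------------------------------------------------
# dose-response / reporter
# ---------------------------------------------------------------------------

_SCHEMES = {
    "halflog_120uM": (120e-6, 10.0**0.5),
    "halflog_12uM": (12e-6, 10.0**0.5),
    "threefold_12uM": (12e-6, 3.0),
}


def concentration_scheme(scheme: str, n_points: int = 10) -> np.ndarray:
    """Named dilution scheme -> descending molar concentrations.

    ``halflog_120uM`` / ``halflog_12uM``: 10-point half-log series from 120
    or 12 uM; ``threefold_12uM``: 10-point 3-fold series from 12 uM.
    """
    if scheme not in _SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; expected one of {sorted(_SCHEMES)} or pass custom concentrations")
    top, ratio = _SCHEMES[scheme]
    return top / ratio ** np.arange(n_points)


def gen_dose_response(
    truth: Mapping[str, float] | None = None,
    scheme: str = "halflog_12uM",
    *,
    n_replicates: int = 3,
    config: GeneratorConfig | None = None,
    compound_id: str = "CMPD-1",
    n_control_wells: int = 16,
    concentrations: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate a compound dilution series with on-plate controls.

    ``truth`` holds the generating 4PL parameters (``bottom, top, hill,
    xc50``; defaults: background 2500, uninhibited 50000, hill 1, midpoint
    10 nM).  Sample wells follow the named scheme; ``n_control_wells``
    uninhibited DMSO wells (role ``neg_ctrl``, concentration 0) and as many
    fully-inhibited wells (role ``pos_ctrl``) are included per replicate,
    as on a real 384-well potency plate.

    Returns ``(measurements, truth)`` with measurements in the
    ``dose_response`` schema.
    """
    config = config or GeneratorConfig()
    t = dict(bottom=2500.0, top=50_000.0, hill=1.0, xc50=10e-9)
    t.update(truth or {})
    conc = concentration_scheme(scheme) if concentrations is None else np.asarray(concentrations, dtype=float)
    rng = _stream(config, f"dose_response.{compound_id}.{scheme}")
    recs = []
    for rep in range(1, n_replicates + 1):
        mean = four_pl(conc, t["bottom"], t["top"], t["xc50"], t["hill"])
        sig = np.maximum(_apply_noise(rng, config, mean), 0.0)
        for c, s in zip(conc, sig):
            recs.append(dict(compound_id=compound_id, concentration_molar=c, replicate=rep, signal=s, role="sample"))
        for role, level in (("neg_ctrl", t["top"]), ("pos_ctrl", t["bottom"])):
            ctrl = np.maximum(_apply_noise(rng, config, np.full(n_control_wells, level)), 0.0)
            for s in ctrl:
                recs.append(dict(compound_id=compound_id, concentration_molar=0.0, replicate=rep, signal=s, role=role))
    return pd.DataFrame(recs), t


def gen_reporter(
    ec50: float = 150e-9,
    *,
    hill: float = 1.0,
    top_activity: float = 1.0,
    bottom_activity: float = 0.05,
    scheme: str = "threefold_12uM",
    n_replicates: int = 4,
    n_dmso: int = 16,
    firefly_mean: float = 20_000.0,
    firefly_cv: float = 0.15,
    nano_per_firefly: float = 2.0,
    config: GeneratorConfig | None = None,
    compound_id: str = "CMPD-1",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate a dual NanoLuc/Firefly end-joining reporter dose series.

    Per-well Firefly signals vary log-normally (``firefly_cv``, emulating
    seeding/transfection differences); the NanoLuc signal is Firefly times a
    4PL repair activity with midpoint ``ec50`` plus assay noise, so the
    Firefly normalization in :func:`assaykit.cellassays.tmej_activity` must
    cancel the per-well variation before the dose-response is recoverable.
    DMSO wells (``is_dmso=True``, concentration 0, activity 1) provide the
    final normalization reference.
    """
    config = config or GeneratorConfig()
    conc = concentration_scheme(scheme)
    rng = _stream(config, f"reporter.{compound_id}")
    truth = dict(bottom=bottom_activity, top=top_activity, hill=hill, xc50=ec50)
    sigma_ff = math.sqrt(math.log1p(firefly_cv**2))
    recs = []
    for rep in range(1, n_replicates + 1):
        activity = four_pl(conc, bottom_activity, top_activity, ec50, hill)
        ff = firefly_mean * np.exp(rng.normal(-0.5 * sigma_ff**2, sigma_ff, size=conc.size))
        nano = np.maximum(_apply_noise(rng, config, ff * nano_per_firefly * activity), 0.0)
        for c, f, n in zip(conc, ff, nano):
            recs.append(dict(compound_id=compound_id, conc_molar=c, replicate=rep, nano=n, firefly=f, is_dmso=False))
    ff = firefly_mean * np.exp(rng.normal(-0.5 * sigma_ff**2, sigma_ff, size=n_dmso))
    nano = np.maximum(_apply_noise(rng, config, ff * nano_per_firefly * top_activity), 0.0)
    for f, n in zip(ff, nano):
        recs.append(dict(compound_id="DMSO", conc_molar=0.0, replicate=1, nano=n, firefly=f, is_dmso=True))
    return pd.DataFrame(recs), truth


# ---------------------------------------------------------------------------
# mechanism-of-action grids
# ---------------------------------------------------------------------------

_DEFAULT_KINETICS = {
    "dna_grid": dict(vmax=100.0, km=50.0, ki=10.0, alpha=1.0),
    "dntp_grid": dict(vmax=100.0, km=1.25, ki=10.0, alpha=1.0),
}


def _grid_axes(grid: str) -> tuple[np.ndarray, np.ndarray, str]:
    if grid == "dna_grid":
        return np.array(DNA_GRID_NM), np.array(INHIBITOR_GRID_NM), "DNA"
    if grid == "dntp_grid":
        return np.array(DNTP_GRID_UM), np.array(INHIBITOR_GRID_NM), "dNTP"
    raise ValidationError("grid must be 'dna_grid' or 'dntp_grid'")


def gen_progress_grid(
    modality: str = "uncompetitive",
    params: Mapping[str, float] | None = None,
    grid: str = "dna_grid",
    *,
    config: GeneratorConfig | None = None,
    baseline: float = 200.0,
    n_replicates: int = 1,
    depletion_conversion: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a quenched progress-curve grid under one inhibition modality.

    ``signal(S, I, t) = baseline + v(S, I) * t`` in the default linear mode;
    with ``depletion_conversion = f`` the trace saturates first-order so that
    the stated fraction of substrate is converted by the final timepoint
    (initial slope still v, later points bend — the endpoint-analysis trap).
    Rates come from :func:`assaykit.enzymology.modality_rate` with ``params``
    (Vmax in signal/min, Km in grid substrate units, Ki in nM).

    Returns ``(measurements, true_rates)``: measurements in the ``progress``
    schema; truth with columns ``substrate_conc, inhibitor_nM, rate``.
    """
    config = config or GeneratorConfig()
    if modality not in MODALITIES:
        raise ValidationError(f"modality must be one of {MODALITIES}")
    S_axis, I_axis, substrate = _grid_axes(grid)
    p = dict(_DEFAULT_KINETICS[grid])
    p.update(params or {})
    rng = _stream(config, f"progress.{grid}.{modality}")
    k_dep = None
    if depletion_conversion is not None:
        if not 0 < depletion_conversion < 1:
            raise ValidationError("depletion_conversion must be in (0, 1)")
        k_dep = -math.log(1.0 - depletion_conversion) / TIMEPOINTS_MIN[-1]
    recs, truth = [], []
    for S in S_axis:
        for I in I_axis:
            v = float(modality_rate(S, I, modality=modality, **p))
            truth.append(dict(substrate_conc=S, inhibitor_nM=I, rate=v))
            for rep in range(1, n_replicates + 1):
                t = np.array(TIMEPOINTS_MIN)
                growth = v * t if k_dep is None else v * (1.0 - np.exp(-k_dep * t)) / k_dep
                sig = np.maximum(_apply_noise(rng, config, baseline + growth), 0.0)
                for ti, si in zip(t, sig):
                    recs.append(
                        dict(
                            varied_substrate=substrate,
                            substrate_conc=float(S),
                            inhibitor_nM=float(I),
                            time_min=float(ti),
                            replicate=rep,
                            signal=float(si),
                        )
                    )
    return pd.DataFrame(recs), pd.DataFrame(truth)


def gen_rate_table(
    modality: str = "uncompetitive",
    params: Mapping[str, float] | None = None,
    grid: str = "dna_grid",
    *,
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Rate table v(S, I) drawn directly from a rate law plus noise.

    Shortcut past the time-course layer for Monte-Carlo studies of the
    modality classifier alone.
    """
    config = config or GeneratorConfig()
    S_axis, I_axis, _ = _grid_axes(grid)
    p = dict(_DEFAULT_KINETICS[grid])
    p.update(params or {})
    rng = _stream(config, f"rates.{grid}.{modality}")
    Sg, Ig = np.meshgrid(S_axis, I_axis, indexing="ij")
    v = modality_rate(Sg.ravel(), Ig.ravel(), modality=modality, **p)
    v = np.maximum(_apply_noise(rng, config, v), 0.0)
    return (
        pd.DataFrame({"substrate_conc": Sg.ravel(), "inhibitor_nM": Ig.ravel(), "rate": v}),
        dict(p, modality=modality),
    )


# ---------------------------------------------------------------------------
# DSF melt curves
# ---------------------------------------------------------------------------


def gen_melt(
    tm_protein: float = 48.0,
    *,
    dna_bonus: float = 2.0,
    dtm_max: float = 3.0,
    dtm_ec50_nM: float = 300.0,
    dna_dependent: bool = True,
    concs_nM: np.ndarray | None = None,
    conditions: tuple[str, ...] = ("protein", "protein+DNA", "protein+compound", "protein+DNA+compound"),
    n_replicates: int = 4,
    temp_step: float = 0.5,
    config: GeneratorConfig | None = None,
    compound_id: str = "CMPD-1",
    width: float = 1.5,
    amplitude: float = 1000.0,
    floor: float = 100.0,
    pre_slope: float = 2.0,
    point_noise: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate DSF melt curves over the 20 -> 99 C ramp.

    Curves are Boltzmann sigmoids (midpoint = true Tm, ``width`` C) on a
    gently sloping baseline.  Melt-curve error is dominated by well-to-well
    gain differences, not point-to-point scatter, so each replicate curve gets
    one multiplicative log-normal gain factor (CV = ``config.cv``) plus small
    additive per-point read noise of SD ``point_noise * amplitude`` — the
    derivative-based Tm extraction is gain/offset invariant, so only the
    per-point term limits its precision.  The protein+DNA
    baseline melts ``dna_bonus`` C above apo protein.  The compound shifts Tm
    by a saturating dose term ``dtm_max * c / (c + dtm_ec50_nM)``, applied in
    +DNA conditions only when ``dna_dependent`` (a DNA-dependent stabilizer;
    set ``dtm_max=0`` for an inactive-isomer null).  A ``DNA``-only condition,
    if requested, yields a transition-free trace.

    Returns ``(measurements, truth)``: measurements in the ``melt`` schema,
    truth with true Tm per (condition, conc).
    """
    config = config or GeneratorConfig()
    if not 20.0 < tm_protein < 99.0:
        raise ValidationError("tm_protein must lie inside the 20-99 C ramp")
    temps = np.arange(20.0, 99.0 + 1e-9, temp_step)
    concs = (
        np.asarray(concs_nM, dtype=float)
        if concs_nM is not None
        else 12_000.0 / (10.0**0.5) ** np.arange(10)
    )
    rng = _stream(config, f"melt.{compound_id}")
    recs, truth = [], []

    def emit(condition: str, conc: float, true_tm: float | None):
        truth.append(dict(condition=condition, conc_nM=conc, tm=np.nan if true_tm is None else true_tm))
        for rep in range(1, n_replicates + 1):
            base = floor + pre_slope * (temps - temps[0])
            if true_tm is not None:
                base = base + amplitude / (1.0 + np.exp((true_tm - temps) / width))
            gain = _noise_factor(rng, config, 1)[0]
            pts = rng.normal(0.0, point_noise * amplitude, size=temps.size) if point_noise > 0 else 0.0
            sig = np.maximum(base * gain + pts, 0.0)
            for T, F in zip(temps, sig):
                recs.append(
                    dict(
                        condition=condition,
                        compound_id=compound_id if "compound" in condition else "",
                        conc_nM=conc,
                        temp_C=float(T),
                        fluorescence=float(F),
                        replicate=rep,
                    )
                )

    for condition in conditions:
        has_dna = "+DNA" in condition or condition == "DNA"
        if condition == "DNA":
            emit(condition, 0.0, None)
            continue
        base_tm = tm_protein + (dna_bonus if has_dna else 0.0)
        if "compound" in condition:
            for c in concs:
                shift = dtm_max * c / (c + dtm_ec50_nM) if (has_dna or not dna_dependent) else 0.0
                emit(condition, float(c), base_tm + shift)
        else:
            emit(condition, 0.0, base_tm)
    return pd.DataFrame(recs), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# resection qPCR
# ---------------------------------------------------------------------------


def gen_resection(
    true_ssdna_pct,
    *,
    config: GeneratorConfig | None = None,
    ct_mock_mean: float = 25.0,
    site_ids=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate digested/mock qPCR Ct pairs for given true ssDNA percentages.

    The true cycle difference is the exact inverse of the ssDNA%% formula,
    ``delta_ct = log2(100/pct - 0.5) + 1``; both Ct values then receive
    additive Gaussian noise of SD ``config.ct_sd`` cycles.  At ``ct_sd = 0``
    the measurement round-trips exactly.
    """
    config = config or GeneratorConfig()
    pct = np.atleast_1d(np.asarray(true_ssdna_pct, dtype=float))
    dct = np.atleast_1d(delta_ct_for_ssdna(pct))
    rng = _stream(config, "resection")
    sites = list(site_ids) if site_ids is not None else [f"site_{i + 1}" for i in range(pct.size)]
    if len(sites) != pct.size:
        raise ValidationError("site_ids must match true_ssdna_pct in length")
    ct_mock = ct_mock_mean + rng.normal(0.0, config.ct_sd, size=pct.size)
    ct_dig = ct_mock_mean + dct + rng.normal(0.0, config.ct_sd, size=pct.size)
    df = pd.DataFrame(
        {
            "site_id": sites,
            "sample_id": [f"S{i + 1}" for i in range(pct.size)],
            "ct_digested": ct_dig,
            "ct_mock": ct_mock,
        }
    )
    truth = pd.DataFrame({"site_id": sites, "ssdna_pct": pct, "delta_ct": dct})
    return df, truth
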