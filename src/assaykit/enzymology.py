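"""Steady-state inhibition kinetics and thermal-shift (DSF) melt analysis.

Mechanism-of-action experiments vary one substrate (primer/template DNA or
dNTPs) against an inhibitor dilution series and quench the reaction at fixed
timepoints.  This module extracts initial rates from those progress-curve
grids, globally fits the four classical steady-state rate laws

    competitive     v = Vmax*S / (Km*(1 + I/Ki) + S)
    uncompetitive   v = Vmax*S / (Km + S*(1 + I/Ki))
    noncompetitive  v = Vmax*S / ((Km + S)*(1 + I/Ki))
    mixed           v = Vmax*S / (Km*(1 + I/Ki) + S*(1 + I/(alpha*Ki)))

with shared (Vmax, Km, Ki[, alpha]) across the whole (S, I) table, and picks
the winning modality by small-sample corrected AIC.  A mixed fit whose alpha
is indistinguishable from 1 collapses to noncompetitive.  The apparent-IC50
trend with substrate (rising = competitive, falling = uncompetitive, flat =
noncompetitive) is available as a closed-form secondary diagnostic.

DSF melt curves are handled by :func:`melt_tm` (Tm = temperature of the first
derivative extremum of the locally smoothed fluorescence, i.e. the melting
inflection) and :func:`delta_tm` (compound-induced Tm shifts against matched
DMSO references, reported separately with and without DNA).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks, savgol_filter

from .plates import ValidationError

__all__ = [
    "MODALITIES",
    "modality_rate",
    "apparent_ic50",
    "initial_rates",
    "InhibitionFit",
    "classify_modality",
    "MeltTm",
    "melt_tm",
    "delta_tm",
]

MODALITIES = ("competitive", "uncompetitive", "noncompetitive", "mixed")


def modality_rate(S, I, *, vmax: float, km: float, ki: float, alpha: float = 1.0, modality: str):
    """Steady-state rate v(S, I) under one inhibition modality.

    ``km`` shares units with the varied substrate axis and ``ki`` with the
    inhibitor axis.  All four laws reduce to Michaelis-Menten at I = 0.
    """
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    if min(vmax, km, ki) <= 0 or alpha <= 0:
        raise ValidationError("kinetic parameters must be positive")
    if modality == "competitive":
        return vmax * S / (km * (1.0 + I / ki) + S)
    if modality == "uncompetitive":
        return vmax * S / (km + S * (1.0 + I / ki))
    if modality == "noncompetitive":
        return vmax * S / ((km + S) * (1.0 + I / ki))
    if modality == "mixed":
        return vmax * S / (km * (1.0 + I / ki) + S * (1.0 + I / (alpha * ki)))
    raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")


def apparent_ic50(S, *, km: float, ki: float, alpha: float = 1.0, modality: str):
    """Closed-form apparent IC50 versus substrate concentration.

    Derived from v(S, I50) = v(S, 0)/2: rises with S for competitive
    inhibition, falls for uncompetitive, and is constant (= Ki) for pure
    noncompetitive inhibition.
    """
    S = np.asarray(S, dtype=float)
    if modality == "competitive":
        return ki * (1.0 + S / km)
    if modality == "uncompetitive":
        return ki * (1.0 + km / S)
    if modality == "noncompetitive":
        return ki * np.ones_like(S)
    if modality == "mixed":
        return (km + S) / (km / ki + S / (alpha * ki))
    raise ValueError(f"unknown modality {modality!r}")


# ---------------------------------------------------------------------------
# initial rates from quenched progress curves
# ---------------------------------------------------------------------------


def _linear_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, its standard error, and R^2 of an ordinary least-squares line."""
    A = np.vstack([np.ones_like(t), t]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = A @ coef
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = max(t.size - 2, 1)
    denom = float(np.sum((t - t.mean()) ** 2))
    se = np.sqrt(ss_res / dof / denom) if denom > 0 else np.inf
    return float(coef[1]), se, r2


def initial_rates(
    progress: pd.DataFrame,
    *,
    r2_min: float = 0.98,
    min_points: int = 3,
) -> pd.DataFrame:
    """Initial velocities v(S, I) from a quenched time-course grid.

    For each (substrate, inhibitor) condition, replicate signals are averaged
    per timepoint, the t = 0 baseline is subtracted, and the rate is the
    least-squares slope over the *initial linear window*: the largest prefix
    of timepoints whose linear fit has R^2 >= ``r2_min`` (minimum
    ``min_points`` points).  Substrate depletion bends late timepoints off the
    line, so the window shrinks automatically where curvature appears.

    Flags: ``flat`` (no signal growth, v = 0), ``nonlinear`` (no prefix met
    the R^2 rule; the minimal window was used), ``nonmonotone`` (significantly
    negative slope).
    """
    required = {"substrate_conc", "inhibitor_nM", "time_min", "signal"}
    if not required.issubset(progress.columns):
        raise ValidationError(f"progress table must have columns {sorted(required)}")
    rows = []
    for (S, I), sub in progress.groupby(["substrate_conc", "inhibitor_nM"], sort=True):
        series = sub.groupby("time_min", sort=True)["signal"].mean()
        t = series.index.to_numpy(dtype=float)
        y = series.to_numpy(dtype=float)
        if t.size < min_points:
            raise ValidationError(f"condition (S={S}, I={I}) has only {t.size} timepoints")
        y = y - y[0]  # t=0 (earliest) baseline
        scale = max(abs(float(series.iloc[0])), 1.0)
        if np.allclose(y, 0.0, atol=1e-9 * scale):
            rows.append(dict(substrate_conc=S, inhibitor_nM=I, rate=0.0, n_points_used=t.size, r2=np.nan, flag="flat"))
            continue
        chosen = None
        for k in range(t.size, min_points - 1, -1):
            slope, se, r2 = _linear_fit(t[:k], y[:k])
            if r2 >= r2_min:
                chosen = (k, slope, se, r2, "")
                break
        if chosen is None:
            slope, se, r2 = _linear_fit(t[:min_points], y[:min_points])
            chosen = (min_points, slope, se, r2, "nonlinear")
        k, slope, se, r2, flag = chosen
        if slope < 0 and np.isfinite(se) and abs(slope) > 2 * se:
            flag = "nonmonotone"
        rows.append(dict(substrate_conc=S, inhibitor_nM=I, rate=slope, n_points_used=k, r2=r2, flag=flag))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# global modality fitting / model selection
# ---------------------------------------------------------------------------


@dataclass
class InhibitionFit:
    """Global fit of the inhibition-modality model family to a rate table."""

    params: dict[str, dict[str, float]]
    rss: dict[str, float]
    aicc: dict[str, float]
    winner: str
    delta_aicc: float
    collapsed_from_mixed: bool = field(default=False)


def _aicc(rss: float, n: int, k: int, rss_floor: float) -> float:
    # k counts fitted parameters + 1 for the residual variance.  rss is floored
    # at numerical precision so that nested models fitting noiseless data
    # equally well are separated by the parameter penalty, not by meaningless
    # ~1e-26 residual differences.
    k = k + 1
    aic = n * np.log(max(rss, rss_floor) / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = np.inf
    return float(aic)


def _fit_one_modality(S, I, v, modality: str) -> tuple[dict[str, float], float] | None:
    """Best least-squares fit (log-parameterized for positivity) or None."""
    vmax0 = max(float(np.max(v)), 1e-9) * 1.1
    km0 = float(np.median(S))
    pos_I = I[I > 0]
    ki_starts = [float(np.exp(np.mean(np.log(pos_I))))] if pos_I.size else [1.0]
    if pos_I.size:
        ki_starts += [float(pos_I.min()), float(pos_I.max())]
    alpha_starts = [0.3, 1.0, 3.0] if modality == "mixed" else [1.0]
    n_par = 4 if modality == "mixed" else 3

    def resid(logp):
        p = np.exp(logp)
        kw = dict(vmax=p[0], km=p[1], ki=p[2])
        if modality == "mixed":
            kw["alpha"] = p[3]
        return modality_rate(S, I, modality=modality, **kw) - v

    best = None
    for ki0, a0 in itertools.product(ki_starts, alpha_starts):
        x0 = np.log([vmax0, km0, ki0] + ([a0] if modality == "mixed" else []))
        try:
            sol = least_squares(resid, x0=x0, xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=800)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol, rss)
    if best is None:
        return None
    sol, rss = best
    p = np.exp(sol.x)
    params = dict(vmax=float(p[0]), km=float(p[1]), ki=float(p[2]))
    params["alpha"] = float(p[3]) if modality == "mixed" else 1.0
    params["n_parameters"] = n_par
    return params, rss


def classify_modality(
    rates: pd.DataFrame,
    *,
    modalities: tuple[str, ...] = MODALITIES,
    mixed_margin_aicc: float = 2.0,
) -> InhibitionFit:
    """Fit all candidate rate laws globally and select the modality by AICc.

    *rates* needs columns ``substrate_conc``, ``inhibitor_nM`` and ``rate``
    (the output of :func:`initial_rates`), covering >= 4 substrate levels and
    >= 3 inhibitor levels including the uninhibited (I = 0) row — the
    no-inhibitor Michaelis-Menten behaviour anchors Vmax and Km.

    Small-sample corrected AIC is used because the grids are small.  The
    mixed law nests all three pure laws (alpha -> infinity, 0 and 1 recover
    competitive, uncompetitive and noncompetitive respectively), so it always
    fits at least as well numerically; it is therefore treated as the
    umbrella model and declared the winner only when it improves on the best
    pure law by at least ``mixed_margin_aicc`` AICc points (the conventional
    "models within ~2 AICc are equivalent; prefer the simpler" rule).
    Otherwise the best pure law wins, with ``collapsed_from_mixed=True`` when
    mixed had the numerically lowest AICc.  ``delta_aicc`` is the winner's
    margin to the best *rival pure law* — the scientifically competing
    hypothesis — never to its own nested umbrella.
    """
    required = {"substrate_conc", "inhibitor_nM", "rate"}
    if not required.issubset(rates.columns):
        raise ValidationError(f"rate table must have columns {sorted(required)}")
    S = rates["substrate_conc"].to_numpy(dtype=float)
    I = rates["inhibitor_nM"].to_numpy(dtype=float)
    v = rates["rate"].to_numpy(dtype=float)
    if np.unique(S).size < 4 or np.unique(I).size < 3:
        raise ValidationError("need >= 4 substrate levels and >= 3 inhibitor levels (incl. 0)")
    if not np.any(I == 0):
        raise ValidationError("rate table must include the uninhibited (I = 0) condition")

    params: dict[str, dict[str, float]] = {}
    rss: dict[str, float] = {}
    aicc: dict[str, float] = {}
    rss_floor = v.size * (1e-6 * max(float(np.sqrt(np.mean(v**2))), 1e-12)) ** 2
    for m in modalities:
        out = _fit_one_modality(S, I, v, m)
        if out is None:
            import warnings

            warnings.warn(f"modality {m!r} failed to converge and was excluded", RuntimeWarning, stacklevel=2)
            continue
        params[m], rss[m] = out
        aicc[m] = _aicc(rss[m], n=v.size, k=int(params[m]["n_parameters"]), rss_floor=rss_floor)
    if not aicc:
        raise ValidationError("all candidate modalities failed to fit")

    pure = [m for m in aicc if m != "mixed"]
    collapsed = False
    if not pure:
        winner = "mixed"
    else:
        winner = min(pure, key=aicc.get)
        if "mixed" in aicc:
            if aicc["mixed"] < aicc[winner] - mixed_margin_aicc:
                winner = "mixed"
            elif aicc["mixed"] < aicc[winner]:
                collapsed = True
    rivals = [m for m in pure if m != winner]
    delta = float(min(aicc[m] for m in rivals) - aicc[winner]) if rivals else np.inf
    return InhibitionFit(params=params, rss=rss, aicc=aicc, winner=winner, delta_aicc=delta, collapsed_from_mixed=collapsed)


# ---------------------------------------------------------------------------
# DSF melt curves
# ---------------------------------------------------------------------------


@dataclass
class MeltTm:
    """Tm extraction result: the melting-transition inflection temperature.

    ``ok`` is False when no interior derivative extremum exists (no
    transition within the ramp).  ``secondary`` lists the temperatures of any
    additional transitions (>= 25% of the main transition's derivative
    amplitude), e.g. free DNA melting separately from the protein.
    """

    tm: float
    ok: bool
    secondary: tuple[float, ...] = ()


def _refine_peak(x: np.ndarray, y: np.ndarray, i: int) -> float:
    # parabolic interpolation around a grid maximum
    if 0 < i < x.size - 1:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            shift = 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            # local grid step (ramps are uniform in practice)
            step = (x[i + 1] - x[i - 1]) / 2.0
            return float(x[i] + shift * step)
    return float(x[i])


def melt_tm(temperatures, fluorescence, *, window: int = 5, polyorder: int = 2) -> MeltTm:
    """Melting temperature from the first-derivative extremum of a DSF curve.

    The fluorescence trace is smoothed with a local polynomial
    (Savitzky-Golay, ``window`` points, order ``polyorder``), differentiated
    against temperature, and the Tm taken as the temperature of the largest
    interior positive derivative peak (environment-sensitive dyes gain signal
    on unfolding, so the transition is a rising edge), refined by parabolic
    interpolation.  Invariant to any offset or positive gain applied to the
    fluorescence.  A curve with no interior transition returns ``ok=False``.
    """
    T = np.asarray(temperatures, dtype=float)
    F = np.asarray(fluorescence, dtype=float)
    if T.size != F.size or T.size < 20:
        raise ValidationError("need >= 20 (temperature, fluorescence) points spanning the transition")
    if np.any(np.diff(T) <= 0):
        raise ValidationError("temperatures must be strictly increasing")
    window = min(window if window % 2 == 1 else window + 1, T.size - 1 - ((T.size - 1) % 2 == 0))
    window = max(window, polyorder + 1 + (polyorder % 2 == 0))
    smooth = savgol_filter(F, window_length=window, polyorder=polyorder)
    deriv = np.gradient(smooth, T)
    span = float(deriv.max() - deriv.min())
    # a real transition must rise meaningfully above the baseline slope;
    # pure-baseline traces have only ~1e-13 numerical jitter in the derivative
    if span <= 1e-9 * max(float(np.max(np.abs(deriv))), 1e-12):
        return MeltTm(tm=np.nan, ok=False)
    peaks, props = find_peaks(deriv, prominence=0.05 * span)
    if peaks.size == 0:
        return MeltTm(tm=np.nan, ok=False)
    heights = deriv[peaks]
    main = peaks[int(np.argmax(heights))]
    tm = _refine_peak(T, deriv, int(main))
    secondary = tuple(
        _refine_peak(T, deriv, int(p))
        for p in peaks
        if p != main and deriv[p] >= 0.25 * deriv[main]
    )
    return MeltTm(tm=tm, ok=True, secondary=secondary)


def _condition_tm(sub: pd.DataFrame, window: int, polyorder: int) -> float:
    tms = []
    for _, curve in sub.groupby("replicate", sort=True):
        curve = curve.sort_values("temp_C")
        res = melt_tm(curve["temp_C"].to_numpy(), curve["fluorescence"].to_numpy(), window=window, polyorder=polyorder)
        if res.ok:
            tms.append(res.tm)
    return float(np.mean(tms)) if tms else np.nan


def delta_tm(melt: pd.DataFrame, *, window: int = 5, polyorder: int = 2) -> pd.DataFrame:
    """Compound-induced thermal shifts against matched DMSO references.

    *melt* follows the ``melt`` schema with conditions named ``protein``,
    ``protein+DNA``, ``protein+compound``, ``protein+DNA+compound`` (and
    optionally ``DNA``).  For every compound concentration,
    ``delta_tm = Tm(compound) - Tm(matched no-compound reference)``, with the
    reference chosen in the same +/- DNA state — a DNA-dependent stabilizer
    shows a dose-responsive shift only in the +DNA rows.  Tm per condition is
    the mean over replicate curves.

    Returns columns ``compound_id, conc_nM, with_dna, tm, tm_reference,
    delta_tm`` sorted by compound, DNA state and dose.
    """
    required = {"condition", "compound_id", "conc_nM", "temp_C", "fluorescence", "replicate"}
    if not required.issubset(melt.columns):
        raise ValidationError(f"melt table must have columns {sorted(required)}")
    refs: dict[bool, float] = {}
    for with_dna, cond in ((False, "protein"), (True, "protein+DNA")):
        sub = melt[melt["condition"] == cond]
        if not sub.empty:
            refs[with_dna] = _condition_tm(sub, window, polyorder)
    rows = []
    comp = melt[melt["condition"].isin(("protein+compound", "protein+DNA+compound"))]
    if comp.empty:
        raise ValidationError("no compound-containing conditions present")
    for (cond, cid, conc), sub in comp.groupby(["condition", "compound_id", "conc_nM"], sort=True):
        with_dna = cond == "protein+DNA+compound"
        if with_dna not in refs or not np.isfinite(refs[with_dna]):
            raise ValidationError(
                f"missing matched DMSO reference condition {'protein+DNA' if with_dna else 'protein'}"
            )
        tm = _condition_tm(sub, window, polyorder)
        rows.append(
            dict(
                compound_id=cid,
                conc_nM=conc,
                with_dna=with_dna,
                tm=tm,
                tm_reference=refs[with_dna],
                delta_tm=tm - refs[with_dna],
            )
        )
    out = pd.DataFrame(rows).sort_values(["compound_id", "with_dna", "conc_nM"]).reset_index(drop=True)
    return out
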