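"""Cellular assay quantifications.

Four readouts, each a thin deterministic transform of instrument output:

* dual-luciferase end-joining reporter activity (NanoLuc normalized to
  Firefly, then to the DMSO control median),
* DNA end-resection ssDNA% from qPCR Ct pairs at a cut-site-adjacent locus,
* laser-microirradiation recruitment traces (ROI / same-nucleus background),
* live-cell apoptosis fraction (green caspase area over confluence area).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plates import ValidationError

__all__ = [
    "tmej_activity",
    "ssdna_percent",
    "delta_ct_for_ssdna",
    "resection_ssdna",
    "RecruitmentResult",
    "recruitment_curve",
    "apoptosis_fraction",
]


def tmej_activity(reporter: pd.DataFrame) -> pd.DataFrame:
    """Normalized end-joining reporter activity per well (fraction of DMSO).

    Each well's NanoLuc signal is divided by its Firefly signal (a combined
    cell-density / transfection-efficiency reference), then by the median
    NanoLuc/Firefly ratio over the DMSO control wells, so the DMSO set has
    median activity exactly 1.  Input follows the ``reporter`` schema
    (``compound_id, conc_molar, replicate, nano, firefly, is_dmso``).
    """
    required = {"nano", "firefly", "is_dmso"}
    if not required.issubset(reporter.columns):
        raise ValidationError(f"reporter table must have columns {sorted(required)}")
    out = reporter.copy()
    ff = out["firefly"].to_numpy(dtype=float)
    if np.any(~(ff > 0)):
        bad = out.index[~(ff > 0)][0]
        raise ValidationError(f"zero/negative firefly signal in reporter row {bad}")
    dmso = out[out["is_dmso"].astype(bool)]
    if dmso.empty:
        raise ValidationError("no DMSO reference wells (is_dmso=True) present")
    out["ratio"] = out["nano"].to_numpy(dtype=float) / ff
    ref = float(np.median(dmso["nano"].to_numpy(dtype=float) / dmso["firefly"].to_numpy(dtype=float)))
    if ref <= 0:
        raise ValidationError("DMSO reference median ratio must be > 0")
    out["activity"] = out["ratio"] / ref
    return out


def ssdna_percent(delta_ct):
    """ssDNA%% from a qPCR digestion cycle difference: 100 / (2**(dCt - 1) + 0.5).

    A restriction site inside single-stranded (resected) DNA resists
    digestion, so the digested template amplifies later; the constants encode
    digestion of one of the two strands of the remaining duplex fraction.
    Strictly decreasing in delta_ct; 100%% at delta_ct = 0, -> 0 as
    delta_ct -> infinity.
    """
    dct = np.asarray(delta_ct, dtype=float)
    out = 100.0 / (2.0 ** (dct - 1.0) + 0.5)
    return float(out) if out.ndim == 0 else out


def delta_ct_for_ssdna(pct):
    """Inverse of :func:`ssdna_percent` on (0, 100]: delta_ct = log2(100/pct - 0.5) + 1."""
    p = np.asarray(pct, dtype=float)
    if np.any(~((p > 0) & (p <= 100))):
        raise ValidationError("ssDNA%% must lie in (0, 100]")
    out = np.log2(100.0 / p - 0.5) + 1.0
    return float(out) if out.ndim == 0 else out


def resection_ssdna(ct_digested, ct_mock, site_id=None) -> pd.DataFrame:
    """Per-sample resection measurement from digested/mock Ct pairs.

    ``delta_ct = ct_digested - ct_mock`` (the digested template amplifies
    later when the site is double-stranded).  Negative delta_ct values are
    nonphysical (the digested sample cannot amplify earlier); the ssDNA%% is
    still computed (> 100) but flagged rather than clamped.
    """
    dig = np.atleast_1d(np.asarray(ct_digested, dtype=float))
    mock = np.atleast_1d(np.asarray(ct_mock, dtype=float))
    if dig.shape != mock.shape:
        raise ValidationError("ct_digested and ct_mock must have matching shapes")
    if not (np.all(np.isfinite(dig)) and np.all(np.isfinite(mock))):
        raise ValidationError("Ct values must be finite")
    dct = dig - mock
    out = pd.DataFrame(
        {
            "site_id": site_id if site_id is not None else ["site"] * dig.size,
            "ct_digested": dig,
            "ct_mock": mock,
            "delta_ct": dct,
            "ssdna_pct": ssdna_percent(dct),
            "nonphysical": dct < 0,
        }
    )
    return out


@dataclass
class RecruitmentResult:
    """Background-normalized recruitment trace with optional summary stats."""

    times: np.ndarray
    ratio: np.ndarray
    plateau: float | None = None
    t_half: float | None = None
    flags: tuple[str, ...] = ()


def recruitment_curve(
    times,
    roi_intensity,
    background_intensity,
    *,
    rescale: bool = True,
    summary: bool = False,
    n_plateau: int = 10,
) -> RecruitmentResult:
    """Recruitment ratio trace: ROI intensity over same-nucleus background.

    The ratio cancels expression differences between cells and any common
    photobleaching decay.  With ``rescale`` the trace is divided by the
    pre-damage (first-frame) ratio so recruitment starts at 1.  Frames with
    zero background are dropped with a warning.

    ``summary=True`` adds two descriptive extensions beyond the raw trace:
    ``plateau`` (mean of the final ``n_plateau`` frames) and ``t_half`` (first
    time the ratio exceeds halfway between 1 and the plateau); a flat trace
    flags ``no_recruitment`` and leaves ``t_half`` undefined.
    """
    t = np.asarray(times, dtype=float)
    roi = np.asarray(roi_intensity, dtype=float)
    bg = np.asarray(background_intensity, dtype=float)
    if not (t.shape == roi.shape == bg.shape):
        raise ValidationError("times, roi and background must have matching shapes")
    flags: list[str] = []
    keep = bg > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} frame(s) with zero background", RuntimeWarning, stacklevel=2)
        flags.append("dropped_zero_background")
        t, roi, bg = t[keep], roi[keep], bg[keep]
    if t.size == 0:
        raise ValidationError("no usable frames")
    ratio = roi / bg
    if rescale:
        if ratio[0] <= 0:
            raise ValidationError("pre-damage ratio must be > 0 to rescale")
        ratio = ratio / ratio[0]
    plateau = t_half = None
    if summary:
        plateau = float(np.mean(ratio[-n_plateau:]))
        if plateau <= 1.0 + 1e-9:
            flags.append("no_recruitment")
        else:
            thresh = (1.0 + plateau) / 2.0
            above = np.nonzero(ratio >= thresh)[0]
            t_half = float(t[above[0]]) if above.size else None
    return RecruitmentResult(times=t, ratio=ratio, plateau=plateau, t_half=t_half, flags=tuple(flags))


def apoptosis_fraction(confluence_pct, green_area):
    """Apoptosis%% over time: 100 * green (caspase) area / confluence area.

    Timepoints with zero confluence are undefined (NaN); negative areas are a
    validation error.
    """
    conf = np.asarray(confluence_pct, dtype=float)
    green = np.asarray(green_area, dtype=float)
    if conf.shape != green.shape:
        raise ValidationError("confluence and green-area traces must have matching shapes")
    if np.any(conf < 0) or np.any(green < 0):
        raise ValidationError("areas must be nonnegative")
    out = np.full(conf.shape, np.nan)
    ok = conf > 0
    out[ok] = 100.0 * green[ok] / conf[ok]
    return out
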