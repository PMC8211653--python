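"""Drug Effect scoring for drug-vs-vehicle siRNA chemosensitization screens.

A chemosensitization screen measures cell viability (luminescence) for each
siRNA twice: in the presence of a drug and in the presence of the vehicle
(DMSO).  After per-plate log2/median normalization (:mod:`assaykit.plates`),
the **Drug Effect** score of an siRNA is

    DE = norm(drug arm) - norm(vehicle arm)        [log2 units]

so negative DE means the siRNA makes cells *more* sensitive to the drug.
DE scores are Z-standardized against the screen median and median absolute
deviation (raw MAD, no 1.4826 consistency factor, so Z = -2 means "two MADs
below the median effect"), and sensitization hits are called at Z < -2
(strict) by default.  One screen = one drug/vehicle arm pair; different
compounds are scored independently.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .plates import ValidationError, plate_median_normalize

__all__ = [
    "combine_replicates",
    "drug_effect",
    "z_standardize",
    "call_hits",
    "score_screen",
    "screen_qc",
]

logger = logging.getLogger(__name__)


def combine_replicates(normalized: pd.DataFrame, method: str = "median") -> pd.DataFrame:
    """Collapse replicate plate-normalized values to one value per (perturbation, arm).

    Parameters
    ----------
    normalized
        Output of :func:`assaykit.plates.plate_median_normalize`; only
        library-role wells are combined.
    method
        ``"median"`` (default, robust to a single bad replicate) or ``"mean"``.

    Returns
    -------
    DataFrame with columns ``perturbation_id, arm, value, n_replicates_used``.
    """
    if method not in ("median", "mean"):
        raise ValueError(f"method must be 'median' or 'mean', got {method!r}")
    if "pm_normalized" not in normalized.columns:
        raise ValidationError("expected plate-normalized wells (missing 'pm_normalized' column)")
    lib = normalized[normalized["role"] == "library"]
    agg = (
        lib.groupby(["perturbation_id", "arm"], sort=True)["pm_normalized"]
        .agg(value=method, n_replicates_used="size")
        .reset_index()
    )
    return agg


def drug_effect(norm_drug, norm_vehicle):
    """Drug Effect score: drug-arm minus vehicle-arm normalized signal (log2 units)."""
    d = np.asarray(norm_drug, dtype=float)
    v = np.asarray(norm_vehicle, dtype=float)
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(v))):
        raise ValidationError("drug_effect requires finite normalized values")
    out = d - v
    return float(out) if out.ndim == 0 else out


def z_standardize(de_values, *, scaled_mad: bool = False) -> np.ndarray:
    """Z-standardize DE scores by screen median and median absolute deviation.

    z_i = (de_i - median(de)) / MAD(de), with raw MAD = median(|de - median|).
    Set ``scaled_mad=True`` to apply the 1.4826 normal-consistency factor
    (not used by default: Z = -2 is meant to read "two MADs below the median").

    If MAD is exactly 0 (degenerate screens), the sample standard deviation is
    substituted with a warning rather than crashing; fewer than 3 values is an
    error.
    """
    de = np.asarray(de_values, dtype=float)
    if de.size < 3:
        raise ValidationError(f"need >= 3 library perturbations to standardize, got {de.size}")
    if not np.all(np.isfinite(de)):
        raise ValidationError("DE scores must be finite")
    med = np.median(de)
    mad = np.median(np.abs(de - med))
    if scaled_mad:
        mad = 1.4826 * mad
    if mad == 0:
        warnings.warn(
            "MAD of DE scores is 0; falling back to the sample standard deviation",
            RuntimeWarning,
            stacklevel=2,
        )
        mad = float(np.std(de, ddof=1))
        if mad == 0:
            # Perfectly constant screen: all z are 0 by convention.
            return np.zeros_like(de)
    return (de - med) / mad


def call_hits(de_z, threshold: float = -2.0) -> np.ndarray:
    """Flag sensitization hits: z strictly below *threshold* (default -2)."""
    z = np.asarray(de_z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValidationError("Z scores must be finite")
    return z < threshold


def score_screen(
    wells: pd.DataFrame,
    *,
    drug_arm: str = "drug",
    vehicle_arm: str = "vehicle",
    combine: str = "median",
    threshold: float = -2.0,
    scaled_mad: bool = False,
    include_controls_in_median: bool = False,
) -> pd.DataFrame:
    """Run the full screen-scoring pipeline on raw screen wells.

    Steps: per-plate log2/median normalization -> replicate combination ->
    DE = drug - vehicle -> Z-standardization over library perturbations ->
    hit calling at ``z < threshold``.

    Returns one row per library perturbation present in both arms, sorted by
    ``de_z`` ascending (strongest sensitizers first), with columns
    ``perturbation_id, norm_drug, norm_vehicle, de, de_z, hit,
    n_replicates_drug, n_replicates_vehicle``.  Perturbations present in one
    arm only are excluded with a logged warning.
    """
    norm = plate_median_normalize(wells, include_controls=include_controls_in_median)
    per = combine_replicates(norm, method=combine)
    per = per[per["arm"].isin((drug_arm, vehicle_arm))]
    wide = per.pivot(index="perturbation_id", columns="arm", values=["value", "n_replicates_used"])
    have_both = wide["value"].notna().all(axis=1) if wide["value"].shape[1] == 2 else pd.Series(False, index=wide.index)
    dropped = wide.index[~have_both].tolist()
    if dropped:
        logger.warning(
            "%d perturbation(s) present in only one arm were excluded from scoring: %s%s",
            len(dropped),
            dropped[:5],
            "..." if len(dropped) > 5 else "",
        )
    wide = wide[have_both]
    res = pd.DataFrame(
        {
            "perturbation_id": wide.index,
            "norm_drug": wide[("value", drug_arm)].to_numpy(dtype=float),
            "norm_vehicle": wide[("value", vehicle_arm)].to_numpy(dtype=float),
            "n_replicates_drug": wide[("n_replicates_used", drug_arm)].to_numpy(dtype=int),
            "n_replicates_vehicle": wide[("n_replicates_used", vehicle_arm)].to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
    res["de"] = drug_effect(res["norm_drug"], res["norm_vehicle"])
    res["de_z"] = z_standardize(res["de"].to_numpy(), scaled_mad=scaled_mad)
    res["hit"] = call_hits(res["de_z"].to_numpy(), threshold)
    res = res.sort_values("de_z", kind="mergesort").reset_index(drop=True)
    return res[
        [
            "perturbation_id",
            "norm_drug",
            "norm_vehicle",
            "de",
            "de_z",
            "hit",
            "n_replicates_drug",
            "n_replicates_vehicle",
        ]
    ]


def screen_qc(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-plate positive/negative control separation report.

    For each ``(plate_id, arm, replicate)`` plate the separation is
    ``median(log2 positive controls) - median(log2 negative controls)``; a
    cell-killing positive control (e.g. an essential-gene siRNA) should give a
    clearly negative separation.  ``separation_z`` is a robust standardized
    score (separation over the pooled scaled MAD of the two control groups).
    Plates whose positive controls do not fall below the negatives are
    ``flagged``; plates lacking either control group are ``computable=False``.
    """
    if "log2_signal" not in normalized.columns:
        raise ValidationError("expected plate-normalized wells (missing 'log2_signal' column)")
    rows = []
    for (plate, arm, rep), sub in normalized.groupby(["plate_id", "arm", "replicate"], sort=True):
        neg = sub.loc[sub["role"] == "negative_control", "log2_signal"].to_numpy(dtype=float)
        pos = sub.loc[sub["role"] == "positive_control", "log2_signal"].to_numpy(dtype=float)
        rec = {"plate_id": plate, "arm": arm, "replicate": rep, "n_neg": neg.size, "n_pos": pos.size}
        if neg.size == 0 or pos.size == 0:
            rec.update(computable=False, separation=np.nan, separation_z=np.nan, flagged=True)
        else:
            sep = float(np.median(pos) - np.median(neg))
            spread = 1.4826 * np.hypot(
                np.median(np.abs(neg - np.median(neg))), np.median(np.abs(pos - np.median(pos)))
            )
            rec.update(
                computable=True,
                separation=sep,
                separation_z=sep / spread if spread > 0 else np.sign(sep) * np.inf if sep else 0.0,
                flagged=not sep < 0,
            )
        rows.append(rec)
    if not rows:
        raise ValidationError("no plates found")
    return pd.DataFrame(rows)
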