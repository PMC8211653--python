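"""Long-format plate-reader data: schemas, CSV round-trip, and normalization.

All assay readouts move through the package as long-format :class:`pandas.DataFrame`
objects with one measurement per row.  Seven named schemas cover the supported
assay families:

``screen``
    384-well siRNA chemosensitization screen wells (drug vs vehicle arms).
``dose_response``
    Compound dilution series with on-plate neg/pos control wells.
``progress``
    Quenched progress-curve grids (substrate x inhibitor x time).
``melt``
    Differential scanning fluorimetry temperature ramps.
``reporter``
    Dual NanoLuc/Firefly luminescence wells.
``ct``
    qPCR Ct pairs (restriction-digested vs mock-digested genomic DNA).
``trace``
    Generic long-format time traces (recruitment ratio, confluence, green area).

:func:`read_measurements` / :func:`write_measurements` give a validated,
bit-faithful CSV round trip on the declared fields.  :func:`plate_median_normalize`
implements the screen's shared normalization primitive: per-well log2 transform
followed by subtraction of the per-plate median, the plate aggregate being taken
over library wells only (controls sit at fixed positions with biased values, so
they are normalized *with* the library-derived median but excluded from
computing it; set ``include_controls=True`` to override).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "SCHEMAS",
    "ROLES",
    "ROWS_384",
    "read_measurements",
    "write_measurements",
    "validate_measurements",
    "plate_median_normalize",
]

#: Valid row letters on a 384-well plate (16 rows x 24 columns).
ROWS_384: tuple[str, ...] = tuple(chr(ord("A") + i) for i in range(16))

#: Well roles on a screen plate.
ROLES: tuple[str, ...] = ("library", "negative_control", "positive_control", "empty")

_DR_ROLES = ("sample", "neg_ctrl", "pos_ctrl")


class SchemaError(ValueError):
    """The file header does not match the declared measurement schema."""


class ValidationError(ValueError):
    """Rows parse but violate a field contract (range, role, finiteness)."""


_STR, _INT, _FLOAT, _BOOL = "str", "int", "float", "bool"

#: Declared columns (name -> dtype class) for each measurement schema,
#: in canonical on-disk order.
SCHEMAS: Mapping[str, Mapping[str, str]] = {
    "screen": {
        "plate_id": _STR,
        "row": _STR,
        "col": _INT,
        "role": _STR,
        "perturbation_id": _STR,
        "arm": _STR,
        "replicate": _INT,
        "signal": _FLOAT,
    },
    "dose_response": {
        "compound_id": _STR,
        "concentration_molar": _FLOAT,
        "replicate": _INT,
        "signal": _FLOAT,
        "role": _STR,
    },
    "progress": {
        "varied_substrate": _STR,
        "substrate_conc": _FLOAT,
        "inhibitor_nM": _FLOAT,
        "time_min": _FLOAT,
        "replicate": _INT,
        "signal": _FLOAT,
    },
    "melt": {
        "condition": _STR,
        "compound_id": _STR,
        "conc_nM": _FLOAT,
        "temp_C": _FLOAT,
        "fluorescence": _FLOAT,
        "replicate": _INT,
    },
    "reporter": {
        "compound_id": _STR,
        "conc_molar": _FLOAT,
        "replicate": _INT,
        "nano": _FLOAT,
        "firefly": _FLOAT,
        "is_dmso": _BOOL,
    },
    "ct": {
        "site_id": _STR,
        "sample_id": _STR,
        "ct_digested": _FLOAT,
        "ct_mock": _FLOAT,
    },
    "trace": {
        "trace_id": _STR,
        "time": _FLOAT,
        "channel": _STR,
        "value": _FLOAT,
    },
}


def _well_name(rec: pd.Series) -> str:
    if {"plate_id", "row", "col"}.issubset(rec.index):
        return f"{rec['plate_id']}:{rec['row']}{int(rec['col'])}"
    return f"line {rec.name}"


def _coerce(df: pd.DataFrame, schema: str, origin: str) -> pd.DataFrame:
    """Coerce columns to their declared dtypes; malformed rows -> error with line numbers."""
    spec = SCHEMAS[schema]
    out = df.copy()
    bad_lines: list[int] = []
    for name, kind in spec.items():
        col = out[name]
        if kind == _STR:
            out[name] = col.fillna("").astype(str)
        elif kind == _BOOL:
            if col.dtype == bool:
                continue
            mapped = (
                col.astype(str).str.strip().str.lower().map({"true": True, "false": False, "1": True, "0": False})
            )
            bad_lines += [int(i) + 2 for i in col.index[mapped.isna()]]
            out[name] = mapped.fillna(False).astype(bool)
        else:
            num = pd.to_numeric(col, errors="coerce")
            newly_bad = num.isna() & col.notna()
            bad_lines += [int(i) + 2 for i in col.index[newly_bad]]
            out[name] = num.astype(float if kind == _FLOAT else "Int64")
    if bad_lines:
        raise ValidationError(
            f"{origin}: malformed values in schema '{schema}' at line(s) "
            f"{sorted(set(bad_lines))[:20]} (header = line 1)"
        )
    for name, kind in spec.items():
        if kind == _INT:
            if out[name].isna().any():
                lines = [int(i) + 2 for i in out.index[out[name].isna()]]
                raise ValidationError(f"{origin}: missing integer '{name}' at line(s) {lines[:20]}")
            out[name] = out[name].astype(int)
    return out


def validate_measurements(df: pd.DataFrame, schema: str, origin: str = "<dataframe>") -> pd.DataFrame:
    """Validate *df* against a named schema, returning a dtype-coerced copy.

    Raises
    ------
    SchemaError
        If the schema name is unknown or required columns are missing.
    ValidationError
        If any row violates a field contract; the message names the offending
        well (or line) so instrument-side problems can be traced.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema '{schema}'; expected one of {sorted(SCHEMAS)}")
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{origin}: schema '{schema}' is missing required column(s) {missing}")
    out = _coerce(df, schema, origin)

    def _require(mask: pd.Series, msg: str) -> None:
        if mask.any():
            first = out.loc[mask].iloc[0]
            raise ValidationError(f"{origin}: {msg} (first offender: well {_well_name(first)})")

    if schema == "screen":
        _require(~out["row"].isin(ROWS_384), "row must be a letter A-P")
        _require((out["col"] < 1) | (out["col"] > 24), "col must be in 1..24")
        _require(~out["role"].isin(ROLES), f"role must be one of {ROLES}")
        _require(out["replicate"] < 1, "replicate must be >= 1")
        _require(~(out["signal"] >= 0), "signal must be a nonnegative real")
        _require((out["role"] == "empty") & (out["perturbation_id"] != ""), "empty wells carry no perturbation_id")
        dup = out.duplicated(subset=["plate_id", "row", "col", "arm", "replicate"], keep=False)
        _require(dup, "(plate_id, row, col) must be unique within one replicate of one arm")
    elif schema == "dose_response":
        _require(~(out["concentration_molar"] >= 0), "concentration_molar must be >= 0")
        _require(~(out["signal"] >= 0), "signal must be a nonnegative real")
        _require(~out["role"].isin(_DR_ROLES), f"role must be one of {_DR_ROLES}")
    elif schema == "progress":
        _require(~out["varied_substrate"].isin(("DNA", "dNTP")), "varied_substrate must be DNA or dNTP")
        _require(~(out["substrate_conc"] > 0), "substrate_conc must be > 0")
        _require(~(out["inhibitor_nM"] >= 0), "inhibitor_nM must be >= 0")
        _require(~(out["time_min"] >= 0), "time_min must be >= 0")
        _require(~(out["signal"] >= 0), "signal must be a nonnegative real")
    elif schema == "melt":
        _require(~np.isfinite(out["temp_C"]), "temp_C must be finite")
        _require(~(out["fluorescence"] >= 0), "fluorescence must be a nonnegative real")
        _require(~(out["conc_nM"] >= 0), "conc_nM must be >= 0")
    elif schema == "reporter":
        _require(~(out["conc_molar"] >= 0), "conc_molar must be >= 0")
        _require(~(out["nano"] >= 0), "nano must be a nonnegative real")
        _require(~(out["firefly"] > 0), "firefly must be > 0 (transfection/viability reference)")
    elif schema == "ct":
        _require(~np.isfinite(out["ct_digested"]), "ct_digested must be finite")
        _require(~np.isfinite(out["ct_mock"]), "ct_mock must be finite")
    elif schema == "trace":
        _require(~np.isfinite(out["value"]), "value must be finite")
    return out


def read_measurements(path, schema: str) -> pd.DataFrame:
    """Read a measurement CSV, check its header against *schema*, validate rows.

    Parameters
    ----------
    path
        CSV file with a header line (UTF-8, comma separated).
    schema
        One of ``screen, dose_response, progress, melt, reporter, ct, trace``.

    Returns
    -------
    pandas.DataFrame
        Validated records with canonical dtypes; row count preserved.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema '{schema}'; expected one of {sorted(SCHEMAS)}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    return validate_measurements(df, schema, origin=str(path))


def write_measurements(df: pd.DataFrame, path, schema: str) -> None:
    """Validate and write records to CSV in canonical column order.

    Re-reading the file with :func:`read_measurements` reproduces the declared
    fields bit-for-bit (floats are written with shortest round-trip repr).
    """
    out = validate_measurements(df, schema, origin="<write_measurements>")
    out[list(SCHEMAS[schema])].to_csv(path, index=False)


def plate_median_normalize(wells: pd.DataFrame, *, include_controls: bool = False) -> pd.DataFrame:
    """Log2-transform signals and subtract each plate's median log2 signal.

    Normalization is applied independently within each ``(plate_id, arm,
    replicate)`` group.  The plate aggregate is the median of ``log2(signal)``
    over **library** wells (controls and empties excluded) unless
    ``include_controls`` is set, in which case control wells join the pool.
    Control wells are always normalized with the resulting median; empty wells
    are never part of any aggregate.

    Returns a copy of *wells* with ``log2_signal`` and ``pm_normalized``
    columns added.  By construction the median of ``pm_normalized`` over the
    pool wells of every plate is exactly 0, and the result is invariant to
    multiplicative rescaling of all signals on a plate.

    Raises
    ------
    ValidationError
        If a plate has no library wells, or a pool well has a non-positive
        signal (library log2 must be finite for downstream Drug Effect scores;
        zero signals are tolerated only in control wells outside the pool).
    """
    out = validate_measurements(wells, "screen", origin="<plate_median_normalize>")
    with np.errstate(divide="ignore"):
        out["log2_signal"] = np.log2(out["signal"].to_numpy(dtype=float))
    out["pm_normalized"] = np.nan
    for (plate, arm, rep), idx in out.groupby(["plate_id", "arm", "replicate"], sort=False).groups.items():
        sub = out.loc[idx]
        pool = sub["role"] == "library"
        if include_controls:
            pool = pool | sub["role"].isin(("negative_control", "positive_control"))
        if not pool.any():
            raise ValidationError(f"plate {plate} (arm={arm}, replicate={rep}) has no library wells")
        nonpos = pool & ~(sub["signal"] > 0)
        if nonpos.any():
            first = sub.loc[nonpos].iloc[0]
            raise ValidationError(
                f"plate {plate} (arm={arm}, replicate={rep}): non-positive signal in "
                f"well {_well_name(first)} used for the plate median"
            )
        med = float(np.median(sub.loc[pool, "log2_signal"]))
        out.loc[idx, "pm_normalized"] = sub["log2_signal"] - med
    return out
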