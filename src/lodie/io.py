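"""CSV readers and writers for every table the pipeline touches.

All files are comma-separated UTF-8 with a header row and "." decimals.
Readers sort deterministically (by compound/feature id, then concentration),
so output order never depends on input row order. Floats are written with
17 significant digits, which makes read-write round trips lossless.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError, LodieError
from .records import CalibrationSeries, CompoundRecord, FeatureRecord, LoDEstimate

FLOAT_FMT = "%.17g"

_CAL_REQUIRED = ["compound_id", "concentration_M", "replicate", "peak_area"]
_LOD_CORE = ["compound_id", "method", "lod_M"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _to_float(value, path, row: int, column: str, allow_nan: bool = False) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if allow_nan:
            return float("nan")
        raise ParseError(f"{path} row {row}: empty value in column {column!r}")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"{path} row {row}: non-numeric value {value!r} in column {column!r}"
        ) from None


def read_calibration_csv(path) -> list[CalibrationSeries]:
    """Read a long-format calibration table into one series per compound.

    Required columns: compound_id, concentration_M, replicate, peak_area.
    Optional: sn, blank_area (constant per compound). An empty peak_area
    cell means the peak was not detected for that replicate.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _CAL_REQUIRED, path)
    has_sn = "sn" in df.columns
    has_blank = "blank_area" in df.columns

    rows = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        conc = _to_float(getattr(row, "concentration_M"), path, i, "concentration_M")
        if conc <= 0:
            raise ValidationError(
                f"{path} row {i}: non-positive concentration {conc} "
                f"for compound {row.compound_id!r}"
            )
        area = _to_float(getattr(row, "peak_area"), path, i, "peak_area", allow_nan=True)
        sn = (
            _to_float(getattr(row, "sn"), path, i, "sn", allow_nan=True)
            if has_sn
            else float("nan")
        )
        blank = (
            _to_float(getattr(row, "blank_area"), path, i, "blank_area", allow_nan=True)
            if has_blank
            else float("nan")
        )
        rows.append((row.compound_id, conc, str(row.replicate), area, sn, blank))

    tidy = pd.DataFrame(
        rows,
        columns=["compound_id", "concentration_M", "replicate", "peak_area", "sn", "blank_area"],
    )
    dup = tidy.duplicated(subset=["compound_id", "concentration_M", "replicate"])
    if dup.any():
        first = tidy[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate (compound, concentration, replicate) row for "
            f"{first['compound_id']!r} at {first['concentration_M']} M "
            f"replicate {first['replicate']!r}"
        )

    series: list[CalibrationSeries] = []
    for compound_id, grp in tidy.groupby("compound_id", sort=True):
        areas = grp.pivot(index="concentration_M", columns="replicate", values="peak_area")
        areas = areas.sort_index().reindex(sorted(areas.columns), axis=1)
        concs = areas.index.to_numpy(dtype=float)
        sn_matrix = None
        if has_sn:
            sn_p = grp.pivot(index="concentration_M", columns="replicate", values="sn")
            sn_p = sn_p.sort_index().reindex(sorted(sn_p.columns), axis=1)
            sn_matrix = sn_p.to_numpy(dtype=float)
            if np.all(np.isnan(sn_matrix)):
                sn_matrix = None
        blank = None
        if has_blank:
            vals = grp["blank_area"].dropna().unique()
            if vals.size > 1:
                raise ValidationError(
                    f"{path}: blank_area not constant for compound {compound_id!r}"
                )
            if vals.size == 1:
                blank = float(vals[0])
        series.append(
            CalibrationSeries(
                compound_id=str(compound_id),
                concentrations=concs,
                areas=areas.to_numpy(dtype=float),
                sn=sn_matrix,
                blank_area=blank,
            )
        )
    return series


def write_calibration_csv(series: Sequence[CalibrationSeries], path) -> None:
    """Write calibration series back to the long format read by `read_calibration_csv`."""
    if not series:
        raise ValidationError("refusing to write an empty calibration table")
    any_sn = any(s.sn is not None for s in series)
    any_blank = any(s.blank_area is not None for s in series)
    rows = []
    for s in sorted(series, key=lambda s: s.compound_id):
        for i, c in enumerate(s.concentrations):
            for j in range(s.n_replicates):
                row = {
                    "compound_id": s.compound_id,
                    "concentration_M": c,
                    "replicate": j + 1,
                    "peak_area": s.areas[i, j],
                }
                if any_sn:
                    row["sn"] = s.sn[i, j] if s.sn is not None else float("nan")
                if any_blank:
                    row["blank_area"] = (
                        s.blank_area if s.blank_area is not None else float("nan")
                    )
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def _coerce_cell(value: str):
    """Best-effort typed read-back of a flattened diagnostics cell."""
    if value == "":
        return None
    if value == "True":
        return True
    if value == "False":
        return False
    try:
        f = float(value)
    except ValueError:
        return value
    if f.is_integer() and "." not in value and "e" not in value.lower():
        return int(f)
    return f


def write_lod_table(estimates: Sequence[LoDEstimate], path) -> None:
    """Write LoD estimates as CSV; diagnostics are flattened into extra columns.

    Rows are sorted by (compound_id, method) and extra columns by name, so
    the file bytes do not depend on input order.
    """
    if not estimates:
        raise ValidationError("refusing to write an empty LoD table")
    diag_cols = sorted({k for e in estimates for k in e.diagnostics})
    rows = []
    for e in sorted(estimates, key=lambda e: (e.compound_id, e.method)):
        row = {"compound_id": e.compound_id, "method": e.method, "lod_M": e.lod}
        for k in diag_cols:
            row[k] = e.diagnostics.get(k, "")
        rows.append(row)
    pd.DataFrame(rows, columns=_LOD_CORE + diag_cols).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_lod_table(path) -> list[LoDEstimate]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _LOD_CORE, path)
    extra = [c for c in df.columns if c not in _LOD_CORE]
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        lod = _to_float(getattr(row, "lod_M"), path, i, "lod_M")
        diag = {}
        for c in extra:
            v = _coerce_cell(getattr(row, c))
            if v is not None:
                diag[c] = v
        out.append(
            LoDEstimate(
                compound_id=row.compound_id, method=row.method, lod=lod, diagnostics=diag
            )
        )
    return out


def read_compound_table(path) -> list[CompoundRecord]:
    """Read compounds with predicted log IE (columns compound_id, log_ie,
    optional monoisotopic_fraction, formula, mz)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["compound_id", "log_ie"], path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        kwargs = {
            "compound_id": row.compound_id,
            "log_ie": _to_float(row.log_ie, path, i, "log_ie"),
        }
        if "monoisotopic_fraction" in df.columns and row.monoisotopic_fraction != "":
            kwargs["monoisotopic_fraction"] = _to_float(
                row.monoisotopic_fraction, path, i, "monoisotopic_fraction"
            )
        if "formula" in df.columns and row.formula != "":
            kwargs["formula"] = row.formula
        if "mz" in df.columns and row.mz != "":
            kwargs["mz"] = _to_float(row.mz, path, i, "mz")
        out.append(CompoundRecord(**kwargs))
    return sorted(out, key=lambda r: r.compound_id)


def write_compound_table(records: Sequence[CompoundRecord], path) -> None:
    if not records:
        raise ValidationError("refusing to write an empty compound table")
    rows = []
    for r in sorted(records, key=lambda r: r.compound_id):
        rows.append(
            {
                "compound_id": r.compound_id,
                "log_ie": r.log_ie,
                "monoisotopic_fraction": r.monoisotopic_fraction,
                "formula": r.formula if r.formula is not None else "",
                "mz": r.mz if r.mz is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_feature_table(path) -> list[FeatureRecord]:
    """Read features.csv (feature_id, mz, rt_min, log_ie). An est_lod_M
    column on input is ignored: predictions are always recomputed."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["feature_id", "mz", "rt_min", "log_ie"], path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        out.append(
            FeatureRecord(
                feature_id=row.feature_id,
                mz=_to_float(row.mz, path, i, "mz"),
                rt=_to_float(row.rt_min, path, i, "rt_min"),
                log_ie=_to_float(row.log_ie, path, i, "log_ie"),
            )
        )
    return sorted(out, key=lambda r: r.feature_id)


def write_feature_table(records: Sequence[FeatureRecord], path) -> None:
    if not records:
        raise ValidationError("refusing to write an empty feature table")
    rows = []
    for r in sorted(records, key=lambda r: r.feature_id):
        row = {
            "feature_id": r.feature_id,
            "mz": r.mz,
            "rt_min": r.rt,
            "log_ie": r.log_ie,
        }
        if r.est_lod is not None:
            row["est_lod_M"] = r.est_lod
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)
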