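"""The four limit-of-detection estimators.

cutoff
    LoD = lowest concentration detected in at least ``min_replicates``
    replicates, with a dynamic-range sanity flag.
sn_extrapolation
    Extrapolates the S/N at the lowest detected in-range level down to the
    target S/N (default 3): LoD = c_lowest * sn_target / (S/N at c_lowest).
sd_based
    LoD = k_sd * SD(replicate areas at the lowest detected level) / slope.
residuals
    LoD = k_resid * SD(residuals of the n lowest in-range levels) / slope.

The multipliers default to 3.3 (the usual 3.3*sigma/slope convention) and
are configurable. SDs use the sample (n-1) form. Estimators whose
preconditions fail report themselves as unavailable with a reason; they
never return 0 or NaN in place of a value.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .calibration import (
    LinearRangeResult,
    blank_pass,
    detect_levels,
    determine_linear_range,
    level_mean_areas,
)
from .errors import (
    EstimatorUnavailableError,
    NoDetectionError,
    NotAcceptedError,
    NotEnoughDataError,
)
from .records import CalibrationSeries, LoDEstimate


@dataclass
class EstimatorConfig:
    """Tuning constants shared by the four approaches."""

    sn_target: float = 3.0
    k_sd: float = 3.3
    k_resid: float = 3.3
    n_resid_levels: int = 3

    def __post_init__(self) -> None:
        if self.sn_target <= 0 or self.k_sd <= 0 or self.k_resid <= 0:
            raise ValueError("sn_target, k_sd and k_resid must be strictly positive")
        if self.n_resid_levels < 2:
            raise ValueError("n_resid_levels must be >= 2")


@dataclass
class CompoundLoDResult:
    """All estimates for one compound, plus reasons for anything unavailable."""

    compound_id: str
    estimates: list[LoDEstimate] = field(default_factory=list)
    unavailable: dict[str, str] = field(default_factory=dict)
    excluded_reason: Optional[str] = None
    range_result: Optional[LinearRangeResult] = None
    detected: Optional[np.ndarray] = None


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1))


def lod_cutoff(
    series: CalibrationSeries,
    detected: np.ndarray,
    range_result: Optional[LinearRangeResult] = None,
) -> LoDEstimate:
    """Lowest detected concentration, flagged when it falls outside the
    dynamic range (above the accepted linear range, or with a level mean
    not below the next level's mean)."""
    if not detected.any():
        raise NoDetectionError(f"{series.compound_id}: nothing detected")
    idx = int(np.flatnonzero(detected)[0])
    lod = float(series.concentrations[idx])
    diag: dict = {"level_used_M": lod}
    means = level_mean_areas(series)
    if idx + 1 < series.n_levels and np.isfinite(means[idx + 1]):
        if not means[idx] < means[idx + 1]:
            diag["flag_dynamic_range"] = True
    if range_result is not None and range_result.accepted:
        if lod > float(range_result.included_levels[-1]):
            diag["flag_above_linear_range"] = True
    return LoDEstimate(series.compound_id, "cutoff", lod, diag)


def lod_sn_extrapolation(
    series: CalibrationSeries,
    detected: np.ndarray,
    range_result: LinearRangeResult,
    config: EstimatorConfig = EstimatorConfig(),
) -> LoDEstimate:
    """Linear S/N extrapolation from the lowest detected in-range level."""
    if series.sn is None:
        raise EstimatorUnavailableError(
            f"{series.compound_id}: no S/N column; S/N extrapolation unavailable"
        )
    if not range_result.accepted:
        raise EstimatorUnavailableError(
            f"{series.compound_id}: linear range not accepted"
        )
    in_range = np.isin(series.concentrations, range_result.included_levels)
    usable = detected & in_range
    if not usable.any():
        raise EstimatorUnavailableError(
            f"{series.compound_id}: no detected level inside the linear range"
        )
    idx = int(np.flatnonzero(usable)[0])
    sn_vals = series.sn[idx]
    sn_vals = sn_vals[~np.isnan(sn_vals)]
    if sn_vals.size == 0:
        raise EstimatorUnavailableError(
            f"{series.compound_id}: S/N missing at the lowest in-range level"
        )
    sn = float(sn_vals.mean())
    if sn <= 0:
        raise EstimatorUnavailableError(
            f"{series.compound_id}: nonpositive S/N at the lowest in-range level"
        )
    c_lowest = float(series.concentrations[idx])
    lod = c_lowest * config.sn_target / sn
    diag = {"level_used_M": c_lowest, "sn": sn}
    if lod > c_lowest:
        diag["flag_above_measured_floor"] = True
    return LoDEstimate(series.compound_id, "sn_extrapolation", lod, diag)


def lod_sd(
    series: CalibrationSeries,
    detected: np.ndarray,
    range_result: LinearRangeResult,
    config: EstimatorConfig = EstimatorConfig(),
) -> LoDEstimate:
    """k_sd * SD(replicate areas at the lowest detected level) / slope."""
    if not range_result.accepted:
        raise EstimatorUnavailableError(
            f"{series.compound_id}: linear range not accepted"
        )
    slope = range_result.fit.slope
    if slope <= 0:
        raise NotAcceptedError(f"{series.compound_id}: nonpositive slope")
    if not detected.any():
        raise NoDetectionError(f"{series.compound_id}: nothing detected")
    idx = int(np.flatnonzero(detected)[0])
    areas = series.areas[idx]
    areas = areas[~np.isnan(areas)]
    if areas.size < 2:
        raise EstimatorUnavailableError(
            f"{series.compound_id}: fewer than 2 replicate areas at the lowest "
            "detected level"
        )
    sd = _sample_sd(areas)
    lod = config.k_sd * sd / slope
    diag = {
        "level_used_M": float(series.concentrations[idx]),
        "sd": sd,
        "slope_M_inv": slope,
    }
    if sd == 0:
        diag["flag_degenerate"] = True
    return LoDEstimate(series.compound_id, "sd_based", lod, diag)


def lod_residuals(
    series: CalibrationSeries,
    range_result: LinearRangeResult,
    config: EstimatorConfig = EstimatorConfig(),
) -> LoDEstimate:
    """k_resid * SD(residuals of the n_resid_levels lowest in-range levels) / slope."""
    if not range_result.accepted:
        raise EstimatorUnavailableError(
            f"{series.compound_id}: linear range not accepted"
        )
    fit = range_result.fit
    if fit.n_points < config.n_resid_levels:
        raise EstimatorUnavailableError(
            f"{series.compound_id}: {fit.n_points} in-range levels, need "
            f"{config.n_resid_levels} for the residuals approach"
        )
    resid = fit.residuals[: config.n_resid_levels]
    sd = _sample_sd(resid)
    # an exact line leaves only rounding dust in the residuals: snap to 0
    scale_ref = float(np.max(np.abs(fit.mean_areas[: config.n_resid_levels])))
    if sd <= 1e-12 * scale_ref:
        sd = 0.0
    lod = config.k_resid * sd / fit.slope
    diag = {"sd": sd, "slope_M_inv": fit.slope, "n_points": config.n_resid_levels}
    if sd == 0:
        diag["flag_degenerate"] = True
    if range_result.included_levels.size and lod > float(range_result.included_levels[-1]):
        diag["flag_above_top_level"] = True
    return LoDEstimate(series.compound_id, "residuals", lod, diag)


def estimate_all(
    series: CalibrationSeries,
    config: EstimatorConfig = EstimatorConfig(),
    min_replicates: int = 2,
    min_area: float = 10_000.0,
    blank_ratio: float = 5.0,
    rel_tol: float = 0.05,
    min_levels: int = 4,
    min_points: int = 3,
    r2_min: float = 0.90,
) -> CompoundLoDResult:
    """Run detection, blank filter, linear range and all four estimators.

    Estimators whose preconditions fail are listed in ``unavailable`` with
    the reason; a compound failing detection or the blank filter is excluded
    outright with ``excluded_reason`` set.
    """
    result = CompoundLoDResult(series.compound_id)
    detected = detect_levels(series, min_replicates, min_area)
    result.detected = detected
    if not detected.any():
        result.excluded_reason = "no-detection"
        return result
    if not blank_pass(series, blank_ratio, detected, min_replicates, min_area):
        result.excluded_reason = "blank-filter"
        return result

    range_result = None
    try:
        range_result = determine_linear_range(
            series,
            rel_tol=rel_tol,
            min_levels=min_levels,
            r2_min=r2_min,
            min_points=min_points,
            detected=detected,
        )
    except NotEnoughDataError as exc:
        result.unavailable["linear_range"] = str(exc)
    result.range_result = range_result

    result.estimates.append(lod_cutoff(series, detected, range_result))

    if range_result is None:
        reason = result.unavailable.get("linear_range", "no linear range")
        for method in ("sn_extrapolation", "sd_based", "residuals"):
            result.unavailable[method] = reason
        return result

    for method, runner in (
        ("sn_extrapolation", lambda: lod_sn_extrapolation(series, detected, range_result, config)),
        ("sd_based", lambda: lod_sd(series, detected, range_result, config)),
        ("residuals", lambda: lod_residuals(series, range_result, config)),
    ):
        try:
            result.estimates.append(runner())
        except (EstimatorUnavailableError, NotAcceptedError, NoDetectionError) as exc:
            result.unavailable[method] = str(exc)
    return result
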