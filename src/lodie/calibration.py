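"""Detection logic, blank filtering, and linear-range determination.

The linear range is found by iterative bottom trimming: fit all detected
levels, and while any absolute relative residual exceeds the tolerance
(default 5%), drop the lowest remaining level and refit. Trimming never
touches the top of the range, so top-end saturation surfaces as an R²
failure rather than being repaired.

The response factor — the method's sensitivity toward a compound — is the
slope of the accepted calibration line, in M⁻¹ (area per molar).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateFitError,
    NotAcceptedError,
    NotEnoughDataError,
)
from .records import CalibrationSeries


@dataclass
class LinearFit:
    """An ordinary least-squares line through per-level mean areas."""

    slope: float            # M^-1 (area per molar)
    intercept: float        # area units
    r2: float
    residuals: np.ndarray       # observed - fitted, area units
    rel_residuals: np.ndarray   # |observed - fitted| / fitted
    concentrations: np.ndarray
    mean_areas: np.ndarray
    minimal: bool = False       # only two points: r2 = 1 by construction

    @property
    def n_points(self) -> int:
        return int(self.concentrations.size)


@dataclass
class LinearRangeResult:
    """Outcome of the trimming loop.

    ``included_levels`` is always a contiguous upper suffix of the detected
    concentration levels. ``accepted`` requires at least ``min_points``
    retained levels, the residual tolerance met, and r² above the threshold.
    """

    included_levels: np.ndarray
    fit: LinearFit
    accepted: bool
    n_removed: int
    tolerance_met: bool
    detected_levels: np.ndarray


def detect_levels(
    series: CalibrationSeries,
    min_replicates: int = 2,
    min_area: float = 10_000.0,
) -> np.ndarray:
    """Flag each level detected iff >= min_replicates replicate areas reach min_area."""
    if min_replicates < 1:
        raise ConfigurationError("min_replicates must be >= 1")
    if min_replicates > series.n_replicates:
        raise ConfigurationError(
            f"min_replicates={min_replicates} exceeds the "
            f"{series.n_replicates} measured replicates"
        )
    present = ~np.isnan(series.areas)
    hits = (series.areas >= min_area) & present
    return hits.sum(axis=1) >= min_replicates


def level_mean_areas(series: CalibrationSeries) -> np.ndarray:
    """Per-level mean over detected replicates (present and > 0); NaN if none."""
    areas = series.areas
    mask = (~np.isnan(areas)) & (areas > 0)
    with np.errstate(invalid="ignore"):
        sums = np.where(mask, areas, 0.0).sum(axis=1)
        counts = mask.sum(axis=1)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means


def blank_pass(
    series: CalibrationSeries,
    blank_ratio: float = 5.0,
    detected: np.ndarray | None = None,
    min_replicates: int = 2,
    min_area: float = 10_000.0,
) -> bool:
    """Blank filter: mean area at the lowest detected level must be at least
    ``blank_ratio`` times the blank area. Vacuously passes without a blank."""
    if series.blank_area is None:
        return True
    if detected is None:
        detected = detect_levels(series, min_replicates, min_area)
    if not detected.any():
        return False
    lowest = int(np.flatnonzero(detected)[0])
    mean_area = level_mean_areas(series)[lowest]
    return bool(mean_area >= blank_ratio * series.blank_area)


def fit_line(concs: np.ndarray, mean_areas: np.ndarray) -> LinearFit:
    """OLS fit of mean area on concentration, with intercept.

    rel_residuals use the fitted value as denominator so the criterion stays
    defined when an observation is 0; a fitted value of 0 gives rel_residual
    0 for a 0 observation and inf otherwise.
    """
    concs = np.asarray(concs, dtype=float)
    y = np.asarray(mean_areas, dtype=float)
    if concs.size < 2:
        raise NotEnoughDataError("need at least 2 points for a line")
    if np.ptp(concs) == 0:
        raise DegenerateFitError("all concentrations identical")
    slope, intercept = np.polyfit(concs, y, 1)
    fitted = intercept + slope * concs
    residuals = y - fitted
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(residuals) / fitted
    rel = np.where((fitted == 0) & (residuals == 0), 0.0, rel)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        r2=r2,
        residuals=residuals,
        rel_residuals=rel,
        concentrations=concs,
        mean_areas=y,
        minimal=concs.size == 2,
    )


def determine_linear_range(
    series: CalibrationSeries,
    rel_tol: float = 0.05,
    min_levels: int = 4,
    r2_min: float = 0.90,
    min_points: int = 3,
    min_replicates: int = 2,
    min_area: float = 10_000.0,
    detected: np.ndarray | None = None,
) -> LinearRangeResult:
    """Iteratively trim the lowest level until all |relative residuals| <= rel_tol.

    ``min_levels`` guards the loop (at least this many levels must remain,
    default 4, i.e. "more than three"); ``min_points`` (default 3) together
    with ``r2_min`` govern acceptance of the final fit.
    """
    if detected is None:
        detected = detect_levels(series, min_replicates, min_area)
    det_idx = np.flatnonzero(detected)
    if det_idx.size < min_levels:
        raise NotEnoughDataError(
            f"{series.compound_id}: only {det_idx.size} detected levels, "
            f"need at least {min_levels}"
        )
    means = level_mean_areas(series)
    concs = series.concentrations[det_idx]
    y = means[det_idx]
    detected_levels = concs.copy()

    n_removed = 0
    while True:
        fit = fit_line(concs[n_removed:], y[n_removed:])
        tolerance_met = bool(np.all(fit.rel_residuals <= rel_tol))
        if tolerance_met:
            break
        if concs.size - n_removed - 1 < min_levels:
            break
        n_removed += 1

    accepted = bool(tolerance_met and fit.n_points >= min_points and fit.r2 > r2_min)
    return LinearRangeResult(
        included_levels=concs[n_removed:],
        fit=fit,
        accepted=accepted,
        n_removed=n_removed,
        tolerance_met=tolerance_met,
        detected_levels=detected_levels,
    )


def response_factor(result: LinearRangeResult) -> float:
    """Slope of the accepted calibration line, M⁻¹."""
    if not result.accepted:
        raise NotAcceptedError("linear range not accepted; no response factor")
    return result.fit.slope
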