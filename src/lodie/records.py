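"""Core domain records for LoD estimation.

Concentrations are molar throughout (the printed LoD ranges in this field
are molar); peak areas are arbitrary detector counts. A missing peak area
(NaN) means "not detected at this level/replicate"; an area of 0 is treated
the same way by the detection logic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

#: The four LoD estimation approaches.
METHODS = ("cutoff", "sn_extrapolation", "sd_based", "residuals")


@dataclass
class CalibrationSeries:
    """One compound's dilution series with replicate peak areas.

    Parameters
    ----------
    compound_id
        Opaque identifier.
    concentrations
        Strictly increasing, strictly positive molar concentrations,
        one per dilution level.
    areas
        Peak-area matrix, shape (n_levels, n_replicates); NaN = not detected.
    sn
        Optional signal-to-noise matrix aligned with ``areas``.
    blank_area
        Optional nonnegative mean blank peak area for the blank filter.
    """

    compound_id: str
    concentrations: np.ndarray
    areas: np.ndarray
    sn: Optional[np.ndarray] = None
    blank_area: Optional[float] = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.areas = np.atleast_2d(np.asarray(self.areas, dtype=float))
        if self.concentrations.ndim != 1:
            raise ValidationError(f"{self.compound_id}: concentrations must be 1-D")
        if np.any(~np.isfinite(self.concentrations)) or np.any(self.concentrations <= 0):
            raise ValidationError(
                f"{self.compound_id}: concentrations must be finite and > 0"
            )
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValidationError(
                f"{self.compound_id}: concentrations must be strictly increasing"
            )
        if self.areas.shape[0] != self.concentrations.size:
            raise ValidationError(
                f"{self.compound_id}: areas has {self.areas.shape[0]} rows for "
                f"{self.concentrations.size} concentration levels"
            )
        present = ~np.isnan(self.areas)
        if np.any(self.areas[present] < 0):
            raise ValidationError(f"{self.compound_id}: negative peak area")
        if self.sn is not None:
            self.sn = np.atleast_2d(np.asarray(self.sn, dtype=float))
            if self.sn.shape != self.areas.shape:
                raise ValidationError(
                    f"{self.compound_id}: sn shape {self.sn.shape} does not match "
                    f"areas shape {self.areas.shape}"
                )
        if self.blank_area is not None:
            self.blank_area = float(self.blank_area)
            if self.blank_area < 0:
                raise ValidationError(f"{self.compound_id}: blank_area must be >= 0")

    @property
    def n_levels(self) -> int:
        return int(self.concentrations.size)

    @property
    def n_replicates(self) -> int:
        return int(self.areas.shape[1])


@dataclass
class CompoundRecord:
    """A compound with an externally predicted ionization efficiency (log10 IE)."""

    compound_id: str
    log_ie: float
    monoisotopic_fraction: float = 1.0
    formula: Optional[str] = None
    mz: Optional[float] = None

    def __post_init__(self) -> None:
        self.log_ie = float(self.log_ie)
        self.monoisotopic_fraction = float(self.monoisotopic_fraction)
        if not 0 < self.monoisotopic_fraction <= 1:
            raise ValidationError(
                f"{self.compound_id}: monoisotopic_fraction must be in (0, 1], "
                f"got {self.monoisotopic_fraction}"
            )
        if self.mz is not None:
            self.mz = float(self.mz)
            if self.mz <= 0:
                raise ValidationError(f"{self.compound_id}: mz must be > 0")


@dataclass
class FeatureRecord:
    """A nontargeted LC-HRMS feature: (m/z, retention time) with predicted log IE."""

    feature_id: str
    mz: float
    rt: float
    log_ie: float
    est_lod: Optional[float] = None

    def __post_init__(self) -> None:
        self.mz = float(self.mz)
        self.rt = float(self.rt)
        self.log_ie = float(self.log_ie)
        if self.mz <= 0:
            raise ValidationError(f"{self.feature_id}: mz must be > 0")
        if self.rt < 0:
            raise ValidationError(f"{self.feature_id}: rt must be >= 0")
        if self.est_lod is not None:
            self.est_lod = float(self.est_lod)


@dataclass
class LoDEstimate:
    """A method-tagged molar LoD with free-form diagnostics.

    ``lod`` may be exactly 0 in the degenerate zero-noise case (flagged
    in diagnostics); it is never negative.
    """

    compound_id: str
    method: str
    lod: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(
                f"unknown LoD method {self.method!r}; expected one of {METHODS}"
            )
        self.lod = float(self.lod)
        if self.lod < 0:
            raise ValidationError(f"{self.compound_id}/{self.method}: lod must be >= 0")
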