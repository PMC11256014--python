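"""Synthetic calibration experiments with known ground truth.

The generator emulates a standards-based LC/ESI/HRMS calibration study:
16 dilution levels in triplicate spanning ~7.5 orders of magnitude,
per-compound response factors log-uniform over ~10^12.5-10^16.5 M^-1,
an additive detector-noise floor plus proportional (multiplicative)
scatter, an optional top-end saturation cap, and a noisy negative-slope
linear link between log IE and log10 LoD.

True LoD is defined as sn_target * sigma / RF, so the S/N-extrapolation
assumption holds exactly in expectation and estimator deviations are
attributable to the estimators, not to simulator mismatch.

Every simulator is a pure function of (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .records import CalibrationSeries, CompoundRecord, FeatureRecord

#: Relative dilution factors of the 16-level series (top level = 1),
#: mirroring a 500 ... 0.00001 ug/L standards ladder.
DEFAULT_GRID_FACTORS = (
    1.0, 0.2, 0.1, 0.02, 0.01, 0.002, 0.001, 2e-4,
    1e-4, 2e-5, 1e-5, 2e-6, 1e-6, 2e-7, 1e-7, 2e-8,
)


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic experiments.

    ``noise_sd_range`` (additive area noise, log-uniform draw) defaults to
    (1500, 3000): with the 10 000-count detection floor this places the
    true LoD within about one dilution step of the lowest detectable level
    while keeping spurious sub-LoD detections negligible.
    """

    n_compounds: int = 100
    seed: int = 0
    rf_log10_range: tuple[float, float] = (12.5, 16.5)
    noise_sd_range: tuple[float, float] = (1500.0, 3000.0)
    mult_noise_cv: float = 0.05
    saturation_area: float | None = None
    detection_min_area: float = 10_000.0
    sn_target: float = 3.0
    top_concentration: float = 1.67e-6  # M; ~500 ug/L at MW 300 g/mol
    grid_factors: tuple[float, ...] = DEFAULT_GRID_FACTORS
    replicates: int = 3
    ie_link: tuple[float, float, float] = (-5.0, -1.0, 0.5)  # (a, b, sigma)

    def __post_init__(self) -> None:
        if self.n_compounds < 0:
            raise ConfigurationError("n_compounds must be >= 0")
        if self.rf_log10_range[0] > self.rf_log10_range[1]:
            raise ConfigurationError("rf_log10_range must be ordered")
        if not 0 < self.noise_sd_range[0] <= self.noise_sd_range[1]:
            raise ConfigurationError("noise_sd_range must be positive and ordered")
        if self.replicates < 2:
            raise ConfigurationError("replicates must be >= 2")
        f = np.asarray(self.grid_factors, dtype=float)
        if np.any(np.diff(f) >= 0) or np.any(f <= 0):
            raise ConfigurationError("grid_factors must be strictly decreasing and > 0")
        if self.ie_link[1] == 0:
            raise ConfigurationError("ie_link slope b must be nonzero")
        if self.ie_link[2] < 0:
            raise ConfigurationError("ie_link sigma must be >= 0")

    @property
    def concentrations(self) -> np.ndarray:
        """Ascending molar concentration grid."""
        return np.sort(self.top_concentration * np.asarray(self.grid_factors))


@dataclass
class TruthRecord:
    """Ground truth behind one synthetic compound."""

    compound_id: str
    rf_true: float          # M^-1
    noise_sd_true: float    # area units
    lod_true: float         # M, = sn_target * noise_sd / rf
    log_ie_true: float


def _log_ie_range(config: SimConfig) -> tuple[float, float]:
    """log IE sampling range implied by the configured response-factor span.

    log10 RF = log10(sn_target * sigma) - log10 LoD, so sampling log IE
    uniformly over this interval makes the implied RF span match
    rf_log10_range up to the noise-SD jitter and the link noise.
    """
    a, b, _ = config.ie_link
    log_sn_sigma = float(
        np.log10(config.sn_target) + np.mean(np.log10(config.noise_sd_range))
    )
    bounds = [((log_sn_sigma - r) - a) / b for r in config.rf_log10_range]
    return (min(bounds), max(bounds))


def _draw_truth(config: SimConfig, rng: np.random.Generator, cid: str) -> TruthRecord:
    """log IE is generative: LoD follows from the link, RF from the noise floor.

    Drawing in this order keeps log10 LoD = a + b*logIE + noise a true
    conditional model, so regressing estimated LoDs on log IE recovers
    (a, b) without attenuation.
    """
    a, b, sigma = config.ie_link
    log_ie = rng.uniform(*_log_ie_range(config))
    eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
    lod = 10.0 ** (a + b * log_ie + eps)
    lo, hi = np.log10(config.noise_sd_range)
    sd = 10.0 ** rng.uniform(lo, hi)
    rf = config.sn_target * sd / lod
    return TruthRecord(cid, float(rf), float(sd), float(lod), float(log_ie))


def simulate_compounds(
    config: SimConfig,
) -> list[tuple[CompoundRecord, TruthRecord]]:
    """Draw compounds with response factors, noise SDs and linked log IE."""
    rng = np.random.default_rng(config.seed)
    out = []
    width = max(3, len(str(max(config.n_compounds, 1))))
    for i in range(config.n_compounds):
        cid = f"C{i + 1:0{width}d}"
        truth = _draw_truth(config, rng, cid)
        out.append((CompoundRecord(compound_id=cid, log_ie=truth.log_ie_true), truth))
    return out


def simulate_calibration(
    truth: TruthRecord, config: SimConfig, seed: int
) -> CalibrationSeries:
    """One compound's dilution series: area = sat(RF*c)*(1+eps_m) + eps_a.

    eps_m ~ N(0, mult_noise_cv), eps_a ~ N(0, noise_sd_true); negative
    draws are floored at 0. The S/N column is area / noise_sd_true. Areas
    below the detection floor are still recorded — detection is downstream
    logic, not the simulator's job.
    """
    rng = np.random.default_rng(seed)
    concs = config.concentrations
    u = truth.rf_true * concs
    if config.saturation_area is not None:
        cap = config.saturation_area
        u = cap * (1.0 - np.exp(-u / cap))
    shape = (concs.size, config.replicates)
    eps_m = rng.normal(0.0, config.mult_noise_cv, size=shape) if config.mult_noise_cv > 0 else 0.0
    eps_a = (
        rng.normal(0.0, truth.noise_sd_true, size=shape)
        if truth.noise_sd_true > 0
        else 0.0
    )
    areas = np.maximum(u[:, None] * (1.0 + eps_m) + eps_a, 0.0)
    sn = areas / truth.noise_sd_true if truth.noise_sd_true > 0 else None
    return CalibrationSeries(
        compound_id=truth.compound_id,
        concentrations=concs,
        areas=areas,
        sn=sn,
    )


def simulate_study(
    config: SimConfig,
) -> tuple[list[CalibrationSeries], list[CompoundRecord], list[TruthRecord]]:
    """Full synthetic experiment: compounds plus one calibration series each."""
    pairs = simulate_compounds(config)
    children = np.random.SeedSequence(config.seed).spawn(len(pairs))
    series = []
    for (_, truth), child in zip(pairs, children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        series.append(simulate_calibration(truth, config, child_seed))
    compounds = [c for c, _ in pairs]
    truths = [t for _, t in pairs]
    return series, compounds, truths


def simulate_feature_table(
    config: SimConfig,
    n_features: int | None = None,
    pred_noise_sd: float = 0.0,
    mz_range: tuple[float, float] = (100.0, 1500.0),
    rt_range: tuple[float, float] = (0.0, 13.0),
) -> tuple[list[FeatureRecord], pd.DataFrame]:
    """Nontargeted features with predicted log IE and a hidden true LoD.

    ``pred_noise_sd`` perturbs the recorded log IE around the truth,
    mimicking prediction-model error. Returns (features, truth table).
    """
    if n_features is None:
        n_features = config.n_compounds
    rng = np.random.default_rng(config.seed + 1)
    features, rows = [], []
    width = max(3, len(str(max(n_features, 1))))
    for i in range(n_features):
        fid = f"F{i + 1:0{width}d}"
        truth = _draw_truth(config, rng, fid)
        log_ie_obs = truth.log_ie_true + (
            rng.normal(0.0, pred_noise_sd) if pred_noise_sd > 0 else 0.0
        )
        features.append(
            FeatureRecord(
                feature_id=fid,
                mz=float(rng.uniform(*mz_range)),
                rt=float(rng.uniform(*rt_range)),
                log_ie=float(log_ie_obs),
            )
        )
        rows.append(
            {
                "feature_id": fid,
                "rf_true": truth.rf_true,
                "noise_sd_true": truth.noise_sd_true,
                "lod_true": truth.lod_true,
                "log_ie_true": truth.log_ie_true,
            }
        )
    return features, pd.DataFrame(rows)


def truth_table(truths: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": t.compound_id,
                "rf_true": t.rf_true,
                "noise_sd_true": t.noise_sd_true,
                "lod_true": t.lod_true,
                "log_ie_true": t.log_ie_true,
            }
            for t in truths
        ]
    )
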