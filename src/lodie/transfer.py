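"""Robust transfer model: predicted log IE -> log10 LoD (M).

LoD spans many orders of magnitude, so the line is fitted on the log10
scale:  log10 LoD = intercept + slope * logIE, with slope expected < 0
(better-ionizing compounds are detectable at lower concentrations).

The default fit is a Huber M-estimate via iteratively reweighted least
squares: tuning constant 1.345, scale re-estimated each iteration as the
normalized median absolute deviation of residuals, convergence when the
largest coefficient change drops below 1e-8, at most 100 iterations.
Theil-Sen is available as an alternative. On outlier-free collinear data
both return the exact line.

Two model flavours are kept distinct by ``label`` (e.g. structure-based
vs fingerprint-based log IE); appliers should refuse a mismatched label
unless forced.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, ValidationError
from .records import CompoundRecord, FeatureRecord

HUBER_C = 1.345
#: 1 / Phi^-1(0.75): scales the MAD to estimate a Gaussian sigma.
MAD_NORM = 1.0 / 0.6744897501960817


@dataclass
class RobustLine:
    slope: float
    intercept: float
    scale: float
    n_used: int
    converged: bool
    n_iter: int
    se_slope: float = float("nan")
    se_intercept: float = float("nan")
    label: Optional[str] = None
    method: str = "huber"


@dataclass
class PriorityTable:
    """Ranked features; ``direction`` is 'lowest' or 'highest' (by est. LoD)."""

    table: pd.DataFrame
    direction: str


def correct_log_ie(record: CompoundRecord) -> float:
    """Shift log IE to account for the monoisotopic (main) peak only."""
    if record.monoisotopic_fraction <= 0:
        raise ValidationError(f"{record.compound_id}: monoisotopic_fraction must be > 0")
    return record.log_ie + float(np.log10(record.monoisotopic_fraction))


def _ols(x: np.ndarray, y: np.ndarray, w: Optional[np.ndarray] = None):
    X = np.column_stack([np.ones_like(x), x])
    if w is not None:
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta  # (intercept, slope)


def fit_robust(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "huber",
    c: float = HUBER_C,
    tol: float = 1e-8,
    max_iter: int = 100,
    label: Optional[str] = None,
) -> RobustLine:
    """Fit log10 LoD = intercept + slope * logIE robustly.

    Requires at least 3 finite pairs with non-constant x. Non-convergence
    of the IRLS is reported via ``converged=False``, not raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise DegenerateFitError(f"need >= 3 finite pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("x is constant; slope undefined")

    if method == "theil-sen":
        res = stats.theilslopes(y, x)
        resid = y - (res.intercept + res.slope * x)
        scale = float(np.median(np.abs(resid - np.median(resid))) * MAD_NORM)
        return RobustLine(
            slope=float(res.slope),
            intercept=float(res.intercept),
            scale=scale,
            n_used=int(x.size),
            converged=True,
            n_iter=0,
            label=label,
            method="theil-sen",
        )
    if method != "huber":
        raise ValueError(f"unknown robust method {method!r}")

    beta = _ols(x, y)
    converged = False
    n_iter = 0
    scale = 0.0
    w = np.ones_like(x)
    for n_iter in range(1, max_iter + 1):
        resid = y - (beta[0] + beta[1] * x)
        scale = float(np.median(np.abs(resid - np.median(resid))) * MAD_NORM)
        if scale == 0.0:
            # exact fit (up to >50% of residuals identical): nothing to reweight
            converged = True
            break
        u = np.abs(resid / scale)
        w = np.where(u <= c, 1.0, c / u)
        new_beta = _ols(x, y, w)
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            converged = True
            break
        beta = new_beta

    # standard errors from the final weighted normal equations
    X = np.column_stack([np.ones_like(x), x])
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = scale**2 * np.linalg.inv(XtWX)
        se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_int = se_slope = float("nan")
    return RobustLine(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        scale=scale,
        n_used=int(x.size),
        converged=converged,
        n_iter=n_iter,
        se_slope=se_slope,
        se_intercept=se_int,
        label=label,
        method="huber",
    )


def predict_lod(model: RobustLine, log_ie: float, force: bool = False) -> float:
    """LoD in M: 10 ** (intercept + slope * log_ie)."""
    if not model.converged and not force:
        raise ValidationError("model did not converge; pass force=True to override")
    log_ie = float(log_ie)
    if not np.isfinite(log_ie):
        raise ValidationError(f"non-finite log_ie: {log_ie}")
    return float(10.0 ** (model.intercept + model.slope * log_ie))


def prioritize(
    features: Sequence[FeatureRecord],
    model: RobustLine,
    k: int,
    direction: str = "lowest",
    force: bool = False,
) -> PriorityTable:
    """Fill est_lod from the model, rank, and return the top-k.

    'lowest' ranks the most detectable candidates first (identification
    targets); 'highest' surfaces likely false positives. Ties are broken
    by feature_id for determinism.
    """
    if direction not in ("lowest", "highest"):
        raise ValidationError(f"direction must be 'lowest' or 'highest', got {direction!r}")
    n = len(features)
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} available features")
    rows = []
    for f in features:
        est = predict_lod(model, f.log_ie, force=force)
        f.est_lod = est
        rows.append(
            {
                "feature_id": f.feature_id,
                "mz": f.mz,
                "rt_min": f.rt,
                "log_ie": f.log_ie,
                "est_lod_M": est,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["est_lod_M", "feature_id"], ascending=[direction == "lowest", True]
    ).head(k)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return PriorityTable(table=df.reset_index(drop=True), direction=direction)


def save_model(model: RobustLine, path) -> None:
    payload = {
        "slope": model.slope,
        "intercept": model.intercept,
        "scale": model.scale,
        "n_used": model.n_used,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "se_slope": model.se_slope,
        "se_intercept": model.se_intercept,
        "label": model.label,
        "method": model.method,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path) -> RobustLine:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return RobustLine(**payload)
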