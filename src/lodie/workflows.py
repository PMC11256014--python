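"""End-to-end workflows mirroring the two applications of the pipeline:
calibrate-and-fit (standards -> LoDs -> transfer model) and
predict-and-prioritize (features + model -> ranked candidates).

Every run writes a manifest recording the resolved configuration, seed and
software version; reruns with identical inputs and config are byte-identical.
No compound is silently dropped: every input id appears either in the
outputs or in reasons.csv.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError, WorkflowError
from .estimators import EstimatorConfig, estimate_all
from .io import (
    FLOAT_FMT,
    read_calibration_csv,
    read_compound_table,
    read_feature_table,
    write_lod_table,
)
from .rankstats import correlation_matrix
from .records import LoDEstimate
from .transfer import (
    RobustLine,
    correct_log_ie,
    fit_robust,
    load_model,
    prioritize,
    save_model,
)

DEFAULT_FIT_METHOD_LOD = "cutoff"


@dataclass
class RunConfig:
    """Thresholds and options shared by the workflows."""

    min_replicates: int = 2
    min_area: float = 10_000.0
    blank_ratio: float = 5.0
    rel_tol: float = 0.05
    min_levels: int = 4
    min_points: int = 3
    r2_min: float = 0.90
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    fit_method: str = "huber"
    fit_lod_method: str = DEFAULT_FIT_METHOD_LOD
    model_label: Optional[str] = None
    apply_isotope_correction: bool = True
    k: int = 20
    seed: int = 0


def _write_manifest(out_dir: Path, config: RunConfig, inputs: dict, outputs: list) -> None:
    payload = {
        "software": "lodie",
        "version": __version__,
        "seed": config.seed,
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "estimator"},
            "estimator": asdict(config.estimator),
        },
        "inputs": inputs,
        "outputs": sorted(outputs),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_calibration_workflow(
    calibration_csv,
    compounds_csv,
    out_dir,
    config: RunConfig = RunConfig(),
) -> dict:
    """Standards workflow: detect -> blank filter -> linear range -> four
    LoD estimators -> correlations -> robust transfer fit.

    Writes lod_table.csv, linear_range.csv, reasons.csv, correlations.csv,
    model.json and manifest.json into ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series = read_calibration_csv(calibration_csv)
    compounds = {c.compound_id: c for c in read_compound_table(compounds_csv)}

    estimates: list[LoDEstimate] = []
    reasons, range_rows = [], []
    for s in series:
        res = estimate_all(
            s,
            config=config.estimator,
            min_replicates=config.min_replicates,
            min_area=config.min_area,
            blank_ratio=config.blank_ratio,
            rel_tol=config.rel_tol,
            min_levels=config.min_levels,
            min_points=config.min_points,
            r2_min=config.r2_min,
        )
        if res.excluded_reason:
            reasons.append(
                {"compound_id": s.compound_id, "stage": "exclusion",
                 "reason": res.excluded_reason}
            )
            continue
        for method, why in sorted(res.unavailable.items()):
            reasons.append(
                {"compound_id": s.compound_id, "stage": method, "reason": why}
            )
        estimates.extend(res.estimates)
        if res.range_result is not None:
            rr = res.range_result
            range_rows.append(
                {
                    "compound_id": s.compound_id,
                    "n_levels_in": int(rr.detected_levels.size),
                    "n_removed": rr.n_removed,
                    "slope_M_inv": rr.fit.slope,
                    "intercept": rr.fit.intercept,
                    "r2": rr.fit.r2,
                    "accepted": rr.accepted,
                }
            )
    if not estimates:
        raise WorkflowError(
            "no compound yielded any LoD estimate; see the per-compound reasons"
        )

    write_lod_table(estimates, out_dir / "lod_table.csv")
    pd.DataFrame(
        range_rows,
        columns=["compound_id", "n_levels_in", "n_removed", "slope_M_inv",
                 "intercept", "r2", "accepted"],
    ).sort_values("compound_id").to_csv(
        out_dir / "linear_range.csv", index=False, float_format=FLOAT_FMT
    )
    pd.DataFrame(
        reasons, columns=["compound_id", "stage", "reason"]
    ).sort_values(["compound_id", "stage"]).to_csv(out_dir / "reasons.csv", index=False)

    lod_df = pd.DataFrame(
        [{"compound_id": e.compound_id, "method": e.method, "lod_M": e.lod}
         for e in estimates]
    )

    # covariates: response factor (accepted slope) and corrected log IE
    rf_rows = [
        {"compound_id": r["compound_id"], "response_factor": r["slope_M_inv"]}
        for r in range_rows
        if r["accepted"]
    ]
    cov = pd.DataFrame(rf_rows, columns=["compound_id", "response_factor"])
    ie_rows = []
    for cid, rec in compounds.items():
        val = correct_log_ie(rec) if config.apply_isotope_correction else rec.log_ie
        ie_rows.append({"compound_id": cid, "log_ie": val})
    cov = cov.merge(pd.DataFrame(ie_rows), on="compound_id", how="outer")
    correlations = correlation_matrix(lod_df, cov)
    correlations.to_csv(out_dir / "correlations.csv", index=False, float_format=FLOAT_FMT)

    # transfer model on (log IE, log10 LoD) for the configured approach
    fit_df = lod_df[
        (lod_df["method"] == config.fit_lod_method) & (lod_df["lod_M"] > 0)
    ].merge(pd.DataFrame(ie_rows), on="compound_id", how="inner")
    if len(fit_df) < 3:
        raise WorkflowError(
            f"only {len(fit_df)} compounds with both a {config.fit_lod_method} LoD "
            "and a log IE value; cannot fit the transfer model"
        )
    model = fit_robust(
        fit_df["log_ie"].to_numpy(),
        np.log10(fit_df["lod_M"].to_numpy()),
        method=config.fit_method,
        label=config.model_label,
    )
    save_model(model, out_dir / "model.json")

    _write_manifest(
        out_dir,
        config,
        inputs={"calibration": str(calibration_csv), "compounds": str(compounds_csv)},
        outputs=["lod_table.csv", "linear_range.csv", "reasons.csv",
                 "correlations.csv", "model.json"],
    )
    return {
        "estimates": estimates,
        "linear_range": pd.DataFrame(range_rows),
        "correlations": correlations,
        "model": model,
        "reasons": pd.DataFrame(reasons, columns=["compound_id", "stage", "reason"]),
    }


def run_prediction_workflow(
    model_json,
    features_csv,
    out_dir,
    config: RunConfig = RunConfig(),
    ie_source: Optional[str] = None,
    force: bool = False,
) -> dict:
    """Predict per-feature LoDs and emit both priority directions.

    The lowest-LoD table lists identification candidates; the highest-LoD
    table lists likely false positives. Refuses to apply a model to a
    mismatched log IE source unless ``force``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model: RobustLine = load_model(model_json)
    if (
        model.label is not None
        and ie_source is not None
        and model.label != ie_source
        and not force
    ):
        raise ValidationError(
            f"model was fitted on {model.label!r} log IE but features use "
            f"{ie_source!r}; pass force=True to override"
        )
    features = read_feature_table(features_csv)
    lowest = prioritize(features, model, k=config.k, direction="lowest", force=force)
    highest = prioritize(features, model, k=config.k, direction="highest", force=force)

    feat_df = pd.DataFrame(
        [
            {"feature_id": f.feature_id, "mz": f.mz, "rt_min": f.rt,
             "log_ie": f.log_ie, "est_lod_M": f.est_lod}
            for f in features
        ]
    )
    feat_df.to_csv(out_dir / "features_est_lod.csv", index=False, float_format=FLOAT_FMT)
    lowest.table.to_csv(out_dir / "priorities_lowest.csv", index=False, float_format=FLOAT_FMT)
    highest.table.to_csv(out_dir / "priorities_highest.csv", index=False, float_format=FLOAT_FMT)
    _write_manifest(
        out_dir,
        config,
        inputs={"model": str(model_json), "features": str(features_csv)},
        outputs=["features_est_lod.csv", "priorities_lowest.csv", "priorities_highest.csv"],
    )
    return {"features": feat_df, "lowest": lowest, "highest": highest, "model": model}
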