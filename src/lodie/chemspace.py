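"""Chemical-space utilities: suspect-list pre-filter, PCA, and diversity selection.

Suspect lists are pre-filtered on composition (must contain carbon and
nitrogen or oxygen) and monoisotopic mass (>= 100 Da, neutral mass from
standard atomic masses) — compounds failing these are unlikely to be seen
with reversed-phase LC/ESI(+)/HRMS.

PCA is computed on the standardized descriptor matrix by SVD, with a
deterministic sign convention (the largest-|loading| entry of each
component is positive). The standardization record (per-column mean, SD,
dropped constant columns) is stored so new compound sets can be projected
into the same space by name-based column alignment.

Representative compounds are selected by greedy farthest-point (maximin)
sampling in the PC1-PC2 plane, seeded at the point farthest from the
centroid; ties go to the lexicographically smallest compound id.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mass as pmass

from .errors import ValidationError


@dataclass
class DescriptorMatrix:
    """Prepared descriptor matrix: no missing values, constant columns dropped."""

    compound_ids: list
    descriptor_names: list
    X: np.ndarray           # standardized values, rows = compounds
    means: np.ndarray
    sds: np.ndarray
    dropped: list           # constant columns removed before standardization


@dataclass
class PCAModel:
    loadings: pd.DataFrame              # descriptor x component
    explained_variance_ratio: np.ndarray
    means: pd.Series
    sds: pd.Series
    dropped: list


def monoisotopic_mass(formula: str) -> float:
    """Neutral monoisotopic mass (Da) from a Hill-style molecular formula."""
    try:
        comp = pmass.Composition(formula=formula)
    except Exception as exc:
        raise ValidationError(f"unparseable formula {formula!r}: {exc}") from exc
    if not comp:
        raise ValidationError(f"unparseable formula {formula!r}: empty composition")
    return float(pmass.calculate_mass(composition=comp))


def filter_suspects(
    records: pd.DataFrame, min_mass: float = 100.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain compounds containing C and (N or O) with monoisotopic mass >= min_mass.

    ``records`` needs columns compound_id and formula. Returns (retained,
    rejected); rejected rows carry a reason instead of crashing on a bad
    formula.
    """
    for col in ("compound_id", "formula"):
        if col not in records.columns:
            raise ValidationError(f"suspect table missing column {col!r}")
    kept, rejected = [], []
    for row in records.itertuples(index=False):
        try:
            comp = pmass.Composition(formula=str(row.formula))
            if not comp:
                raise ValidationError("empty composition")
            mono = float(pmass.calculate_mass(composition=comp))
        except Exception as exc:
            rejected.append(
                {"compound_id": row.compound_id, "formula": row.formula,
                 "reason": f"unparseable-formula: {exc}"}
            )
            continue
        if comp.get("C", 0) < 1:
            reason = "no-carbon"
        elif comp.get("N", 0) < 1 and comp.get("O", 0) < 1:
            reason = "no-nitrogen-or-oxygen"
        elif mono < min_mass:
            reason = f"mass-below-{min_mass:g}"
        else:
            kept.append(
                {"compound_id": row.compound_id, "formula": row.formula,
                 "monoisotopic_mass": mono}
            )
            continue
        rejected.append(
            {"compound_id": row.compound_id, "formula": row.formula, "reason": reason}
        )
    cols_k = ["compound_id", "formula", "monoisotopic_mass"]
    cols_r = ["compound_id", "formula", "reason"]
    return (
        pd.DataFrame(kept, columns=cols_k),
        pd.DataFrame(rejected, columns=cols_r),
    )


def prepare_matrix(df: pd.DataFrame) -> DescriptorMatrix:
    """Standardize a descriptor table (compound_id + numeric columns).

    Constant columns are dropped; remaining columns are scaled to zero mean
    and unit (sample) SD. Missing values are an error.
    """
    if "compound_id" not in df.columns:
        raise ValidationError("descriptor table missing column 'compound_id'")
    ids = df["compound_id"].tolist()
    X = df.drop(columns=["compound_id"]).astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValidationError(f"missing values in descriptor column(s) {bad}")
    sds_all = X.std(ddof=1)
    dropped = sds_all[sds_all == 0].index.tolist()
    X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        raise ValidationError("all descriptor columns are constant")
    means = X.mean()
    sds = X.std(ddof=1)
    Z = (X - means) / sds
    return DescriptorMatrix(
        compound_ids=ids,
        descriptor_names=X.columns.tolist(),
        X=Z.to_numpy(),
        means=means.to_numpy(),
        sds=sds.to_numpy(),
        dropped=dropped,
    )


def fit_pca(df: pd.DataFrame, n_components: int = 2) -> tuple[PCAModel, pd.DataFrame]:
    """PCA of the standardized descriptor matrix via SVD.

    Returns the model and the training scores (computed through the same
    projection path used for new data, so project(training) is bitwise
    identical).
    """
    prep = prepare_matrix(df)
    Z = prep.X
    n, p = Z.shape
    if n < 2:
        raise ValidationError("need at least 2 compounds for PCA")
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, p) * np.finfo(float).eps)) if s.size else 0
    if n_components > rank:
        raise ValidationError(f"n_components={n_components} exceeds matrix rank {rank}")
    V = Vt[:n_components].T  # p x k loadings
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    eigvals = s**2 / (n - 1)
    evr = (eigvals / eigvals.sum())[:n_components]
    loadings = pd.DataFrame(
        V,
        index=prep.descriptor_names,
        columns=[f"pc{j + 1}" for j in range(n_components)],
    )
    model = PCAModel(
        loadings=loadings,
        explained_variance_ratio=evr,
        means=pd.Series(prep.means, index=prep.descriptor_names),
        sds=pd.Series(prep.sds, index=prep.descriptor_names),
        dropped=prep.dropped,
    )
    scores = project(model, df)
    return model, scores


def project(model: PCAModel, df: pd.DataFrame) -> pd.DataFrame:
    """Project a compound table into a fitted PCA space.

    Columns are aligned by name (input order is irrelevant); a missing
    retained descriptor is an error naming the column.
    """
    if "compound_id" not in df.columns:
        raise ValidationError("descriptor table missing column 'compound_id'")
    needed = model.loadings.index
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"missing descriptor column(s) {missing}")
    X = df[needed].astype(float).to_numpy()
    Z = (X - model.means.to_numpy()) / model.sds.to_numpy()
    scores = Z @ model.loadings.to_numpy()
    out = pd.DataFrame(scores, columns=model.loadings.columns)
    out.insert(0, "compound_id", df["compound_id"].tolist())
    return out


def select_representatives(scores: pd.DataFrame, n: int) -> list:
    """Greedy maximin (farthest-point) selection in the PC1-PC2 plane.

    Returns compound ids in selection order. Deterministic: seeded at the
    point farthest from the centroid, ties broken by lowest compound_id.
    """
    for col in ("compound_id", "pc1", "pc2"):
        if col not in scores.columns:
            raise ValidationError(f"scores table missing column {col!r}")
    ids = scores["compound_id"].tolist()
    if n > len(ids):
        raise ValidationError(f"n={n} exceeds the {len(ids)} available compounds")
    # stable order by id so argmax tie-breaks on the lowest id
    order = np.argsort(np.asarray(ids, dtype=object), kind="stable")
    ids_sorted = [ids[i] for i in order]
    pts = scores[["pc1", "pc2"]].to_numpy(dtype=float)[order]

    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1)
    selected = [int(np.argmax(d))]
    min_dist = np.linalg.norm(pts - pts[selected[0]], axis=1)
    while len(selected) < n:
        min_dist[selected] = -np.inf
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, np.linalg.norm(pts - pts[nxt], axis=1))
    return [ids_sorted[i] for i in selected]
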