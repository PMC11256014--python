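"""Rank-based diagnostics: Spearman correlation and the Wilcoxon rank-sum test.

Spearman rho is the Pearson correlation of average (tie-adjusted) ranks.
For small samples (n <= permutation_cap, default 7) the p-value is exact:
all n! rank permutations are enumerated and the two-sided p is the fraction
with |rho| at least the observed one. Larger samples use the usual
t-approximation with n-2 degrees of freedom.

The rank-sum comparison is the Mann-Whitney U with tie-averaged ranks:
exact enumeration when n*m <= 400 and there are no ties, otherwise a normal
approximation with continuity correction (delegated to scipy).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass
class CorrelationReport:
    rho: float
    p_value: float
    n: int
    method: str  # "asymptotic-t" or "exact-permutation"


@dataclass
class RankSumReport:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    n: int
    m: int
    alternative: str
    method: str  # "exact" or "asymptotic"


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValidationError("constant vector: Spearman correlation undefined")
    return float(rx @ ry) / denom


def spearman(
    x: Sequence[float], y: Sequence[float], permutation_cap: int = 7
) -> CorrelationReport:
    """Spearman rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    n = int(x.size)
    if n < 3:
        raise ValidationError("need at least 3 pairs")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValidationError("non-finite values in input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_rho(rx, ry)

    if n <= permutation_cap:
        target = abs(rho) - 1e-12
        count = 0
        total = math.factorial(n)
        for perm in itertools.permutations(ry):
            if abs(_rank_rho(rx, np.asarray(perm))) >= target:
                count += 1
        return CorrelationReport(rho, count / total, n, "exact-permutation")

    if abs(rho) >= 1.0:
        return CorrelationReport(rho, 0.0, n, "asymptotic-t")
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationReport(rho, min(p, 1.0), n, "asymptotic-t")


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = 400,
) -> RankSumReport:
    """Mann-Whitney U comparison of two independent samples.

    ``alternative`` follows scipy: 'less' means the first sample is
    stochastically smaller.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    use_exact = (a.size * b.size <= exact_limit) and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    return RankSumReport(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(a.size),
        m=int(b.size),
        alternative=alternative,
        method=method,
    )


def correlation_matrix(
    lod_table: pd.DataFrame,
    covariates: pd.DataFrame,
    permutation_cap: int = 7,
) -> pd.DataFrame:
    """One Spearman report per (LoD method, covariate) pair.

    ``lod_table`` is long (compound_id, method, lod_M); ``covariates`` has
    a compound_id column plus one numeric column per covariate. Compounds
    are matched pairwise per cell; pairs with fewer than 3 compounds get
    NaN rho with test_variant 'insufficient'.
    """
    for col in ("compound_id", "method", "lod_M"):
        if col not in lod_table.columns:
            raise ValidationError(f"lod_table missing column {col!r}")
    if "compound_id" not in covariates.columns:
        raise ValidationError("covariates missing column 'compound_id'")
    cov_cols = [c for c in covariates.columns if c != "compound_id"]
    if not cov_cols:
        raise ValidationError("no covariate columns")
    if not set(lod_table["compound_id"]) & set(covariates["compound_id"]):
        raise ValidationError("no compounds in common between tables")

    rows = []
    for method in sorted(lod_table["method"].unique()):
        sub = lod_table[lod_table["method"] == method][["compound_id", "lod_M"]]
        merged = sub.merge(covariates, on="compound_id", how="inner")
        for cov in cov_cols:
            pair = merged[["lod_M", cov]].astype(float).dropna()
            if len(pair) < 3:
                rows.append(
                    {
                        "method": method,
                        "covariate": cov,
                        "n": len(pair),
                        "rho": float("nan"),
                        "p_value": float("nan"),
                        "test_variant": "insufficient",
                    }
                )
                continue
            rep = spearman(pair[cov], pair["lod_M"], permutation_cap=permutation_cap)
            rows.append(
                {
                    "method": method,
                    "covariate": cov,
                    "n": rep.n,
                    "rho": rep.rho,
                    "p_value": rep.p_value,
                    "test_variant": rep.method,
                }
            )
    return pd.DataFrame(rows)
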