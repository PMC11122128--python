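"""OLS p-value feature elimination.

A linear probability model ``label ~ intercept + features`` is fit by
ordinary least squares; each coefficient's two-sided p-value comes from its
t-statistic (coefficient over standard error) at n - q degrees of freedom.
Features with p above the threshold (default 0.05) are eliminated.  No
multiple-testing correction is applied — the raw threshold is the deliberate
selection rule.  Collinear columns are dropped (with a warning) before the
fit so the design matrix is full rank.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["ols_pvalues", "eliminate", "significance_report", "DEFAULT_ALPHA"]

DEFAULT_ALPHA = 0.05

#: columns of a feature table that are metadata, not features
META_COLUMNS = ("label", "sequence_id", "source", "group_id")


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def _full_rank_columns(X: np.ndarray, names: list[str]) -> list[int]:
    """Greedy left-to-right selection of a maximal independent column set
    (after the intercept)."""
    keep: list[int] = []
    n = X.shape[0]
    basis = np.ones((n, 1))
    for j in range(X.shape[1]):
        cand = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(cand) > basis.shape[1]:
            keep.append(j)
            basis = cand
        else:
            logger.warning("dropping collinear feature %r", names[j])
    return keep


def ols_pvalues(table: pd.DataFrame) -> pd.Series:
    """Per-feature p-values from a joint OLS fit of label on all features.

    Returns a Series indexed by feature name; collinear features that were
    dropped get p-value NaN (they carry no independent information).
    """
    feats = _feature_columns(table)
    y = table["label"].to_numpy(dtype=float)
    X = table[feats].to_numpy(dtype=float)
    n, q = X.shape
    if n < q + 2:
        raise ValueError(
            "fewer rows than features + intercept; use univariate_pvalues instead"
        )
    keep = _full_rank_columns(X, feats)
    design = sm.add_constant(X[:, keep], has_constant="add")
    res = sm.OLS(y, design).fit()
    pvals = pd.Series(np.nan, index=pd.Index(feats, name="feature"))
    pvals.iloc[keep] = res.pvalues[1:]
    return pvals


def univariate_pvalues(table: pd.DataFrame) -> pd.Series:
    """Fallback for wide tables (n < q): one OLS fit per feature."""
    feats = _feature_columns(table)
    y = table["label"].to_numpy(dtype=float)
    out = {}
    for f in feats:
        x = table[f].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            out[f] = np.nan
            continue
        design = sm.add_constant(x)
        out[f] = float(sm.OLS(y, design).fit().pvalues[1])
    return pd.Series(out, name="p_value").rename_axis("feature")


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def significance_report(
    table: pd.DataFrame, pvalues: pd.Series, method: str = "", domain: str = ""
) -> pd.DataFrame:
    """Per-feature class means/SDs and p-values, one row per feature."""
    pos = table["label"] == 1
    rows = []
    for f, p in pvalues.items():
        x = table[f].to_numpy(dtype=float)
        rows.append(
            {
                "method": method,
                "domain": domain,
                "feature": f,
                "mean_focus": float(x[pos].mean()),
                "sd_focus": float(x[pos].std(ddof=1)),
                "mean_notfocus": float(x[~pos].mean()),
                "sd_notfocus": float(x[~pos].std(ddof=1)),
                "p_value": float(p) if np.isfinite(p) else np.nan,
                "stars": _stars(p) if np.isfinite(p) else "",
            }
        )
    return pd.DataFrame(rows)


def eliminate(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    pvalues: pd.Series | None = None,
    method: str = "",
    domain: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep exactly the features with p <= alpha.

    Returns ``(reduced_table, report)``; metadata columns are preserved.
    Raises if no feature survives (the report is attached to the error).
    """
    if pvalues is None:
        pvalues = ols_pvalues(table)
    report = significance_report(table, pvalues, method=method, domain=domain)
    kept = [f for f, p in pvalues.items() if np.isfinite(p) and p <= alpha]
    if not kept:
        err = ValueError(f"no features retained at alpha={alpha}")
        err.report = report  # type: ignore[attr-defined]
        raise err
    meta = [c for c in META_COLUMNS if c in table.columns]
    return table[kept + meta].copy(), report
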