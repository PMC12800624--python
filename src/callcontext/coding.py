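"""Coefficient-of-variation coding indices and feature selection.

The Potential of Contextual Coding (PCC) of an acoustic feature is the
ratio of its between-context coefficient of variation to the mean of its
within-context coefficients of variation,

    CVw = 100 * (sd / mean) * (1 + 1/(4n))      (small-sample corrected)
    CVb = 100 * (sd / mean)                     (over the pooled sample)
    PCC = CVb / mean(CVw over contexts)

Features with PCC at or above 1 vary more between contexts than within
them and are candidates for discriminant analysis.  ``select_features``
applies the three-step screen: PCC threshold, Shapiro-Wilk normality,
then redundancy pruning by |Pearson r| clustering keeping one
representative (the median-type variant when one exists, else the
highest PCC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import shapiro

__all__ = [
    "UndefinedCVError",
    "EmptySelectionError",
    "cv_within",
    "cv_between",
    "pcc_index",
    "pcc_table",
    "balance_by_caller",
    "select_features",
]


class UndefinedCVError(ValueError):
    """CV is undefined: nonpositive mean or degenerate sample."""


class EmptySelectionError(RuntimeError):
    """No feature survived the three-step selection."""


def cv_within(values: Sequence[float], n: int | None = None) -> float:
    """Small-sample-corrected within-group CV in percent.

    ``n`` defaults to ``len(values)``; sd uses denominator n-1.
    """
    x = np.asarray(values, dtype=float)
    n = len(x) if n is None else n
    if n < 2:
        raise UndefinedCVError("within-group CV needs n >= 2")
    mean = x.mean()
    if mean <= 0:
        raise UndefinedCVError(f"nonpositive group mean {mean:.4g}")
    return 100.0 * (x.std(ddof=1) / mean) * (1.0 + 1.0 / (4.0 * n))


def cv_between(values: Sequence[float]) -> float:
    """Between-group CV in percent over the pooled sample (sd denominator n-1)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise UndefinedCVError("between-group CV needs n >= 2")
    mean = x.mean()
    if mean <= 0:
        raise UndefinedCVError(f"nonpositive pooled mean {mean:.4g}")
    return 100.0 * (x.std(ddof=1) / mean)


def pcc_index(groups: Mapping[str, Sequence[float]]) -> dict[str, float | int | dict]:
    """PCC for one feature from its per-context value groups.

    Returns a dict row with ``cvb``, ``mean_cvw``, per-context CVw and n,
    ``pcc`` and ``n_total``.  Raises :class:`UndefinedCVError` on
    degenerate input (caller flags and excludes the feature).
    """
    if len(groups) < 2:
        raise UndefinedCVError("PCC needs at least 2 contexts")
    cvw: dict[str, float] = {}
    ns: dict[str, int] = {}
    pooled: list[float] = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            raise UndefinedCVError(f"context {name!r} has fewer than 2 observations")
        cvw[name] = cv_within(vals)
        ns[name] = len(vals)
        pooled.extend(vals.tolist())
    cvb = cv_between(pooled)
    mean_cvw = float(np.mean(list(cvw.values())))  # unweighted across contexts
    if mean_cvw == 0:
        raise UndefinedCVError("all within-context CVs are zero (constant feature)")
    return {
        "cvb": cvb,
        "mean_cvw": mean_cvw,
        "cvw_by_context": cvw,
        "n_by_context": ns,
        "pcc": cvb / mean_cvw,
        "n_total": len(pooled),
    }


def pcc_table(table: pd.DataFrame, features: Sequence[str], context_col: str = "context") -> pd.DataFrame:
    """PCC rows for each feature; undefined features get NaN and a flag."""
    rows = []
    for feat in features:
        groups = {c: g[feat].dropna().to_numpy() for c, g in table.groupby(context_col)}
        try:
            row = pcc_index(groups)
            rows.append(
                {
                    "feature": feat,
                    "cvb": row["cvb"],
                    "mean_cvw": row["mean_cvw"],
                    "pcc": row["pcc"],
                    "n_total": row["n_total"],
                    "defined": True,
                    "note": "",
                }
            )
        except UndefinedCVError as exc:
            rows.append(
                {
                    "feature": feat,
                    "cvb": np.nan,
                    "mean_cvw": np.nan,
                    "pcc": np.nan,
                    "n_total": int(table[feat].notna().sum()),
                    "defined": False,
                    "note": str(exc),
                }
            )
    return pd.DataFrame(rows)


def balance_by_caller(
    table: pd.DataFrame,
    max_per_caller_per_context: int,
    seed: int = 0,
    caller_col: str = "caller_id",
    context_col: str = "context",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cap each (caller, context) cell, sampling without replacement.

    Equalizing caller contributions keeps any one individual from
    dominating a context and biasing the PCC/DFA.  Returns the balanced
    table and a report of removed rows.
    """
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    keep_idx: list[int] = []
    removed = []
    for (caller, context), grp in table.groupby([caller_col, context_col], sort=True):
        if len(grp) <= max_per_caller_per_context:
            keep_idx.extend(grp.index.tolist())
        else:
            chosen = rng.choice(grp.index.to_numpy(), size=max_per_caller_per_context, replace=False)
            keep_idx.extend(chosen.tolist())
            for i in set(grp.index) - set(chosen.tolist()):
                removed.append({"index": i, "caller_id": caller, "context": context})
    balanced = table.loc[sorted(keep_idx)].reset_index(drop=True)
    return balanced, pd.DataFrame(removed, columns=["index", "caller_id", "context"])


def _representative(cluster_feats: list[str], pcc_map: Mapping[str, float]) -> str:
    """Median-type variant of a {mean, median, sd} family wins; else top PCC."""
    medians = [f for f in cluster_feats if "median" in f]
    pool = medians if medians else cluster_feats
    return max(pool, key=lambda f: (pcc_map.get(f, -np.inf), f))


def select_features(
    table: pd.DataFrame,
    features: Sequence[str],
    pcc_threshold: float = 1.0,
    alpha_normality: float = 0.05,
    redundancy_r: float = 0.9,
    context_col: str = "context",
    normality_scope: str = "pooled",
) -> pd.DataFrame:
    """Three-step feature screen with a full per-feature audit trail.

    Steps: (i) keep PCC >= ``pcc_threshold``; (ii) drop features whose
    Shapiro-Wilk p (pooled by default, smallest per-context p with
    ``normality_scope="per_context"``) falls below ``alpha_normality``;
    (iii) single-linkage cluster survivors at |Pearson r| >=
    ``redundancy_r`` and keep one representative per cluster.

    Returns a DataFrame with one row per input feature and columns
    ``pcc, passed_pcc, shapiro_p, passed_normality, cluster_id,
    is_representative, retained, rationale``.  Raises
    :class:`EmptySelectionError` when nothing survives.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 candidate features")
    ptab = pcc_table(table, features, context_col=context_col).set_index("feature")
    report = pd.DataFrame(index=pd.Index(features, name="feature"))
    report["pcc"] = ptab["pcc"]
    report["passed_pcc"] = ptab["defined"] & (ptab["pcc"] >= pcc_threshold)
    report["shapiro_p"] = np.nan
    report["passed_normality"] = False
    report["cluster_id"] = -1
    report["is_representative"] = False
    report["rationale"] = [
        f"undefined CV: {note}" if not d else ""
        for d, note in zip(ptab["defined"], ptab["note"])
    ]

    survivors = [f for f in features if report.loc[f, "passed_pcc"]]
    for f in features:
        if f not in survivors and not report.loc[f, "rationale"]:
            report.loc[f, "rationale"] = f"PCC {report.loc[f, 'pcc']:.3f} below threshold {pcc_threshold}"

    # step (ii): normality
    normal: list[str] = []
    for f in survivors:
        vals = table[f].dropna().to_numpy()
        if normality_scope == "per_context":
            ps = [
                shapiro(g[f].dropna()).pvalue
                for _, g in table.groupby(context_col)
                if g[f].notna().sum() >= 3
            ]
            p = float(min(ps)) if ps else np.nan
        else:
            p = float(shapiro(vals).pvalue) if len(vals) >= 3 else np.nan
        report.loc[f, "shapiro_p"] = p
        if np.isnan(p) or p < alpha_normality:
            report.loc[f, "rationale"] = f"failed normality (Shapiro-Wilk p={p:.4g})"
        else:
            report.loc[f, "passed_normality"] = True
            normal.append(f)

    # step (iii): redundancy clustering on |r|
    if normal:
        if len(normal) == 1:
            report.loc[normal[0], ["cluster_id", "is_representative"]] = 0, True
        else:
            sub = table[normal].dropna()
            corr = np.abs(np.corrcoef(sub.to_numpy(), rowvar=False))
            corr = np.nan_to_num(corr, nan=0.0)
            np.fill_diagonal(corr, 1.0)
            dist = squareform(1.0 - corr, checks=False)
            clusters = fcluster(linkage(dist, method="single"), t=1.0 - redundancy_r, criterion="distance")
            pcc_map = report["pcc"].to_dict()
            for cid in np.unique(clusters):
                members = [f for f, c in zip(normal, clusters) if c == cid]
                rep = _representative(members, pcc_map)
                for f in members:
                    report.loc[f, "cluster_id"] = int(cid)
                    report.loc[f, "is_representative"] = f == rep
                    if f != rep:
                        report.loc[f, "rationale"] = f"redundant with {rep} (|r| >= {redundancy_r})"

    report["retained"] = report["passed_pcc"] & report["passed_normality"] & report["is_representative"]
    report.loc[report["retained"], "rationale"] = "retained"
    if not report["retained"].any():
        raise EmptySelectionError("no feature survived PCC, normality and redundancy screening")
    return report.reset_index()
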