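"""Linear discriminant classification of calls with LOOCV and exact
binomial assessment against class-proportion chance.

The classifier is the canonical linear discriminant: pooled within-class
covariance (denominator N - g), discriminant axes from the eigenvectors
of W^-1 B scaled to unit within-class variance, and assignment to the
class minimizing Mahalanobis distance adjusted by log prior.  Accuracy
is assessed per class against that class's sample proportion and pooled
against 1/g with exact binomial tail sums computed in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import pearsonr

log = logging.getLogger(__name__)

__all__ = [
    "DfaModel",
    "LoocvResult",
    "fit_dfa",
    "classify_loocv",
    "nested_select_classify_loocv",
    "chance_probabilities",
    "binomial_test",
    "assess_classification",
    "contribution_matrix",
]

_RIDGE_CONDITION_LIMIT = 1e10
_RIDGE_EPS = 1e-8


@dataclass
class DfaModel:
    classes: list[str]
    features: list[str]
    class_means: np.ndarray  # (g, p)
    grand_mean: np.ndarray  # (p,)
    pooled_cov: np.ndarray  # (p, p), possibly ridge-regularized
    pooled_cov_inv: np.ndarray
    priors: np.ndarray  # (g,)
    scaling: np.ndarray  # (p, g-1) discriminant axes, unit within-class variance
    eigenvalues: np.ndarray  # (g-1,)
    ridged: bool

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project rows onto the discriminant axes (LD scores)."""
        return (np.asarray(X, dtype=float) - self.grand_mean) @ self.scaling

    def predict(self, X: np.ndarray) -> list[str]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = np.stack(
            [
                np.einsum("ij,jk,ik->i", X - m, self.pooled_cov_inv, X - m)
                for m in self.class_means
            ],
            axis=1,
        )
        score = -0.5 * d2 + np.log(self.priors)[None, :]
        # ties broken toward the lowest class index (stable argmax)
        return [self.classes[int(np.argmax(s))] for s in score]


@dataclass
class LoocvResult:
    table: pd.DataFrame  # per call: call_id, true, predicted, ld scores
    confusion: pd.DataFrame  # true x predicted counts
    per_class_correct: pd.Series
    total_correct: float
    n_excluded_folds: int = 0


def fit_dfa(
    table: pd.DataFrame,
    features: Sequence[str],
    label_col: str = "context",
    priors: Literal["uniform", "proportional"] = "uniform",
) -> DfaModel:
    """Fit the canonical linear discriminant on complete numeric features."""
    features = list(features)
    sub = table[features + [label_col]].dropna()
    if len(sub) < len(table):
        raise ValueError(f"{len(table) - len(sub)} rows have missing feature values")
    X = sub[features].to_numpy(dtype=float)
    y = sub[label_col].to_numpy()
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = np.array([(y == c).sum() for c in classes])
    if (counts <= 1).any():
        bad = [c for c, n in zip(classes, counts) if n <= 1]
        raise ValueError(f"class(es) with <= 1 row: {bad}")
    g, p, n = len(classes), X.shape[1], X.shape[0]

    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    for c, m in zip(classes, means):
        d = X[y == c] - m
        W += d.T @ d
    W /= n - g
    B = np.zeros((p, p))
    for m, nk in zip(means, counts):
        d = (m - grand)[:, None]
        B += nk * (d @ d.T)
    B /= max(1, g - 1)

    ridged = False
    # scale-invariant conditioning check: correlation form of W
    d = np.sqrt(np.clip(np.diag(W), np.finfo(float).tiny, None))
    cond = np.linalg.cond(W / np.outer(d, d))
    if not np.isfinite(cond) or cond > _RIDGE_CONDITION_LIMIT:
        ridge = _RIDGE_EPS * np.mean(np.diag(W))
        W = W + ridge * np.eye(p)
        ridged = True
        log.warning("near-singular pooled covariance (cond=%.3g): ridge %.3g added", cond, ridge)

    evals, evecs = np.linalg.eig(np.linalg.solve(W, B))
    order = np.argsort(evals.real)[::-1][: g - 1]
    axes = evecs[:, order].real
    evals = evals[order].real
    # scale axes to unit pooled within-class variance (R lda convention)
    for j in range(axes.shape[1]):
        s = float(axes[:, j] @ W @ axes[:, j])
        if s > 0:
            axes[:, j] = axes[:, j] / np.sqrt(s)

    pr = np.full(g, 1.0 / g) if priors == "uniform" else counts / n
    return DfaModel(
        classes=classes,
        features=features,
        class_means=means,
        grand_mean=grand,
        pooled_cov=W,
        pooled_cov_inv=np.linalg.inv(W),
        priors=pr,
        scaling=axes,
        eigenvalues=evals,
        ridged=ridged,
    )


def classify_loocv(
    table: pd.DataFrame,
    features: Sequence[str],
    label_col: str = "context",
    id_col: str = "call_id",
    priors: Literal["uniform", "proportional"] = "uniform",
) -> LoocvResult:
    """Leave-one-out: refit on n-1 rows, predict and score the held-out row.

    Folds whose removal empties a class are flagged and excluded from the
    denominators.
    """
    features = list(features)
    sub = table.reset_index(drop=True)
    classes = sorted(sub[label_col].unique())
    rows = []
    excluded = 0
    for i in range(len(sub)):
        train = sub.drop(index=i)
        held = sub.loc[[i]]
        if (train[label_col].value_counts().reindex(classes).fillna(0) <= 1).any():
            excluded += 1
            log.warning("fold %d excluded: removing the row leaves a class with <= 1 member", i)
            continue
        model = fit_dfa(train, features, label_col=label_col, priors=priors)
        x = held[features].to_numpy(dtype=float)
        pred = model.predict(x)[0]
        scores = model.transform(x)[0]
        row = {
            id_col: held[id_col].iloc[0] if id_col in held else i,
            "true": held[label_col].iloc[0],
            "predicted": pred,
        }
        row.update({f"ld{j + 1}": float(s) for j, s in enumerate(scores)})
        rows.append(row)
    result = pd.DataFrame(rows)
    if result.empty:
        raise ValueError("every fold was excluded; dataset too small for LOOCV")
    confusion = pd.crosstab(result["true"], result["predicted"]).reindex(
        index=classes, columns=classes, fill_value=0
    )
    per_class = pd.Series(
        {c: (confusion.loc[c, c] / confusion.loc[c].sum()) if confusion.loc[c].sum() else np.nan for c in classes}
    )
    total = float(np.trace(confusion.to_numpy()) / confusion.to_numpy().sum())
    return LoocvResult(
        table=result,
        confusion=confusion,
        per_class_correct=per_class,
        total_correct=total,
        n_excluded_folds=excluded,
    )


def chance_probabilities(labels: Sequence[str]) -> dict[str, float]:
    """Class-proportion chance per class plus pooled 1/g chance."""
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be nonempty")
    classes = sorted(set(labels))
    n = len(labels)
    out = {c: labels.count(c) / n for c in classes}
    out["pooled"] = 1.0 / len(classes)
    return out


def _log_binom_pmf(k: np.ndarray, n: int, p0: float) -> np.ndarray:
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * np.log(p0)
        + (n - k) * np.log1p(-p0)
    )


def binomial_test(
    k: int, n: int, p0: float, alternative: Literal["greater", "two_sided"] = "greater"
) -> dict[str, float]:
    """Exact binomial test by explicit tail summation via log-gamma.

    ``greater``: P(X >= k).  ``two_sided``: sum of P(X = j) over all j
    whose probability does not exceed P(X = k) (the minlike convention,
    with a 1 + 1e-7 relative tolerance on the comparison).
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("need 0 < p0 < 1")
    ks = np.arange(n + 1)
    logpmf = _log_binom_pmf(ks, n, p0)
    if alternative == "greater":
        tail = logpmf[k:]
        m = tail.max()
        p = float(np.exp(m) * np.sum(np.exp(tail - m)))
    elif alternative == "two_sided":
        cutoff = logpmf[k] + np.log1p(1e-7)
        sel = logpmf[logpmf <= cutoff]
        m = sel.max()
        p = float(np.exp(m) * np.sum(np.exp(sel - m)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return {"k": k, "n": n, "p0": p0, "alternative": alternative, "p_value": min(1.0, p)}


def assess_classification(
    loocv: LoocvResult,
    alternative: Literal["greater", "two_sided"] = "greater",
) -> pd.DataFrame:
    """Binomial tests per class (against class-proportion chance) and pooled.

    Chance probabilities come from the observed label proportions, so the
    assessment is against proportional chance regardless of the priors
    used by the classifier.
    """
    labels = loocv.table["true"].tolist()
    chance = chance_probabilities(labels)
    rows = []
    for c in loocv.confusion.index:
        n_c = int(loocv.confusion.loc[c].sum())
        k_c = int(loocv.confusion.loc[c, c])
        rows.append({"test": c, **binomial_test(k_c, n_c, chance[c], alternative)})
    n_tot = int(loocv.confusion.to_numpy().sum())
    k_tot = int(np.trace(loocv.confusion.to_numpy()))
    rows.append({"test": "pooled", **binomial_test(k_tot, n_tot, chance["pooled"], alternative)})
    return pd.DataFrame(rows)


def nested_select_classify_loocv(
    table: pd.DataFrame,
    candidate_features: Sequence[str],
    label_col: str = "context",
    id_col: str = "call_id",
    priors: Literal["uniform", "proportional"] = "uniform",
    **selection_kwargs,
) -> LoocvResult:
    """LOOCV with feature selection nested inside each fold.

    Selecting features on the full dataset and then cross-validating only
    the classifier leaks the held-out call into the feature choice and
    inflates the type-I rate of the chance-anchored binomial test; this
    variant re-runs the three-step screen on every training fold, so the
    held-out call influences neither the panel nor the fit.  Folds whose
    training data yield no surviving feature predict the training
    majority class (a chance-level fallback).
    """
    from .coding import EmptySelectionError, select_features

    sub = table.reset_index(drop=True)
    classes = sorted(sub[label_col].unique())
    rows = []
    excluded = 0
    for i in range(len(sub)):
        train = sub.drop(index=i)
        held = sub.loc[[i]]
        if (train[label_col].value_counts().reindex(classes).fillna(0) <= 1).any():
            excluded += 1
            continue
        try:
            report = select_features(train, list(candidate_features), **selection_kwargs)
            feats = report.loc[report["retained"], "feature"].tolist()
        except EmptySelectionError:
            feats = []
        if feats:
            model = fit_dfa(train, feats, label_col=label_col, priors=priors)
            pred = model.predict(held[feats].to_numpy(dtype=float))[0]
        else:
            pred = train[label_col].mode().iloc[0]
        rows.append(
            {
                id_col: held[id_col].iloc[0] if id_col in held else i,
                "true": held[label_col].iloc[0],
                "predicted": pred,
                "n_features": len(feats),
            }
        )
    result = pd.DataFrame(rows)
    confusion = pd.crosstab(result["true"], result["predicted"]).reindex(
        index=classes, columns=classes, fill_value=0
    )
    per_class = pd.Series(
        {c: (confusion.loc[c, c] / confusion.loc[c].sum()) if confusion.loc[c].sum() else np.nan for c in classes}
    )
    total = float(np.trace(confusion.to_numpy()) / confusion.to_numpy().sum())
    return LoocvResult(
        table=result,
        confusion=confusion,
        per_class_correct=per_class,
        total_correct=total,
        n_excluded_folds=excluded,
    )


def contribution_matrix(
    table: pd.DataFrame,
    features: Sequence[str],
    scores: pd.DataFrame | np.ndarray,
) -> pd.DataFrame:
    """Pearson r of each feature with each discriminant axis, long format.

    ``scores`` holds one column per axis (full-data fit scores by
    default; held-out LOOCV scores may be passed instead).  Zero-variance
    features yield missing r with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    rows = []
    for feat in features:
        x = table[feat].to_numpy(dtype=float)
        for j in range(scores.shape[1]):
            if np.std(x) == 0 or np.std(scores[:, j]) == 0:
                log.warning("zero-variance input for %s vs axis %d: r undefined", feat, j + 1)
                r = np.nan
            else:
                r = float(pearsonr(x, scores[:, j])[0])
            rows.append({"feature": feat, "axis": f"LD{j + 1}", "r": r})
    return pd.DataFrame(rows)
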