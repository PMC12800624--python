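"""Mixed models for the playback-experiment responses.

Four generalized linear mixed models with a subject random intercept:

* Model 1 — gaze difference (after - before), zero-inflated Poisson;
* Model 2 — self-directed-behavior difference, zero-inflated Poisson;
* Model 3 — yawn presence in the 3-min window, Bernoulli/logit;
* Model 4 — yawn presence on the grooming subset restricted to
  high-social-yawn vs grunt stimuli, Bernoulli/logit.

The marginal likelihood integrates the random intercept out with
Gauss-Hermite quadrature (order 20 by default) and is maximized by
L-BFGS-B from GLM starting values with jittered restarts.  Zero
inflation is intercept-only on the logit scale.  Model significance is
the likelihood-ratio test of the full model against the control model
(random intercept + control terms only); pairwise contrasts use
delta-method standard errors with Bonferroni (default) or Tukey
adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, studentized_range

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "MixedFit",
    "LrtResult",
    "model_spec",
    "response_differences",
    "filter_model4",
    "build_design",
    "fit_zip_mixed",
    "fit_logistic_mixed",
    "fit_model",
    "likelihood_ratio_test",
    "pairwise_contrasts",
    "vif",
]

#: categorical level orders; the first level present in the data is the
#: dummy-coding baseline (grunt when present, else high_social).
LEVEL_ORDERS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "receiver_context": ("non_social", "social"),
    "trigger_context": ("grunt", "high_social", "low_social", "non_social"),
}
NUMERIC_TERMS = ("trial_order", "gaze_diff")

SEPARATION_BETA_LIMIT = 15.0


@dataclass(frozen=True)
class ModelSpec:
    """Which response, family and terms a model uses.

    ``control_terms`` appear in both the full and the control model;
    ``tested_terms`` only in the full model.
    """

    name: str
    response: str
    family: Literal["zip", "binomial"]
    tested_terms: tuple[str, ...]
    control_terms: tuple[str, ...]
    group_col: str = "subject_id"

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        return self.tested_terms + self.control_terms


def model_spec(model: int) -> ModelSpec:
    """Presets for the four playback models."""
    if model == 1:
        return ModelSpec("model1", "gaze_diff", "zip", ("sex", "receiver_context", "trigger_context"), ("trial_order",))
    if model == 2:
        return ModelSpec("model2", "sdb_diff", "zip", ("sex", "receiver_context", "trigger_context"), ("trial_order",))
    if model == 3:
        return ModelSpec(
            "model3", "yawn_after", "binomial", ("sex", "receiver_context", "trigger_context"), ("trial_order", "gaze_diff")
        )
    if model == 4:
        return ModelSpec("model4", "yawn_after", "binomial", ("trigger_context",), ("sex", "trial_order"))
    raise ValueError("model must be 1, 2, 3 or 4")


def response_differences(trials: pd.DataFrame) -> pd.DataFrame:
    """Derive gaze/SDB after-minus-before differences and the yawn response.

    Rows with missing counts are dropped with a logged reason.
    """
    needed = ["gazes_before", "gazes_after", "sdb_before", "sdb_after", "yawn_after"]
    ok = trials[needed].notna().all(axis=1)
    if (~ok).any():
        for i in trials.index[~ok]:
            log.warning("row %s rejected: missing before/after counts", i)
    out = trials[ok].copy()
    out["gaze_diff"] = out["gazes_after"] - out["gazes_before"]
    out["sdb_diff"] = out["sdb_after"] - out["sdb_before"]
    return out


def filter_model4(trials: pd.DataFrame) -> pd.DataFrame:
    """Grooming-context sessions with high-social yawn or grunt stimuli only."""
    mask = (trials["receiver_context"] == "social") & trials["trigger_context"].isin(["grunt", "high_social"])
    return trials[mask].copy()


def build_design(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Model matrix with intercept; categoricals dummy-coded against the
    first level (in :data:`LEVEL_ORDERS`) present in the data."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(data))}
    baselines: dict[str, str] = {}
    for term in terms:
        if term in LEVEL_ORDERS:
            present = [lv for lv in LEVEL_ORDERS[term] if lv in set(data[term])]
            unknown = set(data[term]) - set(LEVEL_ORDERS[term])
            if unknown:
                raise ValueError(f"unknown level(s) {sorted(unknown)} for {term}")
            baselines[term] = present[0]
            for lv in present[1:]:
                cols[f"{term}[{lv}]"] = (data[term] == lv).to_numpy(dtype=float)
        else:
            cols[term] = data[term].to_numpy(dtype=float)
    out = pd.DataFrame(cols, index=data.index)
    out.attrs["baselines"] = baselines
    return out


@dataclass
class MixedFit:
    spec: ModelSpec
    beta: pd.Series
    zi_logit: float | None
    sigma_b: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    quadrature_order: int
    cov: pd.DataFrame  # fixed-effect covariance (delta-method basis)
    gradient_norm: float
    separation_suspected: bool = False
    baselines: dict[str, str] = field(default_factory=dict)

    @property
    def zi_prob(self) -> float | None:
        return None if self.zi_logit is None else float(expit(self.zi_logit))

    @property
    def n_params(self) -> int:
        return len(self.beta) + (0 if self.zi_logit is None else 1) + 1


@dataclass(frozen=True)
class LrtResult:
    chi2: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# marginal likelihood


def _group_index(groups: pd.Series) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(groups, sort=True)
    return codes, len(uniques)


def _loglik_factory(y: np.ndarray, X: np.ndarray, codes: np.ndarray, n_groups: int, family: str, order: int):
    """Adaptive Gauss-Hermite marginal log-likelihood.

    Quadrature nodes are recentered at each group's conditional posterior
    mode and rescaled by its curvature (lme4's nAGQ scheme); this keeps
    even order ~20 accurate when group posteriors are narrow relative to
    the random-intercept scale.
    """
    nodes, weights = hermgauss(order)
    log_w_exp = np.log(weights) + nodes**2  # stays O(1) for all nodes
    sqrt2 = np.sqrt(2.0)
    p = X.shape[1]
    is_zero = y == 0
    lgamma_y = gammaln(y + 1)

    def obs_loglik(lin: np.ndarray, log_pi: float, log_1mpi: float) -> np.ndarray:
        shape = (-1,) + (1,) * (lin.ndim - 1)
        with np.errstate(over="ignore", invalid="ignore"):
            if family == "zip":
                pois = y.reshape(shape) * lin - np.exp(lin) - lgamma_y.reshape(shape)
                return np.where(
                    is_zero.reshape(shape),
                    np.logaddexp(log_pi, log_1mpi + pois),
                    log_1mpi + pois,
                )
            return np.where(y.reshape(shape) == 1, -np.logaddexp(0.0, -lin), -np.logaddexp(0.0, lin))

    def obs_derivs(lin: np.ndarray, gamma: float) -> tuple[np.ndarray, np.ndarray]:
        """d/db and d2/db2 of each observation's log-likelihood."""
        with np.errstate(over="ignore", invalid="ignore"):
            if family == "zip":
                lam = np.exp(np.clip(lin, -700.0, 50.0))
                d1 = y - lam
                d2 = -lam
                # zero observations mix with the structural-zero mass:
                # w = P(zero came from the Poisson component | y=0, b)
                #   = 1 / (1 + (pi/(1-pi)) e^lam) = expit(-(gamma + lam))
                w = expit(-(gamma + lam))
                d1 = np.where(is_zero, -w * lam, d1)
                d2 = np.where(is_zero, -w * lam * (1.0 - (1.0 - w) * lam), d2)
                return d1, d2
            pr = expit(lin)
            return y - pr, -pr * (1.0 - pr)

    def negloglik(params: np.ndarray) -> float:
        beta = params[:p]
        if family == "zip":
            gamma = params[p]
            log_pi = -np.logaddexp(0.0, -gamma)
            log_1mpi = -np.logaddexp(0.0, gamma)
        else:
            gamma = -np.inf  # no structural zeros
            log_pi = log_1mpi = 0.0
        sigma = float(params[-1])  # bounded >= 0 by the optimizer
        eta = X @ beta

        if sigma < 1e-8:  # random effect vanished: plain fixed-effect sum
            return -float(obs_loglik(eta, log_pi, log_1mpi).sum())

        # damped Newton for each group's conditional posterior mode
        b = np.zeros(n_groups)
        g2 = np.full(n_groups, -1.0 / sigma**2)
        for _ in range(40):
            d1o, d2o = obs_derivs(eta + b[codes], gamma)
            g1 = np.zeros(n_groups)
            g2 = np.zeros(n_groups)
            np.add.at(g1, codes, d1o)
            np.add.at(g2, codes, d2o)
            g1 -= b / sigma**2
            g2 -= 1.0 / sigma**2
            g2 = np.minimum(g2, -1e-10)
            step = np.clip(-g1 / g2, -1.0, 1.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-11:
                break
        s_hat = 1.0 / np.sqrt(-g2)

        t = b[:, None] + sqrt2 * s_hat[:, None] * nodes[None, :]  # (G, q)
        lin = eta[:, None] + t[codes]  # (n, q)
        group_ll = np.zeros((n_groups, order))
        np.add.at(group_ll, codes, obs_loglik(lin, log_pi, log_1mpi))
        integrand = group_ll - t**2 / (2.0 * sigma**2) + log_w_exp[None, :]
        total = (
            logsumexp(integrand, axis=1)
            + np.log(sqrt2 * s_hat)
            - 0.5 * np.log(2.0 * np.pi * sigma**2)
        ).sum()
        return -float(total)

    return negloglik


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    hs = eps * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = hs[i]
            ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * hs[i] * hs[j])
    return H


def _glm_start(y: np.ndarray, X: np.ndarray, family: str) -> np.ndarray:
    """Fixed-effect starting values from the corresponding plain GLM."""
    import statsmodels.api as sm

    try:
        if family == "zip":
            model = sm.GLM(y, X, family=sm.families.Poisson())
        else:
            model = sm.GLM(y, X, family=sm.families.Binomial())
        with np.errstate(all="ignore"):
            return np.asarray(model.fit(maxiter=100).params, dtype=float)
    except Exception:  # pragma: no cover - degenerate start fallback
        return np.zeros(X.shape[1])


def _fit_mixed(
    spec: ModelSpec,
    data: pd.DataFrame,
    quadrature_order: int,
    restarts: int = 3,
    seed: int = 0,
) -> MixedFit:
    design = build_design(data, spec.fixed_terms)
    y = data[spec.response].to_numpy(dtype=float)
    if spec.family == "zip":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError(
                "zero-inflated Poisson requires nonnegative integer responses; "
                "negative differences need the floor-at-zero preprocessing (gaze_mode='floor0')"
            )
    else:
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("binomial family requires a binary response")
    codes, n_groups = _group_index(data[spec.group_col])
    if n_groups < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    X = design.to_numpy(dtype=float)
    p = X.shape[1]
    negloglik = _loglik_factory(y, X, codes, n_groups, spec.family, quadrature_order)

    beta0 = _glm_start(y.astype(int) if spec.family == "binomial" else y, X, spec.family)
    extra0 = []
    if spec.family == "zip":
        frac0 = float(np.mean(y == 0))
        extra0.append(np.log(max(0.05, frac0 / 2) / (1 - max(0.05, frac0 / 2))))
    extra0.append(0.3)  # sigma_b start
    x0 = np.concatenate([beta0, extra0])
    bounds = [(None, None)] * (len(x0) - 1) + [(0.0, None)]

    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    best = None
    for attempt in range(restarts):
        if attempt == 0:
            start = x0
        else:
            start = x0 + rng.normal(0, 0.3, size=len(x0))
            start[-1] = abs(start[-1])
        res = optimize.minimize(
            negloglik,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    assert best is not None
    params = best.x
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
    converged = bool(best.success)
    if not converged:
        log.warning("%s: optimizer did not converge (gradient norm %.3g)", spec.name, grad_norm)

    beta = pd.Series(params[:p], index=design.columns)
    zi_logit = float(params[p]) if spec.family == "zip" else None
    sigma_b = float(params[-1])
    if sigma_b < 1e-4:
        log.info("%s: singular fit, random-intercept SD ~ 0", spec.name)

    separation = bool(spec.family == "binomial" and np.any(np.abs(beta.to_numpy()) > SEPARATION_BETA_LIMIT))
    if separation:
        log.warning("%s: |beta| > %.0f suggests complete separation", spec.name, SEPARATION_BETA_LIMIT)

    # covariance of the fixed effects from the numeric Hessian at the optimum
    H = _numeric_hessian(negloglik, params)
    try:
        cov_all = np.linalg.inv(H)
        cov_beta = cov_all[:p, :p]
        if np.any(np.diag(cov_beta) < 0):
            raise np.linalg.LinAlgError("negative variance")
    except np.linalg.LinAlgError:
        log.warning("%s: Hessian not positive definite; SEs unavailable", spec.name)
        cov_beta = np.full((p, p), np.nan)
    cov = pd.DataFrame(cov_beta, index=design.columns, columns=design.columns)

    return MixedFit(
        spec=spec,
        beta=beta,
        zi_logit=zi_logit,
        sigma_b=sigma_b,
        loglik=-float(best.fun),
        converged=converged,
        n_obs=len(y),
        n_groups=n_groups,
        quadrature_order=quadrature_order,
        cov=cov,
        gradient_norm=grad_norm,
        separation_suspected=separation,
        baselines=dict(design.attrs.get("baselines", {})),
    )


def marginal_loglik(fit: MixedFit, data: pd.DataFrame, quadrature_order: int | None = None) -> float:
    """Re-evaluate a fit's marginal log-likelihood, optionally at a
    different quadrature order (integration-accuracy check)."""
    design = build_design(data, fit.spec.fixed_terms)
    y = data[fit.spec.response].to_numpy(dtype=float)
    codes, n_groups = _group_index(data[fit.spec.group_col])
    order = quadrature_order or fit.quadrature_order
    negll = _loglik_factory(y, design.to_numpy(dtype=float), codes, n_groups, fit.spec.family, order)
    params = list(fit.beta.reindex(design.columns).to_numpy())
    if fit.zi_logit is not None:
        params.append(fit.zi_logit)
    params.append(fit.sigma_b)
    return -negll(np.asarray(params))


def fit_zip_mixed(
    spec: ModelSpec, data: pd.DataFrame, quadrature_order: int = 20, seed: int = 0, restarts: int = 3
) -> MixedFit:
    """Zero-inflated Poisson mixed fit (intercept-only zero inflation)."""
    if spec.family != "zip":
        raise ValueError("spec family must be 'zip'")
    return _fit_mixed(spec, data, quadrature_order, restarts=restarts, seed=seed)


def fit_logistic_mixed(
    spec: ModelSpec, data: pd.DataFrame, quadrature_order: int = 20, seed: int = 0, restarts: int = 3
) -> MixedFit:
    """Bernoulli-logit mixed fit with separation detection."""
    if spec.family != "binomial":
        raise ValueError("spec family must be 'binomial'")
    return _fit_mixed(spec, data, quadrature_order, restarts=restarts, seed=seed)


def fit_model(
    model: int, trials: pd.DataFrame, quadrature_order: int = 20, seed: int = 0, restarts: int = 3
) -> tuple[MixedFit, MixedFit, LrtResult]:
    """Fit one of the four preset models: returns (full, control, LRT)."""
    spec = model_spec(model)
    data = response_differences(trials)
    data = data[data["trigger_context"] != "grunt"] if model in (1, 2, 3) else filter_model4(data)
    fit_fn = fit_zip_mixed if spec.family == "zip" else fit_logistic_mixed
    full = fit_fn(spec, data, quadrature_order, seed=seed, restarts=restarts)
    null_spec = replace(spec, name=spec.name + "_control", tested_terms=())
    null = fit_fn(null_spec, data, quadrature_order, seed=seed, restarts=restarts)
    return full, null, likelihood_ratio_test(full, null)


def likelihood_ratio_test(full: MixedFit, null: MixedFit) -> LrtResult:
    """Full-vs-null chi-square test; specs must be nested on the same data."""
    if full.n_obs != null.n_obs:
        raise ValueError("full and null models were fitted on different data")
    if not set(null.beta.index) <= set(full.beta.index):
        raise ValueError("null model terms are not a subset of the full model")
    df = full.n_params - null.n_params
    if df < 1:
        if full.n_params == null.n_params and set(null.beta.index) == set(full.beta.index):
            return LrtResult(0.0, 1, 1.0)  # identical models: no evidence by construction
        raise ValueError("full model must have more parameters than the null")
    chi2 = max(0.0, 2.0 * (full.loglik - null.loglik))
    return LrtResult(float(chi2), int(df), float(chi2_dist.sf(chi2, df)))


def pairwise_contrasts(
    fit: MixedFit,
    factor: str = "trigger_context",
    method: Literal["bonferroni", "tukey"] = "bonferroni",
) -> pd.DataFrame:
    """All pairwise level contrasts of a fitted categorical factor.

    Level effects are 0 for the baseline and the dummy coefficients
    otherwise; contrast SEs come from the fixed-effect covariance by the
    delta method, z statistics are referred to the normal, and p values
    are adjusted by Bonferroni or the studentized-range (Tukey)
    reference.
    """
    prefix = f"{factor}["
    dummy_cols = [c for c in fit.beta.index if c.startswith(prefix)]
    if not dummy_cols:
        raise ValueError(f"factor {factor!r} has no fitted levels")
    levels = [fit.baselines.get(factor, "<baseline>")] + [c[len(prefix) : -1] for c in dummy_cols]

    def effect_vector(level: str) -> np.ndarray:
        v = np.zeros(len(fit.beta))
        col = f"{factor}[{level}]"
        if col in fit.beta.index:
            v[list(fit.beta.index).index(col)] = 1.0
        return v

    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    m = len(pairs)
    k = len(levels)
    rows = []
    V = fit.cov.to_numpy()
    for a, b in pairs:
        c = effect_vector(a) - effect_vector(b)
        est = float(c @ fit.beta.to_numpy())
        se = float(np.sqrt(c @ V @ c))
        z = est / se if se > 0 else np.inf * np.sign(est or 1)
        raw = float(2 * norm.sf(abs(z)))
        if method == "bonferroni":
            adj = min(1.0, raw * m)
        elif method == "tukey":
            adj = float(studentized_range.sf(abs(z) * np.sqrt(2), k, 1e6))
        else:
            raise ValueError(f"unknown adjustment {method!r}")
        rows.append(
            {
                "contrast": f"{a} - {b}",
                "estimate": est,
                "se": se,
                "z": z,
                "p_raw": raw,
                "p_adjusted": max(raw, adj),
                "method": method,
            }
        )
    return pd.DataFrame(rows)


def vif(design: pd.DataFrame, term_groups: Mapping[str, Sequence[str]] | None = None) -> pd.Series:
    """Variance inflation factors of a model matrix.

    Continuous terms get the classic 1/(1-R^2); multi-column categorical
    terms get the generalized VIF^(1/(2 df)) computed from correlation
    determinants.  The intercept column is ignored.  Perfect collinearity
    yields ``inf``.
    """
    cols = [c for c in design.columns if c != "intercept"]
    if len(cols) < 2:
        raise ValueError("need at least 2 predictors")
    X = design[cols].to_numpy(dtype=float)
    if term_groups is None:
        groups: dict[str, list[str]] = {}
        for c in cols:
            term = c.split("[")[0]
            groups.setdefault(term, []).append(c)
    else:
        groups = {t: list(cs) for t, cs in term_groups.items()}

    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    det_R = np.linalg.det(R)
    out = {}
    for term, members in groups.items():
        idx = [cols.index(c) for c in members]
        rest = [i for i in range(len(cols)) if i not in idx]
        if not rest:
            out[term] = 1.0
            continue
        if det_R <= 1e-12:
            out[term] = np.inf
            continue
        det_sub = np.linalg.det(R[np.ix_(idx, idx)])
        det_rest = np.linalg.det(R[np.ix_(rest, rest)])
        gvif = det_sub * det_rest / det_R
        df = len(idx)
        out[term] = float(gvif ** (1.0 / (2 * df))) ** 2 if df == 1 else float(gvif ** (1.0 / (2 * df)))
    return pd.Series(out, name="vif")
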