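"""Multilevel models linking network structure to patient outcomes.

Patients are clustered in networks, and every model carries a
network-level random intercept:

* continuity of care (ACSS total or a subscale) — linear mixed model
  (REML), reporting standardized betas: the outcome and the network
  metric are standardized, patient-level controls (age, sex, HoNOS,
  recruitment service type) stay on their natural scales.
  ICC = sigma_u^2 / (sigma_u^2 + sigma_e^2).
* social integration (SIX total, 0..6) — random-intercept
  proportional-odds (cumulative logit) model, fitted by maximum
  likelihood with Gauss-Hermite quadrature over the network intercept;
  reports one odds ratio per covariate and the latent-scale
  ICC = sigma_u^2 / (sigma_u^2 + pi^2/3).

Model 1 ("bivariate") enters each network metric separately, always with
the controls; Model 2 is a forward-stepwise selection among the metrics
significant in Model 1 (entry p < 0.05, removal p >= 0.05, two-sided
Wald), controls always retained.  ICC p-values come from a likelihood-
ratio test of the variance component against the 50:50 chi2(0)/chi2(1)
mixture reference.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit, logsumexp
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from carenet.patient_scores import acss_total, six_total
from carenet.survey_io import SERVICE_TYPES, PatientRecord

__all__ = [
    "ModelResult",
    "fit_continuity_bivariate",
    "fit_continuity_stepwise",
    "fit_six_model",
    "fit_six_multinomial",
    "screen_candidates",
    "icc",
    "render_model_tables",
    "ALPHA_ENTRY",
]

#: Two-sided Wald significance threshold for Model-1 screening and for
#: stepwise entry/removal.
ALPHA_ENTRY = 0.05

_CONTROL_NOTE = "controlled for age, sex, HoNOS and recruitment service type"


@dataclass
class ModelResult:
    """One fitted model: estimates, clustering summary, fit statistics.

    ``estimates`` maps covariate name to a standardized beta (linear
    models) or an odds ratio (ordinal models); ``pvalues`` holds the
    matching two-sided Wald p-values.  ``selected`` lists the network
    metrics in the final model (one entry for bivariate fits).
    """

    outcome: str
    stage: str
    kind: str  # "linear" | "ordinal"
    estimates: dict[str, float]
    pvalues: dict[str, float]
    icc: float
    icc_p: float
    aic: float
    n_obs: int
    n_groups: int
    selected: list[str] = field(default_factory=list)
    converged: bool = True
    note: str = _CONTROL_NOTE


def icc(var_between: float, var_within: Optional[float] = None, *, ordinal: bool = False) -> float:
    """Intra-class correlation from variance components.

    For ordinal (latent-logistic) models the within-network variance is
    the standard-logistic variance pi^2/3.
    """
    if ordinal:
        if var_within is not None:
            raise ValueError("var_within is fixed at pi^2/3 for ordinal models")
        var_within = math.pi**2 / 3.0
    if var_within is None:
        raise ValueError("var_within required for non-ordinal models")
    if var_between < 0 or var_within < 0:
        raise ValueError("variance components must be non-negative")
    total = var_between + var_within
    if total == 0:
        raise ValueError("both variance components are zero; ICC undefined")
    return var_between / total


# ---------------------------------------------------------------------------
# design-matrix assembly
# ---------------------------------------------------------------------------


def _patient_frame(patients: Sequence[PatientRecord], outcome: str) -> pd.DataFrame:
    rows = []
    for p in patients:
        if not p.complete:
            continue
        if outcome == "six":
            y: float = six_total(p.six_employment, p.six_accommodation, p.six_family, p.six_friends).total
        elif outcome == "continuity":
            y = acss_total(p.acss_items).total
        elif outcome.startswith("continuity:"):
            sub = outcome.split(":", 1)[1]
            y = acss_total(p.acss_items).subscales[sub]
        else:
            raise ValueError(f"unknown outcome {outcome!r}")
        rows.append(
            {
                "network_id": p.network_id,
                "y": float(y),
                "age": float(p.age),
                "male": 1.0 if p.sex == "male" else 0.0,
                "honos": float(p.honos),
                "recruit": p.recruitment_service_type,
            }
        )
    if not rows:
        raise ValueError("no complete patient records")
    return pd.DataFrame(rows)


def _control_matrix(df: pd.DataFrame) -> pd.DataFrame:
    X = df[["age", "male", "honos"]].copy()
    # dummy-code recruitment service type against the first observed level
    levels = [t for t in SERVICE_TYPES if t in set(df["recruit"])]
    for level in levels[1:]:
        X[f"recruit_{level}"] = (df["recruit"] == level).astype(float)
    return X


def _design(
    patients: Sequence[PatientRecord],
    metric_rows: pd.DataFrame,
    metric_names: Sequence[str],
    outcome: str,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Merge standardized network metrics onto complete patient records.

    Networks where any requested metric is undefined (e.g. a Coleman index
    with no out-ties for the type) are excluded from that model, complete-
    case at the network level.  Returns (df, X, metric_columns): ``df``
    has the outcome and grouping, ``X`` the full fixed-effects matrix.
    """
    df = _patient_frame(patients, outcome)
    zcols: list[str] = []
    net = metric_rows.copy()
    for m in metric_names:
        if m not in net.columns:
            raise KeyError(f"metric {m!r} not in the metric table")
        col = net[m].astype(float)
        keep = col.dropna()
        sd = keep.std(ddof=1)
        if len(keep) < 2 or not np.isfinite(sd) or sd == 0:
            raise ValueError(f"metric {m!r} is constant across networks; cannot standardize")
        net[f"z_{m}"] = (col - keep.mean()) / sd
        zcols.append(f"z_{m}")
    merged = df.merge(
        net[zcols].reset_index().rename(columns={net.index.name or "index": "network_id"}),
        on="network_id",
        how="left",
    )
    merged = merged.dropna(subset=zcols)
    if merged["network_id"].nunique() < 2:
        raise ValueError("need patients from at least 2 networks")
    X = _control_matrix(merged)
    for zc in zcols:
        X.insert(0, zc, merged[zc].to_numpy())
    return merged, X, zcols


# ---------------------------------------------------------------------------
# linear mixed models (continuity)
# ---------------------------------------------------------------------------


def _fit_mixedlm(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray):
    exog = X.copy()
    exog.insert(0, "Intercept", 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM(y, exog, groups=groups)
        res_reml = model.fit(reml=True)
        res_ml = MixedLM(y, exog, groups=groups).fit(reml=False)
    return res_reml, res_ml


def _linear_icc_test(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray, llf_ml: float) -> float:
    """LRT p-value for sigma_u^2 = 0 against the 0.5 chi2(0) + 0.5 chi2(1) mixture."""
    import statsmodels.api as sm

    exog = sm.add_constant(X.to_numpy(dtype=float))
    llf_ols = sm.OLS(y, exog).fit().llf
    lr = 2.0 * (llf_ml - llf_ols)
    return 1.0 if lr <= 0 else 0.5 * float(stats.chi2.sf(lr, 1))


def fit_continuity_bivariate(
    patients: Sequence[PatientRecord],
    metric_name: str,
    metric_rows: pd.DataFrame,
    outcome: str = "continuity",
    random_intercept: bool = True,
) -> ModelResult:
    """Model 1: one standardized network metric plus the patient controls.

    With ``random_intercept=False`` the model degenerates to OLS (no
    clustering); that path exists for estimator checks, not for analysis.
    """
    df, X, zcols = _design(patients, metric_rows, [metric_name], outcome)
    y = df["y"].to_numpy(dtype=float)
    ysd = y.std(ddof=1)
    if ysd == 0:
        raise ValueError("outcome is constant; model undefined")
    yz = (y - y.mean()) / ysd
    groups = df["network_id"].to_numpy()

    if not random_intercept:
        import statsmodels.api as sm

        exog = X.copy()
        exog.insert(0, "Intercept", 1.0)
        res = sm.OLS(yz, exog).fit()
        est = {metric_name: float(res.params[zcols[0]])}
        pv = {metric_name: float(res.pvalues[zcols[0]])}
        return ModelResult(
            outcome=outcome,
            stage="bivariate",
            kind="linear",
            estimates=est,
            pvalues=pv,
            icc=0.0,
            icc_p=1.0,
            aic=float(res.aic),
            n_obs=len(yz),
            n_groups=df["network_id"].nunique(),
            selected=[metric_name],
        )

    res_reml, res_ml = _fit_mixedlm(yz, X, groups)
    var_u = float(np.asarray(res_reml.cov_re)[0, 0])
    var_e = float(res_reml.scale)
    estimates = {metric_name: float(res_reml.params[zcols[0]])}
    pvalues = {metric_name: float(res_reml.pvalues[zcols[0]])}
    for c in X.columns:
        if c in zcols:
            continue
        estimates[c] = float(res_reml.params[c])
        pvalues[c] = float(res_reml.pvalues[c])
    return ModelResult(
        outcome=outcome,
        stage="bivariate",
        kind="linear",
        estimates=estimates,
        pvalues=pvalues,
        icc=icc(var_u, var_e),
        icc_p=_linear_icc_test(yz, X, groups, res_ml.llf),
        aic=float(res_ml.aic),
        n_obs=len(yz),
        n_groups=df["network_id"].nunique(),
        selected=[metric_name],
        converged=bool(res_reml.converged),
    )


def screen_candidates(
    patients: Sequence[PatientRecord],
    metric_names: Sequence[str],
    metric_rows: pd.DataFrame,
    outcome: str = "continuity",
    alpha: float = ALPHA_ENTRY,
) -> list[str]:
    """Metrics whose Model-1 (bivariate) Wald p is below ``alpha``."""
    out = []
    for m in metric_names:
        res = fit_continuity_bivariate(patients, m, metric_rows, outcome)
        if res.pvalues[m] < alpha:
            out.append(m)
    return out


def fit_continuity_stepwise(
    patients: Sequence[PatientRecord],
    candidate_metrics: Sequence[str],
    metric_rows: pd.DataFrame,
    outcome: str = "continuity",
    alpha_enter: float = ALPHA_ENTRY,
    alpha_remove: float = ALPHA_ENTRY,
) -> ModelResult:
    """Model 2: forward-stepwise selection among the Model-1-significant metrics.

    At each step the not-yet-included candidate with the smallest Wald p
    enters if p < ``alpha_enter`` (ties broken by smaller p, then
    alphabetically); included metrics with p >= ``alpha_remove`` are then
    dropped.  Controls are always retained.  An empty candidate set yields
    the controls-only model (with a warning).
    """
    candidates = sorted(dict.fromkeys(candidate_metrics))
    if not candidates:
        warnings.warn("empty candidate set; fitting controls-only model")
    df, X_all, zcols = _design(patients, metric_rows, candidates, outcome)
    y = df["y"].to_numpy(dtype=float)
    yz = (y - y.mean()) / y.std(ddof=1)
    groups = df["network_id"].to_numpy()
    controls = [c for c in X_all.columns if c not in zcols]

    def fit_with(selected: list[str]):
        cols = [f"z_{m}" for m in selected] + controls
        return _fit_mixedlm(yz, X_all[cols], groups)

    selected: list[str] = []
    for _ in range(2 * len(candidates) + 2):  # cycling guard
        changed = False
        best: Optional[tuple[float, str]] = None
        for m in candidates:
            if m in selected:
                continue
            try:
                res_try, _ = fit_with(selected + [m])
            except (np.linalg.LinAlgError, ValueError):
                continue
            p = float(res_try.pvalues[f"z_{m}"])
            if not np.isfinite(p):
                continue
            if p < alpha_enter and (best is None or (p, m) < best):
                best = (p, m)
        if best is not None:
            selected.append(best[1])
            selected.sort()
            changed = True
        if selected:
            res_cur, _ = fit_with(selected)
            worst = max(selected, key=lambda m: float(res_cur.pvalues[f"z_{m}"]))
            if float(res_cur.pvalues[f"z_{worst}"]) >= alpha_remove:
                selected.remove(worst)
                changed = True
        if not changed:
            break

    res_reml, res_ml = fit_with(selected)
    var_u = float(np.asarray(res_reml.cov_re)[0, 0])
    var_e = float(res_reml.scale)
    cols = [f"z_{m}" for m in selected] + controls
    estimates, pvalues = {}, {}
    for c in cols:
        name = c[2:] if c.startswith("z_") else c
        estimates[name] = float(res_reml.params[c])
        pvalues[name] = float(res_reml.pvalues[c])
    return ModelResult(
        outcome=outcome,
        stage="stepwise",
        kind="linear",
        estimates=estimates,
        pvalues=pvalues,
        icc=icc(var_u, var_e),
        icc_p=_linear_icc_test(yz, X_all[cols], groups, res_ml.llf),
        aic=float(res_ml.aic),
        n_obs=len(yz),
        n_groups=df["network_id"].nunique(),
        selected=list(selected),
        converged=bool(res_reml.converged),
    )


# ---------------------------------------------------------------------------
# random-intercept proportional-odds model (social integration)
# ---------------------------------------------------------------------------


class _MixedOrdinalFit:
    """ML fit of a cumulative-logit model with a network random intercept.

    The latent response is eta + u_g + logistic noise; category c is
    observed when the latent falls between cutpoints alpha_c and
    alpha_{c+1}.  The marginal likelihood integrates the normal random
    intercept u_g by Gauss-Hermite quadrature (21 nodes).  Cutpoints are
    parameterized as (first, log-increments) to keep them ordered; the
    random-intercept SD as log sigma_u.
    """

    N_QUAD = 21

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y = np.asarray(y, dtype=int)
        self.X = np.asarray(X, dtype=float)
        cats = np.unique(self.y)
        self.cats = cats
        self.ycode = np.searchsorted(cats, self.y)
        self.n_cut = len(cats) - 1
        if self.n_cut < 1:
            raise ValueError("outcome is constant; ordinal model undefined")
        _, self.gidx = np.unique(groups, return_inverse=True)
        self.n_groups = self.gidx.max() + 1
        nodes, weights = hermgauss(self.N_QUAD)
        self.qnodes = nodes * math.sqrt(2.0)
        self.logw = np.log(weights / math.sqrt(math.pi))

    def _cutpoints(self, params: np.ndarray) -> np.ndarray:
        cut = np.empty(self.n_cut)
        cut[0] = params[0]
        if self.n_cut > 1:
            cut[1:] = params[0] + np.cumsum(np.exp(params[1 : self.n_cut]))
        return cut

    def unpack(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        cut = self._cutpoints(params)
        beta = params[self.n_cut : self.n_cut + self.X.shape[1]]
        sigma = math.exp(params[-1])
        return cut, beta, sigma

    def loglike(self, params: np.ndarray) -> float:
        return self.loglike_grad(params)[0]

    def loglike_grad(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        """Marginal log-likelihood and its analytic gradient.

        The gradient uses the standard mixture identity: with posterior
        node weights pi_gk proportional to w_k exp(S_gk), the derivative
        is the pi-weighted sum of per-observation score contributions.
        """
        cut, beta, sigma = self.unpack(params)
        n_cut, p_dim = self.n_cut, self.X.shape[1]
        ext = np.concatenate(([-np.inf], cut, [np.inf]))
        eta = self.X @ beta
        lo = ext[self.ycode][:, None]
        hi = ext[self.ycode + 1][:, None]
        u = (sigma * self.qnodes)[None, :]
        t_hi = hi - eta[:, None] - u
        t_lo = lo - eta[:, None] - u
        F_hi = expit(t_hi)
        F_lo = expit(t_lo)
        f_hi = np.where(np.isfinite(t_hi), F_hi * (1 - F_hi), 0.0)
        f_lo = np.where(np.isfinite(t_lo), F_lo * (1 - F_lo), 0.0)
        prob = np.clip(F_hi - F_lo, 1e-300, None)
        logp = np.log(prob)
        S = np.zeros((self.n_groups, self.N_QUAD))
        np.add.at(S, self.gidx, logp)
        Sw = S + self.logw[None, :]
        group_ll = logsumexp(Sw, axis=1)
        ll = float(np.sum(group_ll))

        post = np.exp(Sw - group_ll[:, None])  # (G, K) posterior node weights
        V = post[self.gidx]  # (n, K) weight for each obs/node
        pc = np.clip(prob, 1e-12, None)
        A = -(f_hi - f_lo) / pc  # dlogp/deta
        row_eta = np.sum(V * A, axis=1)
        grad_beta = self.X.T @ row_eta
        # cutpoint gradient on the alpha scale, then chain to (first, log-diffs)
        r_hi = np.sum(V * (f_hi / pc), axis=1)
        r_lo = np.sum(V * (f_lo / pc), axis=1)
        grad_alpha = np.zeros(n_cut)
        np.add.at(grad_alpha, np.clip(self.ycode, None, n_cut - 1), np.where(self.ycode <= n_cut - 1, r_hi, 0.0))
        np.add.at(grad_alpha, np.clip(self.ycode - 1, 0, None), np.where(self.ycode >= 1, -r_lo, 0.0))
        grad_cutparams = np.empty(n_cut)
        grad_cutparams[0] = grad_alpha.sum()
        if n_cut > 1:
            tail = np.cumsum(grad_alpha[::-1])[::-1]  # sum over cut indices >= r
            grad_cutparams[1:] = np.exp(params[1:n_cut]) * tail[1:]
        grad_logsigma = sigma * float(np.sum(np.sum(V * A * self.qnodes[None, :], axis=1)))
        grad = np.concatenate([grad_cutparams, grad_beta, [grad_logsigma]])
        return ll, grad

    def fit(self, start: np.ndarray, maxiter: int = 500) -> optimize.OptimizeResult:
        def objective(p):
            ll, g = self.loglike_grad(p)
            return -ll, -g

        res = optimize.minimize(
            objective,
            start,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 20000},
        )
        return res


def _ordinal_start(y: np.ndarray, X: pd.DataFrame) -> np.ndarray:
    """Starting values from the fixed-effects proportional-odds fit."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fe = OrderedModel(y, X.to_numpy(dtype=float), distr="logit").fit(method="bfgs", disp=False)
    k = X.shape[1]
    beta = np.asarray(fe.params[:k], dtype=float)
    thresh = np.asarray(fe.params[k:], dtype=float)  # (first, log-increments)
    return np.concatenate([thresh, beta, [math.log(0.3)]]), float(fe.llf), fe


def fit_six_model(
    patients: Sequence[PatientRecord],
    metric_names: Sequence[str],
    metric_rows: pd.DataFrame,
    stage: str = "bivariate",
    alpha_enter: float = ALPHA_ENTRY,
) -> ModelResult:
    """Proportional-odds model of the SIX total on network metrics + controls.

    ``stage`` is ``"bivariate"`` (one metric, Model 1), ``"multivariate"``
    (all supplied metrics forced in, Model 2 under forced entry) or
    ``"stepwise"`` (forward selection among the supplied metrics).
    Reports one odds ratio per covariate (exp of the latent coefficient),
    the latent-scale ICC, and the ML AIC.
    """
    if stage not in ("bivariate", "multivariate", "stepwise"):
        raise ValueError(f"unknown stage {stage!r}")
    metric_names = list(metric_names)
    if stage == "bivariate" and len(metric_names) != 1:
        raise ValueError("bivariate stage takes exactly one metric")
    df, X_all, zcols = _design(patients, metric_rows, metric_names, "six")
    y = df["y"].to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant; ordinal model undefined")
    groups = df["network_id"].to_numpy()
    controls = [c for c in X_all.columns if c not in zcols]

    def fit_cols(sel: list[str]):
        cols = [f"z_{m}" for m in sel] + controls
        X = X_all[cols]
        start, llf_fe, _ = _ordinal_start(y, X)
        mod = _MixedOrdinalFit(y, X.to_numpy(dtype=float), groups)
        res = mod.fit(start)
        if not res.success and abs(res.fun + llf_fe) > 50:  # far from any sane optimum
            raise RuntimeError(
                f"mixed ordinal fit did not converge: {res.message} "
                f"(nit={res.nit}, nfev={res.nfev})"
            )
        return mod, res, llf_fe, cols

    if stage == "stepwise":
        selected: list[str] = []
        while True:
            best = None
            for m in sorted(set(metric_names) - set(selected)):
                mod, res, llf_fe, cols = fit_cols(selected + [m])
                p = _ordinal_wald_p(mod, res, cols.index(f"z_{m}"))
                if p < alpha_enter and (best is None or (p, m) < best[:2]):
                    best = (p, m)
            if best is None:
                break
            selected.append(best[1])
            selected.sort()
        use = selected
    elif stage == "multivariate":
        use = metric_names
    else:
        use = metric_names

    mod, res, llf_fe, cols = fit_cols(use)
    cut, beta, sigma = mod.unpack(res.x)
    se = _ordinal_se(mod, res)
    k_beta0 = mod.n_cut
    estimates, pvalues = {}, {}
    for j, c in enumerate(cols):
        name = c[2:] if c.startswith("z_") else c
        b = beta[j]
        s = se[k_beta0 + j]
        z = b / s if s > 0 else np.nan
        estimates[name] = float(math.exp(b))
        pvalues[name] = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    llf = -res.fun
    n_params = len(res.x)
    lr = 2.0 * (llf - llf_fe)
    icc_p = 1.0 if lr <= 0 else 0.5 * float(stats.chi2.sf(lr, 1))
    return ModelResult(
        outcome="six",
        stage=stage,
        kind="ordinal",
        estimates=estimates,
        pvalues=pvalues,
        icc=icc(sigma**2, ordinal=True),
        icc_p=icc_p,
        aic=float(2 * n_params - 2 * llf),
        n_obs=len(y),
        n_groups=int(mod.n_groups),
        selected=list(use),
        converged=bool(res.success),
    )


def _ordinal_se(mod: _MixedOrdinalFit, res: optimize.OptimizeResult) -> np.ndarray:
    """Wald standard errors: central differences of the analytic gradient."""
    x = res.x
    n = len(x)
    h = 1e-5 * np.maximum(1.0, np.abs(x))
    H = np.zeros((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        _, gp = mod.loglike_grad(x + e)
        _, gm = mod.loglike_grad(x - e)
        H[:, i] = (gp - gm) / (2 * h[i])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n, np.nan)
    return se


def _ordinal_wald_p(mod: _MixedOrdinalFit, res: optimize.OptimizeResult, col_index: int) -> float:
    se = _ordinal_se(mod, res)
    _, beta, _ = mod.unpack(res.x)
    s = se[mod.n_cut + col_index]
    if not np.isfinite(s) or s <= 0:
        return float("nan")
    z = beta[col_index] / s
    return float(2 * stats.norm.sf(abs(z)))


def fit_six_multinomial(
    patients: Sequence[PatientRecord],
    metric_names: Sequence[str],
    metric_rows: pd.DataFrame,
) -> pd.DataFrame:
    """Per-category multinomial logit of the SIX total (no random effects).

    A check model only: it relaxes the proportional-odds assumption and
    ignores clustering, returning one odds ratio per covariate per
    non-reference category (reference: SIX = 0).
    """
    import statsmodels.api as sm

    df, X, zcols = _design(patients, metric_rows, list(metric_names), "six")
    exog = sm.add_constant(X.to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MNLogit(df["y"].to_numpy(dtype=int), exog).fit(disp=False, maxiter=200)
    names = ["const"] + list(X.columns)
    out = pd.DataFrame(np.exp(res.params), index=names)
    out.columns = [f"six_{c}" for c in range(1, out.shape[1] + 1)]
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_model_tables(results: Sequence[ModelResult]) -> tuple[pd.DataFrame, str]:
    """Tidy CSV-ready table plus a plain-text rendering.

    One row per covariate per model with the estimate (standardized beta
    or odds ratio) and p-value; ICC and AIC appear as footer rows per
    model.  The CSV round-trips: reading it back reproduces every number
    exactly (full float precision).
    """
    if not results:
        raise ValueError("no model results to render")
    rows = []
    for r in results:
        model = "+".join(r.selected) if r.selected else "controls_only"
        base = {"outcome": r.outcome, "stage": r.stage, "model": model}
        for cov, est in r.estimates.items():
            rows.append({**base, "row": cov, "estimate": est, "p_value": r.pvalues.get(cov, np.nan)})
        rows.append({**base, "row": "icc", "estimate": r.icc, "p_value": r.icc_p})
        rows.append({**base, "row": "aic", "estimate": r.aic, "p_value": np.nan})
    table = pd.DataFrame(rows)

    buf = io.StringIO()
    for r in results:
        label = "std beta" if r.kind == "linear" else "odds ratio"
        buf.write(f"== {r.outcome} ({r.stage}; {label}; n={r.n_obs}, networks={r.n_groups}) ==\n")
        buf.write(f"   [{r.note}]\n")
        for cov, est in r.estimates.items():
            p = r.pvalues.get(cov, np.nan)
            buf.write(f"  {cov:<34s} {est:8.3f}   p={p:.3f}\n")
        buf.write(f"  {'ICC (network level)':<34s} {100 * r.icc:7.2f}%   p={r.icc_p:.3f}\n")
        buf.write(f"  {'AIC':<34s} {r.aic:10.1f}\n\n")
    return table, buf.getvalue()
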