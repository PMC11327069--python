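"""Prognostic layer: Cox screening, risk signature, KM/log-rank, IPCW AUC.

The Cox model maximizes the Breslow partial likelihood by Newton-Raphson
(gradient norm < 1e-8, at most 100 iterations); standard errors come from
the inverse observed information.  Expression covariates enter as
standardized log2(TPM+1), with means/SDs frozen on the training cohort so a
validation cohort reuses them (and the training median risk score) without
leakage.  Time-dependent discrimination uses the cumulative/dynamic AUC with
inverse-probability-of-censoring weights from the Kaplan-Meier estimate of
the censoring distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    beta: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    loglik: float
    n_iter: int


def _breslow_derivatives(beta, X, time, event):
    """(loglik, gradient, information) of the Breslow partial likelihood."""
    n, p = X.shape
    order = np.argsort(-time, kind="stable")  # descending: cumsums = risk sets
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    eta = eta - eta.max()  # guard overflow; the shift cancels in all ratios
    w = np.exp(np.maximum(eta, -700.0))  # keep risk sums strictly positive
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xs, axis=0)
    S2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)

    # for tied times the risk set is everyone with time >= t: use the last
    # cumsum index within the tie block
    last_idx = np.arange(n)
    i = n - 2
    while i >= 0:
        if ts[i] == ts[i + 1]:
            last_idx[i] = last_idx[i + 1]
        i -= 1

    ev = es.astype(bool)
    idx = last_idx[ev]
    s0 = S0[idx]
    s1 = S1[idx]
    s2 = S2[idx]
    loglik = float(np.sum(eta[ev] - np.log(s0)))
    grad = np.sum(Xs[ev] - s1 / s0[:, None], axis=0)
    ratio = s1 / s0[:, None]
    info = np.sum(s2 / s0[:, None, None] - ratio[:, :, None] * ratio[:, None, :], axis=0)
    return loglik, grad, info


def cox_fit(time, event, X, tol: float = 1e-8, max_iter: int = 100) -> CoxResult:
    """Newton-Raphson Cox fit with Breslow tie handling.

    ``X`` is an (n x p) covariate matrix (array or DataFrame).  Raises on
    <2 events, constant covariates, non-convergence, or monotone likelihood
    (coefficients diverging, i.e. perfect separation).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 2:
        raise ValueError("cox_fit requires at least 2 events")
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant covariate in Cox design")

    beta = np.zeros(X.shape[1])
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        loglik, grad, info = _breslow_derivatives(beta, X, time, event)
        if np.linalg.norm(grad) < tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("Cox information matrix is singular") from exc
        beta = beta + step
        if np.abs(beta).max() > 50:
            raise RuntimeError(
                "Cox coefficients diverging (monotone likelihood / perfect separation)"
            )
    else:
        raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")

    loglik, grad, info = _breslow_derivatives(beta, X, time, event)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    hr = np.exp(beta)
    ci_low = np.exp(beta - 1.959963984540054 * se)
    ci_high = np.exp(beta + 1.959963984540054 * se)
    return CoxResult(beta, se, p, hr, ci_low, ci_high, loglik, n_iter)


# ---------------------------------------------------------------------------
# expression covariates & screening
# ---------------------------------------------------------------------------

def expression_covariates(tpm: pd.DataFrame, samples) -> pd.DataFrame:
    """log2(TPM+1) for the given samples, genes as columns (not standardized)."""
    return np.log2(tpm.loc[:, samples].T + 1.0)


def univariate_screen(
    tpm: pd.DataFrame,
    clinical: pd.DataFrame,
    candidates: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Single-gene Cox screen over ``candidates``; keep Wald p < alpha.

    Returns one row per candidate (beta, se, HR with CI, p, direction,
    selected).  Genes whose fit fails (e.g. constant expression) are reported
    with NaN statistics and not selected.
    """
    missing = set(candidates) - set(tpm.index)
    if missing:
        raise ValueError(f"candidates absent from expression matrix: {sorted(missing)[:5]}")
    covs = expression_covariates(tpm, clinical["sample_id"])
    time = clinical["time_days"].to_numpy()
    event = clinical["event"].to_numpy()
    rows = []
    for gid in candidates:
        x = covs[gid].to_numpy()
        sd = x.std(ddof=0)
        row = {"gene_id": gid, "beta": np.nan, "se": np.nan, "hr": np.nan,
               "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan}
        if sd > 0:
            z = (x - x.mean()) / sd
            try:
                fit = cox_fit(time, event, z[:, None])
                row.update(beta=fit.beta[0], se=fit.se[0], hr=fit.hr[0],
                           ci_low=fit.ci_low[0], ci_high=fit.ci_high[0],
                           p_value=fit.p_value[0])
            except RuntimeError as exc:
                logger.warning("univariate_screen: %s failed (%s)", gid, exc)
        else:
            logger.warning("univariate_screen: %s constant, skipped", gid)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene_id")
    out["direction"] = np.where(out["beta"] > 0, "risk", "protective")
    out["selected"] = out["p_value"] < alpha
    return out


# ---------------------------------------------------------------------------
# risk model
# ---------------------------------------------------------------------------

@dataclass
class RiskModel:
    panel: list[str]
    beta: np.ndarray
    mean: np.ndarray        # training-cohort per-gene mean of log2(TPM+1)
    sd: np.ndarray          # training-cohort per-gene SD
    median_score: float     # training-cohort median risk score

    def to_dict(self) -> dict:
        return {
            "panel": list(self.panel),
            "beta": self.beta.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "median_score": self.median_score,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(list(d["panel"]), np.asarray(d["beta"]), np.asarray(d["mean"]),
                   np.asarray(d["sd"]), float(d["median_score"]))


def fit_risk_model(tpm: pd.DataFrame, clinical: pd.DataFrame, panel: list[str]) -> tuple[RiskModel, CoxResult]:
    """Multivariate Cox over the panel on the training cohort."""
    covs = expression_covariates(tpm, clinical["sample_id"])[panel]
    mean = covs.mean(axis=0).to_numpy()
    sd = covs.std(axis=0, ddof=0).to_numpy()
    if (sd == 0).any():
        bad = [g for g, s in zip(panel, sd) if s == 0]
        raise ValueError(f"panel gene(s) constant in training cohort: {bad}")
    Z = (covs.to_numpy() - mean) / sd
    fit = cox_fit(clinical["time_days"].to_numpy(), clinical["event"].to_numpy(), Z)
    scores = Z @ fit.beta
    model = RiskModel(list(panel), fit.beta, mean, sd, float(np.median(scores)))
    return model, fit


def risk_score(model: RiskModel, tpm: pd.DataFrame, samples=None) -> pd.DataFrame:
    """Linear predictor and median-split labels, using frozen training
    standardization and the training median (all-tie scores all go "low")."""
    samples = list(samples) if samples is not None else list(tpm.columns)
    covs = expression_covariates(tpm, samples)[model.panel]
    Z = (covs.to_numpy() - model.mean) / model.sd
    scores = Z @ model.beta
    labels = np.where(scores > model.median_score, "high", "low")
    return pd.DataFrame({"score": scores, "group": labels}, index=samples)


# ---------------------------------------------------------------------------
# Kaplan-Meier & log-rank
# ---------------------------------------------------------------------------

def km_estimate(time, event) -> pd.DataFrame:
    """Product-limit estimator: one row per distinct event time.

    Columns: time, n_at_risk, n_events, survival.  ``median survival`` is
    available via :func:`km_median`.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("km_estimate requires at least 1 event")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    rows = []
    surv = 1.0
    for ut in np.unique(t[e == 1]):
        n_risk = int((t >= ut).sum())
        d = int(((t == ut) & (e == 1)).sum())
        surv *= 1.0 - d / n_risk
        rows.append((float(ut), n_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def km_median(curve: pd.DataFrame) -> float:
    below = curve[curve["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if len(below) else float("nan")


def km_survival_at(curve: pd.DataFrame, t: float, left: bool = False) -> float:
    """Step-function evaluation S(t) (right-continuous) or S(t-) (left)."""
    if left:
        past = curve[curve["time"] < t]
    else:
        past = curve[curve["time"] <= t]
    return float(past["survival"].iloc[-1]) if len(past) else 1.0


def logrank(time, event, group) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, p, df=k-1)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    k = len(levels)
    if k < 2:
        raise ValueError("logrank requires >=2 groups")
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for ut in np.unique(time[event == 1]):
        at_risk = time >= ut
        n = int(at_risk.sum())
        d = int(((time == ut) & (event == 1)).sum())
        if n <= 1:
            continue
        ng = np.array([(at_risk & (group == lv)).sum() for lv in levels], dtype=float)
        dg = np.array([(((time == ut) & (event == 1)) & (group == lv)).sum() for lv in levels], dtype=float)
        O += dg
        E += d * ng / n
        c = d * (n - d) / (n - 1.0)
        V += c * (np.diag(ng / n) - np.outer(ng, ng) / n**2)
    u = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    if np.allclose(u, 0.0):
        return 0.0, 1.0
    try:
        chi2 = float(u @ np.linalg.solve(Vsub, u))
    except np.linalg.LinAlgError:
        chi2 = float(u @ np.linalg.pinv(Vsub) @ u)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p


# ---------------------------------------------------------------------------
# time-dependent ROC AUC (IPCW cumulative/dynamic)
# ---------------------------------------------------------------------------

def censoring_km(time, event) -> pd.DataFrame:
    """KM estimate of the censoring distribution G (events = censorings)."""
    cens = 1 - np.asarray(event, dtype=int)
    if cens.sum() == 0:
        return pd.DataFrame(columns=["time", "n_at_risk", "n_events", "survival"])
    return km_estimate(time, cens)


def time_dependent_auc(scores, time, event, horizons=(365, 1095, 1825)) -> pd.Series:
    """Cumulative/dynamic AUC at each horizon with IPCW weights.

    Cases at horizon t: event by t; controls: event-free past t.  Case i gets
    weight 1/G(T_i-), control j weight 1/G(t), G the censoring-distribution
    KM.  Horizons with no case, no control, or beyond the last follow-up are
    reported as NaN.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g_curve = censoring_km(time, event)

    def G(t, left=False):
        if g_curve.empty:
            return 1.0
        return km_survival_at(g_curve, t, left=left)

    out = {}
    tmax = time.max()
    for h in horizons:
        if h > tmax:
            out[h] = np.nan
            continue
        case = (time <= h) & (event == 1)
        control = time > h
        if case.sum() == 0 or control.sum() == 0:
            out[h] = np.nan
            continue
        w_case = np.array([1.0 / max(G(t, left=True), 1e-12) for t in time[case]])
        w_ctrl = np.full(int(control.sum()), 1.0 / max(G(h), 1e-12))
        s_case = scores[case]
        s_ctrl = scores[control]
        comp = (s_case[:, None] > s_ctrl[None, :]).astype(float)
        comp += 0.5 * (s_case[:, None] == s_ctrl[None, :])
        wmat = np.outer(w_case, w_ctrl)
        out[h] = float((wmat * comp).sum() / wmat.sum())
    return pd.Series(out, name="auc")
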