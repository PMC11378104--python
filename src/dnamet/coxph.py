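"""Cox proportional-hazards mortality models and model composition.

The partial-likelihood machinery is written directly in numpy: Efron
tie correction, Newton-Raphson with step halving to a gradient norm of
1e-8, standard errors from the inverse observed information.  A fast
pairwise Harrell C-index (with per-subject contribution vectors) powers
both the stepwise backward/forward model composition and the paired
C-index comparison test.  The time-dependent IPCW AUC delegates to
scikit-survival and the proportional-hazards diagnostic to lifelines'
Grambsch-Therneau test; both sit behind this module's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class CoxConvergenceError(RuntimeError):
    pass


@dataclass
class CoxFit:
    """Fitted Cox model: per-covariate estimates plus global summaries."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    log_likelihood: float
    n: int
    n_events: int
    concordance: float

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    def summary(self) -> pd.DataFrame:
        lo = np.exp(self.beta - 1.959963984540054 * self.se)
        hi = np.exp(self.beta + 1.959963984540054 * self.se)
        return pd.DataFrame({"beta": self.beta, "se": self.se, "z": self.z, "p": self.p,
                             "hr": self.hr, "hr_lo95": lo, "hr_hi95": hi}, index=self.names)


def _check_survival(survival: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    time = survival["time"].to_numpy(float)
    event = survival["event"].to_numpy(int)
    if (time <= 0).any():
        raise ValueError("survival times must be strictly positive")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return time, event


class _CoxProblem:
    """Pre-sorted survival layout reused across likelihood evaluations."""

    def __init__(self, X: np.ndarray, time: np.ndarray, event: np.ndarray):
        order = np.argsort(-time, kind="stable")
        self.x = np.ascontiguousarray(X[order])
        t_s = time[order]
        self.e = event[order]
        n = len(t_s)
        boundaries = np.append(np.nonzero(np.diff(t_s))[0], n - 1)
        singles_last, singles_ev = [], []
        tied = []  # (last_index, event positions) for groups with >= 2 tied events
        start = 0
        for last in boundaries:
            ev = start + np.nonzero(self.e[start:last + 1] == 1)[0]
            if len(ev) == 1:
                singles_last.append(last)
                singles_ev.append(ev[0])
            elif len(ev) > 1:
                tied.append((last, ev))
            start = last + 1
        self.singles_last = np.asarray(singles_last, int)
        self.singles_ev = np.asarray(singles_ev, int)
        self.tied = tied

    def loglik(self, beta: np.ndarray, with_derivatives: bool = True):
        x = self.x
        n, p = x.shape
        eta = x @ beta
        eta -= eta.max()  # overflow guard; cancels in ratios and in ll identically
        w = np.exp(eta)
        cw = np.cumsum(w)
        ll = float(eta[self.singles_ev].sum()) - float(np.log(cw[self.singles_last]).sum())
        if with_derivatives:
            wx = w[:, None] * x
            cwx = np.cumsum(wx, axis=0)
            denom = cw[self.singles_last]
            mu = cwx[self.singles_last] / denom[:, None]
            grad = x[self.singles_ev].sum(0) - mu.sum(0)
            # sum_g S2R/denom = sum_i w_i x_i x_i' * (#groups with last >= i)/denom
            # weight for row i: sum over single-event groups with last index >= i of 1/denom_g
            marks = np.zeros(n)
            marks[self.singles_last] = 1.0 / denom
            row_w = np.cumsum(marks[::-1])[::-1]
            xw = x * (w * row_w)[:, None]
            info = x.T @ xw - mu.T @ mu
        for last, ev in self.tied:
            d = len(ev)
            s0r = cw[last]
            s0d = w[ev].sum()
            ll += float(eta[ev].sum())
            if with_derivatives:
                s1r = cwx[last]
                s1d = wx[ev].sum(0)
                x_risk = x[:last + 1]
                w_risk = w[:last + 1]
                s2r = x_risk.T @ (x_risk * w_risk[:, None])
                x_d = x[ev]
                s2d = x_d.T @ (x_d * w[ev][:, None])
                grad += x_d.sum(0)
            for l in range(d):
                frac = l / d
                dnm = s0r - frac * s0d
                ll -= np.log(dnm)
                if with_derivatives:
                    num1 = s1r - frac * s1d
                    mu_l = num1 / dnm
                    grad -= mu_l
                    info += (s2r - frac * s2d) / dnm - np.outer(mu_l, mu_l)
        if with_derivatives:
            return ll, grad, info
        return ll


def efron_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray,
                 with_derivatives: bool = True):
    """Efron-corrected partial log-likelihood (optionally gradient + information)."""
    return _CoxProblem(np.asarray(X, float), np.asarray(time, float),
                       np.asarray(event, int)).loglik(np.asarray(beta, float),
                                                      with_derivatives)


def fit_cox(X: pd.DataFrame, survival: pd.DataFrame, tol: float = 1e-8,
            max_iter: int = 100, compute_concordance: bool = True) -> CoxFit:
    """Newton-Raphson Efron Cox fit; SEs from the inverse observed information.

    Raises on constant covariates and on monotone-likelihood
    non-convergence (where coefficients diverge), suggesting
    penalisation in the latter case.
    """
    time, event = _check_survival(survival.loc[X.index] if hasattr(X, "index") else survival)
    x = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(x.shape[1])]
    if event.sum() < 1:
        raise ValueError("at least one event required")
    sds = x.std(0)
    if (sds == 0).any():
        raise ValueError(f"constant covariate: {names[int(np.flatnonzero(sds == 0)[0])]}")
    if np.isnan(x).any():
        raise ValueError("missing covariate values")

    problem = _CoxProblem(x, time, event)
    beta = np.zeros(x.shape[1])
    ll, grad, info = problem.loglik(beta)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise CoxConvergenceError(
                "singular information matrix (collinear covariates?)") from err
        scale = 1.0
        for _ in range(20):
            cand = beta + scale * step
            ll_new = problem.loglik(cand, with_derivatives=False)
            if ll_new >= ll - 1e-9 * max(1.0, abs(ll)):
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(beta)) > 80:
            raise CoxConvergenceError(
                "coefficients diverging (monotone likelihood); consider penalization")
        ll, grad, info = problem.loglik(beta)
    else:
        if np.max(np.abs(grad)) >= max(tol, 1e-5):
            raise CoxConvergenceError("Newton-Raphson did not converge")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as err:
        raise CoxConvergenceError("singular information at optimum") from err
    se = np.sqrt(np.diag(cov))
    # monotone likelihood plateaus numerically: huge coefficient with an
    # essentially infinite standard error
    runaway = (np.abs(beta) > 20) & (se > 100 * (1 + np.abs(beta)))
    if runaway.any():
        raise CoxConvergenceError(
            f"coefficient for {names[int(np.flatnonzero(runaway)[0])]} diverges "
            "(monotone likelihood); consider penalization")
    c = float("nan")
    if compute_concordance:
        c = concordance(x @ beta, pd.DataFrame({"time": time, "event": event}))
    return CoxFit(names, beta, se, float(ll), len(time), int(event.sum()), c)


# ---------------------------------------------------------------------------
# Harrell concordance


def _usable_pairs(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) index arrays where subject i is the definite earlier failure.

    Usable pairs: i fails (event) strictly before j, or at the same time
    as a censored j.  Pairs with equal times and both events are not
    usable (no ordering of failure is observed).
    """
    t_col = time[:, None]
    e_i = event[:, None].astype(bool)
    first = (t_col < time[None, :]) | ((t_col == time[None, :]) & ~event[None, :].astype(bool))
    first &= e_i
    np.fill_diagonal(first, False)
    return np.nonzero(first)


def concordance(risk: np.ndarray, survival: pd.DataFrame,
                return_contributions: bool = False):
    """Harrell C: higher risk should fail first; score ties count 0.5."""
    time, event = _check_survival(survival)
    risk = np.asarray(risk, float)
    if not np.isfinite(risk).all():
        raise ValueError("non-finite risk scores")
    i_idx, j_idx = _usable_pairs(time, event)
    if len(i_idx) == 0:
        raise ValueError("no usable pairs")
    diff = risk[i_idx] - risk[j_idx]
    score = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    c = float(score.sum() / len(score))
    if not return_contributions:
        return c
    n = len(time)
    num = np.bincount(i_idx, weights=score, minlength=n) + \
        np.bincount(j_idx, weights=score, minlength=n)
    den = np.bincount(i_idx, minlength=n) + np.bincount(j_idx, minlength=n)
    with np.errstate(invalid="ignore"):
        contrib = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return c, contrib


def compare_concordance(risk_a: np.ndarray, risk_b: np.ndarray,
                        survival: pd.DataFrame) -> tuple[float, float]:
    """Paired comparison of two models' C-indices on the same samples.

    Per-subject concordance contributions are computed for each risk
    vector; the difference vector feeds a paired two-sided t-test, which
    accounts for the correlation between the two models' contributions.
    Returns (C_a - C_b, p).
    """
    c_a, contrib_a = concordance(risk_a, survival, return_contributions=True)
    c_b, contrib_b = concordance(risk_b, survival, return_contributions=True)
    mask = np.isfinite(contrib_a) & np.isfinite(contrib_b)
    diffs = contrib_a[mask] - contrib_b[mask]
    if np.allclose(diffs, 0):
        return float(c_a - c_b), 1.0
    tstat, p = stats.ttest_rel(contrib_a[mask], contrib_b[mask])
    return float(c_a - c_b), float(p)


# ---------------------------------------------------------------------------
# Scans and stepwise composition


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def univariate_scan(scores: pd.DataFrame, covariates: pd.DataFrame | None,
                    survival: pd.DataFrame, fdr_level: float = 0.05) -> pd.DataFrame:
    """One covariate-adjusted Cox fit per score column, BH-corrected across scores.

    Scores are expected z-scaled so hazard ratios read per SD.
    Per-feature fit failures are reported in the ``error`` column and
    excluded from the BH family rather than aborting the scan.
    """
    rows = []
    for name in scores.columns:
        if covariates is not None:
            X = pd.concat([scores[[name]], covariates.loc[scores.index]], axis=1)
        else:
            X = scores[[name]]
        row = {"feature": name, "hr": np.nan, "beta": np.nan, "se": np.nan,
               "p": np.nan, "error": ""}
        try:
            fit = fit_cox(X, survival.loc[scores.index])
            row.update(beta=fit.beta[0], se=fit.se[0], hr=fit.hr[0], p=fit.p[0])
        except (CoxConvergenceError, ValueError) as err:
            row["error"] = str(err)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < fdr_level
    out["covariates"] = ",".join(covariates.columns) if covariates is not None else ""
    return out


@dataclass
class StepwiseTrace:
    steps: list[dict] = field(default_factory=list)
    final_variables: list[str] = field(default_factory=list)
    final_fit: CoxFit | None = None
    warnings: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {"steps": self.steps, "final_variables": self.final_variables,
                "warnings": self.warnings,
                "final_c": self.final_fit.concordance if self.final_fit else None}


def stepwise_select(candidates: pd.DataFrame, base_covariates: pd.DataFrame,
                    survival: pd.DataFrame, tol_c: float = 0.001, p_in: float = 0.05,
                    p_out: float = 0.05, max_rounds: int = 100,
                    start_full: bool = False) -> StepwiseTrace:
    """C-index-driven backward/forward Cox composition over candidate scores.

    Base covariates (age, sex) are always retained.  Each round first
    tries the forward move with the largest C gain among candidates with
    Wald p < ``p_in`` (accepted if the gain exceeds ``tol_c``), then the
    backward removal of the worst-p included variable with p > ``p_out``
    whose removal costs at most ``tol_c`` of C.  Stops when no move
    qualifies, on state repetition (cycling), or after ``max_rounds``.
    Deterministic given the candidate column order.
    """
    surv = survival.loc[candidates.index]
    time, event = _check_survival(surv)
    i_idx, j_idx = _usable_pairs(time, event)
    if len(i_idx) == 0:
        raise ValueError("no usable pairs")

    def c_of(risk: np.ndarray) -> float:
        diff = risk[i_idx] - risk[j_idx]
        return float(np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0)).mean())

    def fit_set(included: list[str]):
        X = pd.concat([base_covariates.loc[candidates.index], candidates[included]], axis=1)
        fit = fit_cox(X, surv, compute_concordance=False)
        fit.concordance = c_of(X.to_numpy(float) @ fit.beta)
        return fit, fit.concordance

    trace = StepwiseTrace()
    included: list[str] = list(candidates.columns) if start_full else []
    current_fit, current_c = fit_set(included)
    seen = {frozenset(included)}
    for _ in range(max_rounds):
        moved = False
        # forward
        best = None
        for name in candidates.columns:
            if name in included:
                continue
            try:
                fit, c_new = fit_set(included + [name])
            except (CoxConvergenceError, ValueError):
                continue
            p_var = fit.p[list(fit.names).index(name)]
            if p_var < p_in and c_new - current_c > tol_c:
                if best is None or c_new > best[1]:
                    best = (name, c_new, p_var, fit)
        if best is not None:
            name, c_new, p_var, fit = best
            trace.steps.append({"action": "add", "variable": name, "c_before": current_c,
                                "c_after": c_new, "p": float(p_var)})
            included = included + [name]
            current_fit, current_c = fit, c_new
            moved = True
        else:
            # backward: drop the least significant removable variable
            removable = []
            for name in included:
                p_var = current_fit.p[list(current_fit.names).index(name)]
                if p_var > p_out:
                    try:
                        fit, c_new = fit_set([v for v in included if v != name])
                    except (CoxConvergenceError, ValueError):
                        continue
                    if current_c - c_new <= tol_c:
                        removable.append((p_var, name, fit, c_new))
            if removable:
                p_var, name, fit, c_new = max(removable)
                trace.steps.append({"action": "remove", "variable": name,
                                    "c_before": current_c, "c_after": c_new,
                                    "p": float(p_var)})
                included = [v for v in included if v != name]
                current_fit, current_c = fit, c_new
                moved = True
        if not moved:
            break
        state = frozenset(included)
        if state in seen:
            trace.warnings.append("cycling detected; stopping")
            break
        seen.add(state)
    trace.final_variables = included
    trace.final_fit = current_fit
    return trace


# ---------------------------------------------------------------------------
# Time-dependent discrimination and PH diagnostics


def td_auc(scores: np.ndarray, survival: pd.DataFrame, horizon_years: float) -> float:
    """Cumulative/dynamic IPCW AUC at a fixed horizon.

    Cases are subjects with an observed event by the horizon, controls
    those still at risk beyond it; censoring weights come from the
    Kaplan-Meier estimate of the censoring distribution
    (scikit-survival's ``cumulative_dynamic_auc``).
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    time, event = _check_survival(survival)
    if not ((time <= horizon_years) & (event == 1)).any():
        raise ValueError("no events before the horizon")
    if not (time > horizon_years).any():
        raise ValueError("no subjects at risk beyond the horizon")
    y = Surv.from_arrays(event.astype(bool), time)
    auc, _ = cumulative_dynamic_auc(y, y, np.asarray(scores, float), [horizon_years])
    return float(auc[0])


def schoenfeld_test(X: pd.DataFrame, survival: pd.DataFrame) -> pd.Series:
    """Grambsch-Therneau proportional-hazards test, KM time transform.

    Refits the model with lifelines internally and regresses the scaled
    Schoenfeld residuals on transformed time; returns a per-covariate
    p-value Series.  Requires at least two events.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    surv = survival.loc[X.index]
    time, event = _check_survival(surv)
    if event.sum() < 2:
        raise ValueError("Schoenfeld test needs at least 2 events")
    df = X.copy()
    df["_time"] = time
    df["_event"] = event
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_time", event_col="_event")
        res = proportional_hazard_test(cph, df, time_transform="km")
    p = res.summary["p"]
    p.index = p.index.get_level_values(0)
    return pd.Series({name: float(p.loc[name]) for name in X.columns})
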