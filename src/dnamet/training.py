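"""Nested cross-validated training of DNAm surrogates.

For each metabolic feature: within every outer-training set, a per-cohort
EWAS feeds the sign-consistency pre-selection; an inner K-fold CV tunes
the elastic-net penalty over a log-spaced grid; the model refit at the
best penalty is scored on the untouched outer test fold.  The delivered
model refits on all training data with pre-selection and penalty tuning
recomputed from scratch.  Outer folds estimate generalisation; nothing
from an outer test fold ever enters EWAS, pre-selection or tuning for
that fold, and the report carries a hash audit proving it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .elasticnet import enet_coef_path, fit_elastic_net, lambda_grid, lambda_max
from .ewas import preselect_cpgs, run_ewas


@dataclass
class TrainingConfig:
    """Hyper-parameters of the nested CV.

    alpha is the L1/L2 mixing of the elastic net, fixed at 0.5 by
    default.  ``preselect_in_inner`` re-runs EWAS pre-selection inside
    every inner fold (stricter, slower) instead of once per
    outer-training set.
    """

    alpha: float = 0.5
    n_outer_folds: int = 5
    n_inner_folds: int = 5
    preselect_p: float = 0.05
    variance_prefilter_sd: float | None = None
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4
    enet_tol: float = 1e-4
    preselect_in_inner: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0,1]")
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if not 0 < self.preselect_p < 1:
            raise ValueError("preselect_p must be in (0,1)")


@dataclass
class SurrogateModel:
    """Sparse CpG-weight linear predictor of one metabolic feature."""

    target: str
    intercept: float
    weights: dict[str, float]
    lam: float
    alpha: float
    n_preselected: int
    training_cohorts: list[str]

    @property
    def cpgs(self) -> list[str]:
        return list(self.weights)

    def predict(self, betas: pd.DataFrame, reference: dict[str, float] | None = None) -> pd.Series:
        from .projection import project_surrogates

        return project_surrogates([self], betas, reference)[0].iloc[:, 0]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"target": self.target, "intercept": self.intercept,
                       "alpha": self.alpha, "lambda": self.lam,
                       "n_preselected": self.n_preselected,
                       "training_cohorts": self.training_cohorts,
                       "weights": self.weights}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SurrogateModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["target"], d["intercept"], d["weights"], d["lambda"], d["alpha"],
                   d.get("n_preselected", len(d["weights"])), d.get("training_cohorts", []))


@dataclass
class PerformanceReport:
    target: str
    fold_rows: list[dict] = field(default_factory=list)
    mean_r: float = float("nan")
    tier: str = "undefined"
    empty_preselection: bool = False
    audit: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fold_rows)


def evaluate_predictions(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    """(Pearson R, RMSE); R is NaN when either vector has zero variance."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape or len(pred) < 3:
        raise ValueError("pred and obs must have equal length >= 3")
    if not (np.isfinite(pred).all() and np.isfinite(obs).all()):
        raise ValueError("non-finite values")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.all(pred == pred[0]) or np.all(obs == obs[0]):
        return float("nan"), rmse
    return float(stats.pearsonr(pred, obs)[0]), rmse


def assign_tier(mean_r: float) -> str:
    """Accuracy tier: accurate (R > 0.35), mild (0.2 < R <= 0.35), low (R <= 0.2)."""
    if mean_r is None or not np.isfinite(mean_r):
        return "undefined"
    if mean_r > 0.35:
        return "accurate"
    if mean_r > 0.2:
        return "mild"
    return "low"


def _ids_hash(ids) -> str:
    return hashlib.sha256("\n".join(sorted(map(str, ids))).encode()).hexdigest()


def _preselect_for(y: pd.Series, betas: pd.DataFrame, cohort_labels: pd.Series,
                   cohorts: list[str], config: TrainingConfig) -> list[str]:
    tables = [run_ewas(y, betas, cohort_labels, c) for c in cohorts]
    selected = preselect_cpgs(tables, config.preselect_p)
    if config.variance_prefilter_sd is not None and selected:
        sds = betas[selected].std(0, ddof=0)
        selected = [c for c in selected if sds[c] >= config.variance_prefilter_sd]
    return selected


def _tune_and_fit(y: pd.Series, betas: pd.DataFrame, cohort_labels: pd.Series,
                  cohorts: list[str], config: TrainingConfig, seed: int,
                  audit_entry: dict) -> tuple[float, np.ndarray, list[str], float]:
    """EWAS -> preselect -> inner-CV lambda tuning -> refit on all given data.

    Returns (intercept, coefs over selected CpGs, selected CpG ids, lambda).
    """
    selected = _preselect_for(y, betas, cohort_labels, cohorts, config)
    audit_entry["preselection_ids_hash"] = _ids_hash(betas.index)
    audit_entry["n_preselected"] = len(selected)
    if not selected:
        return float(y.mean()), np.zeros(0), [], float("nan")

    X = betas[selected].to_numpy(float)
    yv = y.to_numpy(float)
    lmax = lambda_max(X, yv, config.alpha)
    grid = lambda_grid(lmax, config.n_lambdas, config.lambda_min_ratio)

    inner = StratifiedKFold(n_splits=config.n_inner_folds, shuffle=True, random_state=seed)
    labels = cohort_labels.loc[betas.index].to_numpy()
    mse = np.zeros((config.n_inner_folds, len(grid)))
    inner_hashes = []
    for i, (tr, va) in enumerate(inner.split(X, labels)):
        if config.preselect_in_inner:
            sub = _preselect_for(y.iloc[tr], betas.iloc[tr], cohort_labels, cohorts, config)
            if not sub:
                mse[i] = np.mean((yv[va] - yv[tr].mean()) ** 2)
                continue
            Xi = betas[sub].to_numpy(float)
            b0s, coefs = enet_coef_path(Xi[tr], yv[tr], config.alpha, grid, config.enet_tol)
            preds = Xi[va] @ coefs + b0s
        else:
            b0s, coefs = enet_coef_path(X[tr], yv[tr], config.alpha, grid, config.enet_tol)
            preds = X[va] @ coefs + b0s
        mse[i] = np.mean((preds - yv[va][:, None]) ** 2, axis=0)
        inner_hashes.append({"train": _ids_hash(betas.index[tr]), "val": _ids_hash(betas.index[va])})
    best = int(np.argmin(mse.mean(0)))
    lam = float(grid[best])
    audit_entry["inner_folds"] = inner_hashes
    b0, coef = fit_elastic_net(X, yv, config.alpha, lam, tol=config.enet_tol)
    return b0, coef, selected, lam


def nested_cv_train(target: pd.Series, betas: pd.DataFrame, cohort_labels: pd.Series,
                    config: TrainingConfig | None = None,
                    target_name: str | None = None) -> tuple[SurrogateModel, PerformanceReport]:
    """Train a surrogate under nested stratified K-fold cross-validation.

    ``target`` must be complete and aligned with ``betas`` rows; at least
    two cohorts are required (per-cohort EWAS drives pre-selection).
    """
    config = config or TrainingConfig()
    target = target.loc[betas.index]
    cohorts = sorted(cohort_labels.loc[betas.index].unique())
    if len(cohorts) < 2:
        raise ValueError("nested CV training requires >= 2 cohorts")
    name = target_name or (target.name if target.name else "target")
    report = PerformanceReport(target=str(name))

    labels = cohort_labels.loc[betas.index].to_numpy()
    outer = StratifiedKFold(n_splits=config.n_outer_folds, shuffle=True,
                            random_state=config.seed)
    for fold, (tr, te) in enumerate(outer.split(np.zeros(len(labels)), labels)):
        audit = {"fold": fold,
                 "train_ids": list(map(str, betas.index[tr])),
                 "test_ids": list(map(str, betas.index[te])),
                 "train_ids_hash": _ids_hash(betas.index[tr]),
                 "test_ids_hash": _ids_hash(betas.index[te])}
        b0, coef, selected, lam = _tune_and_fit(
            target.iloc[tr], betas.iloc[tr], cohort_labels, cohorts, config,
            seed=config.seed + 1000 + fold, audit_entry=audit)
        if selected:
            pred = betas.iloc[te][selected].to_numpy(float) @ coef + b0
        else:
            pred = np.full(len(te), b0)
        r, rmse = evaluate_predictions(pred, target.iloc[te].to_numpy(float))
        report.fold_rows.append({"set": f"outer_fold_{fold}", "r": r, "rmse": rmse,
                                 "n": len(te), "lambda": lam, "n_selected":
                                 int(np.count_nonzero(coef))})
        report.audit.append(audit)

    rs = [row["r"] for row in report.fold_rows if np.isfinite(row["r"])]
    report.mean_r = float(np.mean(rs)) if rs else float("nan")
    report.tier = assign_tier(report.mean_r)

    final_audit = {"fold": "final", "train_ids_hash": _ids_hash(betas.index)}
    b0, coef, selected, lam = _tune_and_fit(target, betas, cohort_labels, cohorts, config,
                                            seed=config.seed + 9999, audit_entry=final_audit)
    report.audit.append(final_audit)
    report.empty_preselection = not selected
    nz = np.flatnonzero(coef) if len(coef) else np.array([], int)
    model = SurrogateModel(
        target=str(name), intercept=float(b0),
        weights={selected[j]: float(coef[j]) for j in nz},
        lam=lam, alpha=config.alpha, n_preselected=len(selected),
        training_cohorts=cohorts)
    return model, report


def evaluate_on_holdout(model: SurrogateModel, target: pd.Series, betas: pd.DataFrame,
                        set_name: str, report: PerformanceReport | None = None) -> dict:
    """Score a trained surrogate on a held-out dataset; optionally append to a report."""
    pred = model.predict(betas)
    r, rmse = evaluate_predictions(pred.to_numpy(), target.loc[betas.index].to_numpy(float))
    row = {"set": set_name, "r": r, "rmse": rmse, "n": len(betas),
           "lambda": model.lam, "n_selected": len(model.weights)}
    if report is not None:
        report.fold_rows.append(row)
        rs = [rr["r"] for rr in report.fold_rows if np.isfinite(rr["r"])]
        report.mean_r = float(np.mean(rs)) if rs else float("nan")
        report.tier = assign_tier(report.mean_r)
    return row
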