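"""Metabolomics quality control.

Fixed chain: per-cohort feature-missingness filter -> robust outlier
flagging -> removal of samples with more than ``max_outliers_per_sample``
flags -> NIPALS imputation of the remaining missing cells -> log
transform and pooled z-standardisation.  The chain is idempotent: a
second pass drops and flags nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class QCConfig:
    outlier_z_threshold: float = 5.0
    max_outliers_per_sample: int = 1
    feature_missingness_threshold: float = 0.3
    detection_limit_policy: str = "keep"  # or "set_missing" for zeros
    outlier_scale: str = "log"  # or "raw"
    nipals_components: int = 5
    nipals_tol: float = 1e-6
    nipals_max_iter: int = 500

    def __post_init__(self):
        if self.outlier_z_threshold <= 0:
            raise ValueError("outlier_z_threshold must be > 0")
        if not 0 < self.feature_missingness_threshold <= 1:
            raise ValueError("feature_missingness_threshold must be in (0,1]")
        if self.detection_limit_policy not in ("keep", "set_missing"):
            raise ValueError("detection_limit_policy must be 'keep' or 'set_missing'")
        if self.outlier_scale not in ("log", "raw"):
            raise ValueError("outlier_scale must be 'log' or 'raw'")


@dataclass
class QCReport:
    dropped_features: dict[str, dict] = field(default_factory=dict)
    flagged_outlier_cells: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)
    n_imputed: int = 0
    imputed_fraction: float = 0.0
    warnings: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "dropped_features": self.dropped_features,
            "flagged_outlier_cells": [list(c) for c in self.flagged_outlier_cells],
            "removed_samples": list(self.removed_samples),
            "n_imputed": int(self.n_imputed),
            "imputed_fraction": float(self.imputed_fraction),
            "warnings": list(self.warnings),
        }


def drop_high_missingness_features(metabolites: pd.DataFrame, cohort_labels: pd.Series,
                                   threshold: float = 0.3) -> tuple[pd.DataFrame, QCReport]:
    """Drop a feature when its missing fraction in ANY cohort exceeds ``threshold``.

    Strict inequality: a feature missing exactly at the threshold is kept.
    The report records the per-cohort missing fractions of dropped features.
    """
    if metabolites.empty:
        raise ValueError("empty metabolite matrix")
    report = QCReport()
    frac = metabolites.isna().groupby(cohort_labels.loc[metabolites.index].to_numpy()).mean()
    drop = frac.columns[(frac > threshold).any(axis=0)]
    for f in drop:
        worst = frac[f].idxmax()
        report.dropped_features[f] = {
            "reason": f"missingness {frac[f].max():.3f} in cohort {worst} > {threshold}",
            "per_cohort_missing": {c: float(v) for c, v in frac[f].items()},
        }
    return metabolites.drop(columns=list(drop)), report


def flag_outliers(metabolites: pd.DataFrame, z_threshold: float = 5.0,
                  scale: str = "log") -> pd.DataFrame:
    """Boolean frame marking cells with robust |z| above ``z_threshold``.

    The robust z of a cell is |x - median_f| / (1.4826 * MAD_f), computed
    per feature ignoring missing values, on the log scale by default.
    Features with zero MAD (constant) produce no flags.
    """
    x = metabolites.to_numpy(float)
    if scale == "log":
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.where(x > 0, np.log(x), np.nan)
    med = np.nanmedian(x, axis=0)
    mad = np.nanmedian(np.abs(x - med), axis=0) * 1.4826
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(x - med) / mad
    flags = (z > z_threshold) & (mad > 0)
    flags = np.where(np.isnan(x), False, flags)
    return pd.DataFrame(flags, index=metabolites.index, columns=metabolites.columns)


def remove_outlier_samples(flags: pd.DataFrame, max_outliers_per_sample: int = 1) -> list[str]:
    """Samples whose outlier-flag count strictly exceeds the allowance.

    The default of 1 mirrors the rule that samples with more than one
    outlying feature are excluded while a single outlier is tolerated.
    """
    counts = flags.sum(axis=1)
    return list(counts.index[counts > max_outliers_per_sample])


def nipals_impute(metabolites: pd.DataFrame, n_components: int = 5, tol: float = 1e-6,
                  max_iter: int = 500, report: QCReport | None = None) -> pd.DataFrame:
    """Impute missing cells from a rank-k NIPALS principal-component model.

    NIPALS iterates score/loading regressions using missing-aware inner
    products (sums over observed cells only), which lets it run directly
    on an incomplete matrix.  Observed cells are returned untouched;
    missing cells are filled from the column means plus the rank-k
    ``scores @ loadings.T`` reconstruction.

    Raises on any all-missing row or column.  Non-convergence of a
    component is a warning (recorded in ``report`` if given); the best
    available estimate is still used.

    After the missing-aware pass, the fill is refined to
    self-consistency: the rank-k reconstruction of the completed matrix
    re-estimates the missing cells until they stop moving.  On data that
    are exactly rank k this drives the imputation error to the
    convergence tolerance rather than leaving the small bias a single
    pass inherits from means computed on observed cells only.
    """
    x = metabolites.to_numpy(float).copy()
    miss = np.isnan(x)
    if not miss.any():
        return metabolites.copy()
    bad_cols = miss.all(axis=0)
    bad_rows = miss.all(axis=1)
    if bad_cols.any():
        raise ValueError(f"all-missing column(s): {list(metabolites.columns[bad_cols])}")
    if bad_rows.any():
        raise ValueError(f"all-missing row(s): {list(metabolites.index[bad_rows])}")

    mu = np.nanmean(x, axis=0)
    xc = x - mu
    xc[miss] = np.nan
    n, p = xc.shape
    k = min(n_components, n - 1, p)
    recon = np.zeros_like(xc)
    resid = xc.copy()
    obs = ~miss
    for comp in range(k):
        r0 = np.where(obs, resid, 0.0)
        # start from the column with the largest observed variance
        start = int(np.nanargmax(np.nansum(r0 ** 2, axis=0)))
        t = r0[:, start].copy()
        if np.allclose(t, 0):
            break
        for _ in range(max_iter):
            denom_p = obs.T @ (t ** 2)
            p_vec = (r0.T @ t) / np.where(denom_p > 0, denom_p, 1.0)
            norm = np.linalg.norm(p_vec)
            if norm == 0:
                break
            p_vec /= norm
            denom_t = obs @ (p_vec ** 2)
            t_new = (r0 @ p_vec) / np.where(denom_t > 0, denom_t, 1.0)
            delta = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
            t = t_new
            if delta < tol:
                break
        else:
            msg = f"NIPALS component {comp + 1} did not converge in {max_iter} iterations"
            warnings.warn(msg)
            if report is not None:
                report.warnings.append(msg)
        recon += np.outer(t, p_vec)
        resid = np.where(obs, resid - np.outer(t, p_vec), np.nan)
        r0 = np.where(obs, resid, 0.0)

    filled = x.copy()
    filled[miss] = (mu + recon)[miss]

    # EM refinement: alternate rank-k PCA of the completed matrix with
    # re-estimation of the missing cells until self-consistent.
    scale = max(float(np.nanstd(x)), 1e-12)
    for _ in range(max_iter):
        mu_f = filled.mean(0)
        u, s, vt = np.linalg.svd(filled - mu_f, full_matrices=False)
        approx = mu_f + (u[:, :k] * s[:k]) @ vt[:k]
        delta = np.max(np.abs(filled[miss] - approx[miss]))
        filled[miss] = approx[miss]
        if delta < tol * scale:
            break

    if report is not None:
        report.n_imputed = int(miss.sum())
        report.imputed_fraction = float(miss.sum() / x.size)
    return pd.DataFrame(filled, index=metabolites.index, columns=metabolites.columns)


def impute_concentrations(metabolites: pd.DataFrame, n_components: int = 5,
                          tol: float = 1e-6, max_iter: int = 500,
                          report: QCReport | None = None) -> pd.DataFrame:
    """NIPALS imputation for positive concentration data.

    Identical to :func:`nipals_impute` except imputed cells are floored
    at half the smallest observed value of their feature, so the matrix
    stays strictly positive for the downstream log transform.
    """
    if not metabolites.isna().to_numpy().any():
        return metabolites.copy()
    was_missing = metabolites.isna()
    floor = metabolites.min(axis=0, skipna=True) * 0.5
    filled = nipals_impute(metabolites, n_components, tol, max_iter, report)
    return filled.mask(was_missing, filled.clip(lower=floor, axis=1))


def log_standardize(metabolites: pd.DataFrame) -> pd.DataFrame:
    """log-transform then z-score each feature across all samples pooled."""
    x = metabolites.to_numpy(float)
    bad = ~(x > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive value at sample {metabolites.index[i]}, feature {metabolites.columns[j]}")
    y = np.log(x)
    y = (y - y.mean(0)) / y.std(0, ddof=0)
    return pd.DataFrame(y, index=metabolites.index, columns=metabolites.columns)


def run_qc(metabolites: pd.DataFrame, cohort_labels: pd.Series,
           config: QCConfig | None = None) -> tuple[pd.DataFrame, QCReport]:
    """Full QC chain; returns the log+z matrix and a merged report.

    Order is fixed: panel filter -> (detection-limit policy) -> outlier
    flagging -> sample removal -> NIPALS imputation -> log + z.
    """
    config = config or QCConfig()
    metab, report = drop_high_missingness_features(
        metabolites, cohort_labels, config.feature_missingness_threshold)
    if config.detection_limit_policy == "set_missing":
        metab = metab.mask(metab <= 0)
    flags = flag_outliers(metab, config.outlier_z_threshold, config.outlier_scale)
    report.flagged_outlier_cells = [
        (str(flags.index[i]), str(flags.columns[j]))
        for i, j in zip(*np.nonzero(flags.to_numpy()))]
    removed = remove_outlier_samples(flags, config.max_outliers_per_sample)
    report.removed_samples = removed
    metab = metab.drop(index=removed)
    metab = impute_concentrations(metab, config.nipals_components, config.nipals_tol,
                                  config.nipals_max_iter, report)
    return log_standardize(metab), report
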